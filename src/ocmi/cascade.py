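"""Neural network cascade (NNC): a ladder of small radial-basis-function
networks that folds screened MEIs, one at a time, into a single integrated
parameter tracking the normalized number of metastatic sites.

Every sub-model is a 1-11-1 or 2-11-1 RBF network: 1 or 2 normalized
inputs, 11 Gaussian hidden units, one linear output.  Training follows a
standard reproducible recipe: hidden centers by k-means on the training
subset, per-center widths from the nearest-center distance, and the output
layer by ridge-regularized least squares with the penalty chosen on a
verification subset.  Records are split 2:1:1 into training, verification
and testing subsets; the testing subset never touches fitting and yields
the generalization diagnostic R_Te alongside the training R_Tr.

The ladder starts from the strongest MEI; each subsequent step proposes a
2-input sub-model on (current integrated parameter, next MEI) and is kept
only when it raises the cohort-level Spearman correlation with the site
count by more than a small epsilon — MEIs that do not enhance the
correlation are rejected and the incumbent parameter carries forward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .cohort import CohortDataset, PatientRecord

#: Theoretical range of the model target (number of metastatic sites).
TARGET_RANGE = (0.0, 15.0)

#: Hidden-layer size of every sub-model (the "11" of 1-11-1 / 2-11-1).
N_HIDDEN = 11

#: Ridge penalties tried for the output layer; the verification subset picks.
RIDGE_GRID = (1e-10, 1e-8, 1e-6, 1e-4, 1e-2, 1e-1)

#: Width = WIDTH_SCALE x distance to the nearest other center, floored.
WIDTH_SCALE = 2.0
WIDTH_FLOOR = 1e-6


@dataclass
class Normalizer:
    """Per-MEI min-max scaling to [0,1], learned on training data; the
    target site count uses the fixed theoretical range [0, 15] so models
    transfer across cohorts."""

    mins: dict
    maxs: dict

    def transform(self, name: str, values):
        if name not in self.mins:
            raise KeyError(f"normalizer knows no MEI named {name!r}")
        lo, hi = self.mins[name], self.maxs[name]
        return np.clip((np.asarray(values, dtype=float) - lo) / (hi - lo), 0.0, 1.0)

    @staticmethod
    def normalize_target(site_counts):
        lo, hi = TARGET_RANGE
        return (np.asarray(site_counts, dtype=float) - lo) / (hi - lo)


def fit_minmax(cohort: CohortDataset, mei_names: list[str]) -> Normalizer:
    """Learn per-MEI training min/max over complete cases."""
    frame = cohort.mei_frame()
    mins: dict[str, float] = {}
    maxs: dict[str, float] = {}
    for name in mei_names:
        values = frame[name].dropna().to_numpy()
        if len(values) < 2 or np.ptp(values) == 0:
            raise ValueError(f"MEI {name!r} is constant or has fewer than 2 values; cannot normalize")
        mins[name] = float(values.min())
        maxs[name] = float(values.max())
    return Normalizer(mins=mins, maxs=maxs)


def apply_normalizer(norm: Normalizer, name: str, values):
    """(x - min)/(max - min), clipped to [0,1] for out-of-range values."""
    return norm.transform(name, values)


def holdout_split(n: int, seed: int, ratio: tuple[int, int, int] = (2, 1, 1)):
    """Random disjoint exhaustive (training, verification, testing) index
    sets in the given 2:1:1 ratio: training = round(n/2), the remainder
    split as evenly as possible with the extra record to verification
    (n=534 -> 267/134/133)."""
    if n < 4:
        raise ValueError(f"need at least 4 records to split 2:1:1, got {n}")
    if tuple(ratio) != (2, 1, 1):
        raise ValueError("only the 2:1:1 ratio is supported")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = round(n / 2)
    rem = n - n_train
    n_ver = rem - rem // 2  # extra record to verification
    train = perm[:n_train]
    ver = perm[n_train:n_train + n_ver]
    test = perm[n_train + n_ver:]
    return train, ver, test


@dataclass
class RBFSubnet:
    """One ladder sub-model: Gaussian RBF layer plus linear output.

    ``weights`` holds the 11 hidden-to-output weights, ``bias`` the output
    bias (together the 12 output-layer parameters); ``r_tr``/``r_te`` are
    Pearson correlations of prediction vs target on the training and
    testing subsets.
    """

    input_arity: int
    centers: np.ndarray          # (k, arity)
    widths: np.ndarray           # (k,)
    weights: np.ndarray          # (k,)
    bias: float
    ridge: float
    r_tr: float
    r_te: float

    def activations(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self.widths[None, :] ** 2))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.activations(X) @ self.weights + self.bias


def _safe_pearson(a: np.ndarray, b: np.ndarray, context: str = "") -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn(f"constant vector in correlation{context}; reporting r = 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_rbf_subnet(
    X,
    y,
    seed: int,
    n_hidden: int = N_HIDDEN,
    ridge_grid=RIDGE_GRID,
    width_scale: float = WIDTH_SCALE,
) -> RBFSubnet:
    """Fit one 1-11-1 / 2-11-1 sub-model on normalized data in [0,1].

    The rows are split 2:1:1; centers come from seeded k-means on the
    training subset, widths from the nearest-center distance (floored), and
    the output layer from ridge least squares with the penalty selected by
    verification-subset mean squared error.  If the training subset has
    fewer points than hidden units, the hidden layer shrinks to
    floor(n_train / 2) with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 2:
        X = X.T
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if X.shape[1] not in (1, 2):
        raise ValueError(f"input arity must be 1 or 2, got {X.shape[1]}")
    train, ver, test = holdout_split(n, seed=seed)
    if len(train) < n_hidden + 1:
        k = max(2, len(train) // 2)
        warnings.warn(
            f"training subset ({len(train)} points) smaller than {n_hidden} hidden "
            f"units; shrinking hidden layer to {k}"
        )
        n_hidden = k

    km = KMeans(n_clusters=n_hidden, random_state=seed % (2**31), n_init=4)
    km.fit(X[train])
    centers = km.cluster_centers_

    if len(centers) > 1:
        d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        widths = width_scale * np.sqrt(d2.min(axis=1))
    else:
        widths = np.array([1.0])
    widths = np.maximum(widths, WIDTH_FLOOR)

    def design(idx):
        d2 = ((X[idx][:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        phi = np.exp(-d2 / (2.0 * widths[None, :] ** 2))
        return np.hstack([phi, np.ones((len(idx), 1))])

    A_tr, A_ver = design(train), design(ver)
    y_tr, y_ver = y[train], y[ver]
    n_params = A_tr.shape[1]
    penalty_mask = np.ones(n_params)
    penalty_mask[-1] = 0.0  # bias not penalized

    best = None
    for lam in ridge_grid:
        # augmented least squares: stable down to tiny penalties
        aug = np.vstack([A_tr, np.sqrt(lam) * np.diag(penalty_mask)])
        rhs = np.concatenate([y_tr, np.zeros(n_params)])
        w, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
        mse = float(np.mean((A_ver @ w - y_ver) ** 2))
        if best is None or mse < best[0]:
            best = (mse, lam, w)
    _, ridge, w = best

    subnet = RBFSubnet(
        input_arity=X.shape[1],
        centers=centers,
        widths=widths,
        weights=w[:-1],
        bias=float(w[-1]),
        ridge=float(ridge),
        r_tr=0.0,
        r_te=0.0,
    )
    subnet.r_tr = _safe_pearson(subnet.predict(X[train]), y_tr, " (training subset)")
    subnet.r_te = _safe_pearson(subnet.predict(X[test]), y[test], " (testing subset)")
    return subnet


@dataclass
class LadderStep:
    """One accepted cascade step and the MEI(s) it folded in."""

    mei_names: list[str]   # 1 name (seed step) or 1 new MEI for later steps
    subnet: RBFSubnet
    rho_after: float


@dataclass
class NNCModel:
    """Fitted cascade: ordered ladder steps, the normalizer, and audit."""

    steps: list[LadderStep]
    normalizer: Normalizer
    rejected: list  # (mei_name, rho_delta)
    rho_train: float
    seed: int

    @property
    def used_meis(self) -> list[str]:
        names: list[str] = []
        for step in self.steps:
            names.extend(step.mei_names)
        return names


def _cohort_training_arrays(cohort: CohortDataset, mei_names: list[str], norm: Normalizer):
    """Complete cases across the candidate MEIs: normalized columns + target."""
    frame = cohort.mei_frame()[mei_names]
    mask = np.isfinite(frame.to_numpy()).all(axis=1)
    counts = cohort.site_counts()[mask]
    columns = {
        name: apply_normalizer(norm, name, frame[name].to_numpy()[mask]) for name in mei_names
    }
    return columns, counts, mask


def _cascade_rho(output: np.ndarray, counts: np.ndarray) -> float:
    if np.ptp(output) == 0 or np.ptp(counts) == 0:
        return 0.0
    return float(stats.spearmanr(output, counts).statistic)


def build_cascade(
    cohort: CohortDataset,
    ordered_meis: list[str] | None = None,
    seed: int = 0,
    epsilon: float = 0.005,
    n_hidden: int = N_HIDDEN,
) -> NNCModel:
    """Fit the full ladder on a cohort.

    Candidate order defaults to descending |rho| against the site count.
    The first step seeds the ladder with a 1-input sub-model on the top
    MEI; a 2-input sub-model on the top two replaces it only if it clears
    the epsilon gain, so a redundant second MEI is rejected rather than
    absorbed.  Later steps always propose 2-input sub-models on (incumbent
    parameter, next MEI).
    """
    if ordered_meis is None:
        frame = cohort.mei_frame()
        counts_all = cohort.site_counts()

        def abs_rho(name: str) -> float:
            v = frame[name].to_numpy()
            m = np.isfinite(v)
            if m.sum() < 3 or np.ptp(v[m]) == 0 or np.ptp(counts_all[m]) == 0:
                return 0.0
            return abs(float(stats.spearmanr(v[m], counts_all[m]).statistic))

        pos = {n: i for i, n in enumerate(cohort.mei_catalog)}
        ordered_meis = sorted(cohort.mei_catalog, key=lambda n: (-abs_rho(n), pos[n]))
    if len(ordered_meis) == 0:
        raise ValueError("no candidate MEIs")

    norm = fit_minmax(cohort, ordered_meis)
    columns, counts, _ = _cohort_training_arrays(cohort, ordered_meis, norm)
    y = Normalizer.normalize_target(counts)

    first = ordered_meis[0]
    subnet0 = fit_rbf_subnet(columns[first][:, None], y, seed=seed, n_hidden=n_hidden)
    output = np.clip(subnet0.predict(columns[first][:, None]), 0.0, 1.0)
    rho = _cascade_rho(output, counts)
    steps = [LadderStep(mei_names=[first], subnet=subnet0, rho_after=rho)]
    rejected: list[tuple[str, float]] = []

    for step_index, name in enumerate(ordered_meis[1:], start=1):
        step_seed = (seed + 7919 * step_index) % (2**31)
        if step_index == 1:
            # challenger consumes the top two MEIs directly (2-11-1)
            X = np.column_stack([columns[first], columns[name]])
        else:
            X = np.column_stack([output, columns[name]])
        subnet = fit_rbf_subnet(X, y, seed=step_seed, n_hidden=n_hidden)
        new_output = np.clip(subnet.predict(X), 0.0, 1.0)
        new_rho = _cascade_rho(new_output, counts)
        if new_rho > rho + epsilon:
            if step_index == 1:
                steps = [LadderStep(mei_names=[first, name], subnet=subnet, rho_after=new_rho)]
            else:
                steps.append(LadderStep(mei_names=[name], subnet=subnet, rho_after=new_rho))
            output, rho = new_output, new_rho
        else:
            rejected.append((name, new_rho - rho))

    if len(steps) == 1 and steps[0].subnet.input_arity == 1 and len(ordered_meis) > 1:
        warnings.warn(
            "no cascade step accepted beyond the seed; model degenerates to the "
            f"single best MEI {first!r}"
        )
    return NNCModel(steps=steps, normalizer=norm, rejected=rejected, rho_train=rho, seed=seed)


def cascade_predict(model: NNCModel, record: PatientRecord) -> float:
    """Forward pass for one patient; output in [0,1]."""
    for name in model.used_meis:
        if record.mei_values.get(name) is None:
            raise ValueError(f"record {record.patient_id!r} lacks required MEI {name!r}")
    return float(cascade_predict_values(model, {
        name: np.array([record.mei_values[name]]) for name in model.used_meis
    })[0])


def cascade_predict_values(model: NNCModel, mei_columns: dict) -> np.ndarray:
    """Vectorized forward pass from raw MEI columns (dict name -> array)."""
    first_step = model.steps[0]
    cols = [
        apply_normalizer(model.normalizer, name, mei_columns[name])
        for name in first_step.mei_names
    ]
    X = np.column_stack(cols)
    output = np.clip(first_step.subnet.predict(X), 0.0, 1.0)
    for step in model.steps[1:]:
        name = step.mei_names[0]
        x = apply_normalizer(model.normalizer, name, mei_columns[name])
        output = np.clip(step.subnet.predict(np.column_stack([output, x])), 0.0, 1.0)
    return output


def cascade_predict_cohort(model: NNCModel, cohort: CohortDataset) -> np.ndarray:
    """Forward pass for every record; raises if a required MEI is missing."""
    frame = cohort.mei_frame()
    for name in model.used_meis:
        col = frame[name].to_numpy()
        if not np.isfinite(col).all():
            bad = [cohort.records[i].patient_id for i in np.flatnonzero(~np.isfinite(col))]
            raise ValueError(f"records lacking required MEI {name!r}: {bad[:5]}")
    return cascade_predict_values(model, {n: frame[n].to_numpy() for n in model.used_meis})


@dataclass
class CVReport:
    fold_rho: list
    pooled_rho: float
    fold_sizes: list
    predictions: np.ndarray  # out-of-fold NNC output per record


def kfold_cv(
    cohort: CohortDataset,
    k: int = 10,
    seed: int = 0,
    ordered_meis: list[str] | None = None,
    epsilon: float = 0.005,
) -> CVReport:
    """k-fold cross-validation of the cascade: mutually exclusive folds of
    nearly equal size, the cascade rebuilt from scratch on each training
    portion, Spearman rho pooled over all out-of-fold predictions."""
    n = len(cohort)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} records for {k}-fold CV, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)

    counts = cohort.site_counts()
    predictions = np.full(n, np.nan)
    fold_rho: list[float] = []
    for i, fold in enumerate(folds):
        train_idx = np.setdiff1d(perm, fold)
        sub = cohort.subset(train_idx)
        model = build_cascade(
            sub, ordered_meis=ordered_meis, seed=(seed + 104729 * i) % (2**31), epsilon=epsilon
        )
        held = cohort.subset(fold)
        preds = cascade_predict_cohort(model, held)
        predictions[fold] = preds
        if np.ptp(preds) > 0 and np.ptp(counts[fold]) > 0:
            fold_rho.append(float(stats.spearmanr(preds, counts[fold]).statistic))
        else:
            fold_rho.append(float("nan"))
    pooled = _cascade_rho(predictions, counts)
    return CVReport(
        fold_rho=fold_rho,
        pooled_rho=pooled,
        fold_sizes=[len(f) for f in folds],
        predictions=predictions,
    )


# -- serialization ------------------------------------------------------

def model_to_dict(model: NNCModel) -> dict:
    return {
        "steps": [
            {
                "mei_names": step.mei_names,
                "rho_after": step.rho_after,
                "subnet": {
                    "input_arity": step.subnet.input_arity,
                    "centers": step.subnet.centers.tolist(),
                    "widths": step.subnet.widths.tolist(),
                    "weights": step.subnet.weights.tolist(),
                    "bias": step.subnet.bias,
                    "ridge": step.subnet.ridge,
                    "r_tr": step.subnet.r_tr,
                    "r_te": step.subnet.r_te,
                },
            }
            for step in model.steps
        ],
        "normalizer": {"mins": model.normalizer.mins, "maxs": model.normalizer.maxs},
        "rejected": [[n, d] for n, d in model.rejected],
        "rho_train": model.rho_train,
        "seed": model.seed,
    }


def model_from_dict(d: dict) -> NNCModel:
    steps = [
        LadderStep(
            mei_names=list(s["mei_names"]),
            rho_after=float(s["rho_after"]),
            subnet=RBFSubnet(
                input_arity=int(s["subnet"]["input_arity"]),
                centers=np.asarray(s["subnet"]["centers"], dtype=float),
                widths=np.asarray(s["subnet"]["widths"], dtype=float),
                weights=np.asarray(s["subnet"]["weights"], dtype=float),
                bias=float(s["subnet"]["bias"]),
                ridge=float(s["subnet"]["ridge"]),
                r_tr=float(s["subnet"]["r_tr"]),
                r_te=float(s["subnet"]["r_te"]),
            ),
        )
        for s in d["steps"]
    ]
    return NNCModel(
        steps=steps,
        normalizer=Normalizer(
            mins={k: float(v) for k, v in d["normalizer"]["mins"].items()},
            maxs={k: float(v) for k, v in d["normalizer"]["maxs"].items()},
        ),
        rejected=[(n, float(x)) for n, x in d["rejected"]],
        rho_train=float(d["rho_train"]),
        seed=int(d["seed"]),
    )
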