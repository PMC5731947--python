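"""Screening of medical examination indicators (MEIs) for association with
metastasis.

Two-stage screen:

1. *metastasis-related*: for each MEI and each of the 15 sites, a ROC test
   of whether the MEI separates site-positive from site-negative patients;
   related if any site gives AUC > 0.5 with P < 0.001 (Mann-Whitney).
2. *multi-organ-metastasis (MOM)-related*: additionally, Spearman |rho|
   > 0.1 with P < 0.001 against the per-patient count of metastatic sites.

MOM-related candidates then pass a collinearity filter: whenever two
candidates correlate at |rho| > 0.3 with each other, the one with the
weaker |rho| against the site count is eliminated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortDataset

#: Correlation-intensity bins on |rho| (right-open except the last).
INTENSITY_BINS = (
    (0.1, 0.3, "extremely weak"),
    (0.3, 0.5, "weak"),
    (0.5, 0.7, "moderate"),
    (0.7, 0.9, "strong"),
    (0.9, 1.0001, "extremely strong"),
)


def intensity_label(rho: float) -> str:
    """Verbal correlation-intensity label for |rho| (below 0.1: 'none')."""
    a = abs(rho)
    for low, high, label in INTENSITY_BINS:
        if low <= a < high:
            return label
    return "none"


def roc_auc(scores, labels, exact_threshold: int = 0) -> tuple[float, float]:
    """AUC of ``scores`` for the binary ``labels`` and the p-value of the
    Mann-Whitney test of AUC = 0.5.

    AUC is the rank (Mann-Whitney U) statistic with ties counted one half.
    The p-value uses the normal approximation with continuity correction;
    when both classes have fewer than ``exact_threshold`` observations the
    exact permutation distribution is used instead.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to compute an AUC")
    method = "exact" if max(len(pos), len(neg)) < exact_threshold else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    auc = float(res.statistic) / (len(pos) * len(neg))
    return auc, float(res.pvalue)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on average ranks) and its
    t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an input vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class MEIScreenRow:
    """Screening evidence for one MEI."""

    name: str
    site_auc: dict = field(default_factory=dict)        # site -> AUC
    site_p: dict = field(default_factory=dict)          # site -> p-value
    significant_sites: list = field(default_factory=list)
    rho: float = float("nan")
    rho_p: float = float("nan")
    intensity: str = "none"
    n_complete: int = 0
    is_metastasis_related: bool = False
    is_mom_related: bool = False
    survived_collinearity: bool = False
    displaced_by: str | None = None


@dataclass
class MEIScreenResult:
    rows: dict  # name -> MEIScreenRow
    alpha: float
    min_abs_rho: float

    @property
    def metastasis_related(self) -> list[str]:
        return [n for n, r in self.rows.items() if r.is_metastasis_related]

    @property
    def mom_related(self) -> list[str]:
        return [n for n, r in self.rows.items() if r.is_mom_related]

    @property
    def retained(self) -> list[str]:
        return [n for n, r in self.rows.items() if r.survived_collinearity]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rows.values():
            rows.append({
                "mei": r.name,
                "n_complete": r.n_complete,
                "rho": r.rho,
                "rho_p": r.rho_p,
                "intensity": r.intensity,
                "n_significant_sites": len(r.significant_sites),
                "significant_sites": ";".join(r.significant_sites),
                "metastasis_related": r.is_metastasis_related,
                "mom_related": r.is_mom_related,
                "survived_collinearity": r.survived_collinearity,
                "displaced_by": r.displaced_by or "",
            })
        return pd.DataFrame(rows)


def screen_meis(
    cohort: CohortDataset,
    alpha: float = 0.001,
    min_abs_rho: float = 0.1,
) -> MEIScreenResult:
    """Run the two-stage screen over the cohort's MEI catalog.

    Each MEI is evaluated on its complete cases.  Sites with fewer than two
    positive or two negative patients among those cases are skipped for that
    MEI; constant MEIs are skipped entirely with a warning.
    """
    site_matrix = cohort.site_matrix().to_numpy()
    sites = list(cohort.site_catalog)
    counts = cohort.site_counts()
    mei_frame = cohort.mei_frame()

    rows: dict[str, MEIScreenRow] = {}
    for name in cohort.mei_catalog:
        values = mei_frame[name].to_numpy()
        mask = np.isfinite(values)
        row = MEIScreenRow(name=name, n_complete=int(mask.sum()))
        if row.n_complete >= 3 and np.ptp(values[mask]) > 0:
            for j, site in enumerate(sites):
                labels = site_matrix[mask, j]
                if labels.sum() < 2 or (1 - labels).sum() < 2:
                    continue
                auc, p = roc_auc(values[mask], labels)
                row.site_auc[site] = auc
                row.site_p[site] = p
                # criterion applied to the marker's discriminating direction,
                # so inverse markers (prealbumin-like) are not discarded
                if max(auc, 1.0 - auc) > 0.5 and p < alpha:
                    row.significant_sites.append(site)
            if np.ptp(counts[mask]) > 0:
                row.rho, row.rho_p = spearman_rho(values[mask], counts[mask])
                row.intensity = intensity_label(row.rho)
            row.is_metastasis_related = len(row.significant_sites) > 0
            row.is_mom_related = (
                row.is_metastasis_related
                and abs(row.rho) > min_abs_rho
                and row.rho_p < alpha
            )
        else:
            warnings.warn(f"MEI {name!r} skipped: constant or fewer than 3 complete cases")
        rows[name] = row
    return MEIScreenResult(rows=rows, alpha=alpha, min_abs_rho=min_abs_rho)


def collinearity_filter(
    candidates: list[str],
    cohort: CohortDataset,
    result: MEIScreenResult | None = None,
    collinearity_threshold: float = 0.3,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy elimination of collinear candidates.

    Candidates are visited in descending |rho| against the site count
    (ties broken by catalog order); a candidate is retained iff its pairwise
    Spearman |rho| with every already-retained candidate is <= the
    threshold, else it is eliminated by the strongest retained partner.
    Returns (survivors, eliminations) where each elimination records
    (eliminated, displacing partner, pairwise |rho|).
    """
    mei_frame = cohort.mei_frame()
    counts = cohort.site_counts()

    def outcome_rho(name: str) -> float:
        if result is not None and name in result.rows and np.isfinite(result.rows[name].rho):
            return abs(result.rows[name].rho)
        values = mei_frame[name].to_numpy()
        mask = np.isfinite(values)
        return abs(spearman_rho(values[mask], counts[mask])[0])

    catalog_pos = {n: i for i, n in enumerate(cohort.mei_catalog)}
    ordered = sorted(candidates, key=lambda n: (-outcome_rho(n), catalog_pos[n]))

    retained: list[str] = []
    eliminations: list[tuple[str, str, float]] = []
    for name in ordered:
        displaced = None
        for kept in retained:
            pair = mei_frame[[name, kept]].dropna()
            r, _ = spearman_rho(pair[name].to_numpy(), pair[kept].to_numpy())
            if abs(r) > collinearity_threshold:
                displaced = (kept, abs(r))
                break
        if displaced is None:
            retained.append(name)
        else:
            eliminations.append((name, displaced[0], displaced[1]))

    if result is not None:
        partner = {e[0]: e[1] for e in eliminations}
        for name in candidates:
            if name in result.rows:
                result.rows[name].survived_collinearity = name in retained
                result.rows[name].displaced_by = partner.get(name)
    return retained, eliminations


def normality_report(cohort: CohortDataset) -> pd.DataFrame:
    """D'Agostino-Pearson omnibus normality test per MEI (diagnostic only:
    motivates rank-based statistics; gates nothing)."""
    mei_frame = cohort.mei_frame()
    rows = []
    for name in cohort.mei_catalog:
        values = mei_frame[name].dropna().to_numpy()
        if len(values) >= 20 and np.ptp(values) > 0:
            stat, p = stats.normaltest(values)
            rows.append({"mei": name, "n": len(values), "k2": float(stat), "p": float(p)})
        else:
            rows.append({"mei": name, "n": len(values), "k2": np.nan, "p": np.nan})
    return pd.DataFrame(rows)
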