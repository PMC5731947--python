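"""Ovarian cancer metastasis index (OCMI).

The index fuses the cascade output with the two intraoperative findings by
multiple linear regression:

    OCMI_raw = b0 + b1 * NNC + b2 * L + b3 * A

where NNC is the cascade's integrated parameter in [0,1], L is laterality
(0 unilateral / 1 bilateral) and A is ascites (0 not detected / 1
detected).  The regression target is the site count normalized by its
theoretical range [0,15], matching the cascade's target; scores are
reported both raw and min-max normalized by the training-score range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import Normalizer


@dataclass
class OCMIModel:
    intercept: float
    coef_nnc: float
    coef_laterality: float
    coef_ascites: float
    raw_min: float
    raw_max: float

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.intercept, self.coef_nnc, self.coef_laterality, self.coef_ascites])


def _design(nnc_outputs, laterality, ascites) -> np.ndarray:
    nnc = np.asarray(nnc_outputs, dtype=float)
    lat = np.asarray(laterality, dtype=float)
    asc = np.asarray(ascites, dtype=float)
    if not (nnc.shape == lat.shape == asc.shape):
        raise ValueError("predictor vectors must share one length")
    return np.column_stack([np.ones_like(nnc), nnc, lat, asc])


def fit_ocmi(nnc_outputs, laterality, ascites, site_counts) -> OCMIModel:
    """Ordinary least squares of the normalized site count on
    (1, NNC, L, A); errors on a rank-deficient design, naming the constant
    column."""
    X = _design(nnc_outputs, laterality, ascites)
    y = Normalizer.normalize_target(site_counts)
    if X.shape[0] < 4:
        raise ValueError(f"need at least 4 records to fit, got {X.shape[0]}")
    if y.shape[0] != X.shape[0]:
        raise ValueError("site_counts length differs from the predictors")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        names = ("nnc_output", "laterality", "ascites")
        constant = [n for n, j in zip(names, range(1, 4)) if np.ptp(X[:, j]) == 0]
        detail = f" (constant column: {', '.join(constant)})" if constant else ""
        raise ValueError(f"design matrix is rank-deficient{detail}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    raw = X @ beta
    return OCMIModel(
        intercept=float(beta[0]),
        coef_nnc=float(beta[1]),
        coef_laterality=float(beta[2]),
        coef_ascites=float(beta[3]),
        raw_min=float(raw.min()),
        raw_max=float(raw.max()),
    )


def ocmi_score(model: OCMIModel, nnc_outputs, laterality, ascites):
    """(raw, normalized) index scores; normalization by the training-score
    min/max, clipped to [0,1] for out-of-range patients."""
    X = _design(nnc_outputs, laterality, ascites)
    raw = X @ model.coefficients
    span = model.raw_max - model.raw_min
    if span <= 0:
        normalized = np.zeros_like(raw)
    else:
        normalized = np.clip((raw - model.raw_min) / span, 0.0, 1.0)
    return raw, normalized


def ocmi_to_dict(model: OCMIModel) -> dict:
    return {
        "intercept": model.intercept,
        "coef_nnc": model.coef_nnc,
        "coef_laterality": model.coef_laterality,
        "coef_ascites": model.coef_ascites,
        "raw_min": model.raw_min,
        "raw_max": model.raw_max,
    }


def ocmi_from_dict(d: dict) -> OCMIModel:
    return OCMIModel(**{k: float(v) for k, v in d.items()})
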