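"""Performance evaluation of metastasis scores.

Covers the pipeline's three evaluation views:

* the M/P curve — patients binned into 10 equidistant intervals of a
  normalized score; M/P is the per-interval ratio of the summed metastatic
  sites to the patient count, and its fitted slope across interval
  midpoints measures how steeply the score tracks metastatic burden;
* ROC analysis of a score for multi-organ metastasis (> 3 sites) and for
  any metastasis (>= 1 site), with Hanley-McNeil confidence intervals;
* Spearman correlations with the site count, overall and stratified by
  menopausal status, plus site-count means over the four ascites x
  laterality strata (S/A-, S/A+, D/A-, D/A+).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortDataset, label_multi_organ
from .screening import roc_auc, spearman_rho

#: ascites x laterality stratum labels: S unilateral / D bilateral,
#: A-/A+ ascites absent/present.
STRATA = ("S/A-", "S/A+", "D/A-", "D/A+")


@dataclass
class MPCurve:
    """M/P statistics over 10 equidistant score intervals on [0,1]."""

    n_intervals: int
    patient_counts: np.ndarray   # per interval
    site_sums: np.ndarray        # per interval
    mp_ratio: np.ndarray         # NaN where the interval is empty
    midpoints: np.ndarray
    slope: float | None          # None when < 2 non-empty intervals
    intercept: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "interval": np.arange(self.n_intervals),
            "midpoint": self.midpoints,
            "n_patients": self.patient_counts,
            "site_sum": self.site_sums,
            "mp_ratio": self.mp_ratio,
        })


def mp_curve(normalized_scores, site_counts, n_intervals: int = 10) -> MPCurve:
    """Bin scores into [i/k, (i+1)/k) (last interval closed) and fit the
    OLS slope of M/P against the non-empty interval midpoints."""
    scores = np.asarray(normalized_scores, dtype=float)
    counts = np.asarray(site_counts, dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("normalized scores must lie in [0, 1]")
    k = n_intervals
    bins = np.minimum((scores * k).astype(int), k - 1)  # closes the last interval
    patient_counts = np.bincount(bins, minlength=k)
    site_sums = np.bincount(bins, weights=counts, minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        mp = np.where(patient_counts > 0, site_sums / np.maximum(patient_counts, 1), np.nan)
    midpoints = (np.arange(k) + 0.5) / k

    nonempty = patient_counts > 0
    if nonempty.sum() >= 2:
        slope, intercept = np.polyfit(midpoints[nonempty], mp[nonempty], 1)
        slope, intercept = float(slope), float(intercept)
    else:
        slope = intercept = None
    return MPCurve(
        n_intervals=k,
        patient_counts=patient_counts,
        site_sums=site_sums,
        mp_ratio=mp,
        midpoints=midpoints,
        slope=slope,
        intercept=intercept,
    )


def hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int, level: float = 0.95):
    """Hanley-McNeil standard error and normal-approximation CI for an AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return max(0.0, auc - z * se), min(1.0, auc + z * se)


@dataclass
class ScoreEvaluation:
    """Evaluation of one named score vector against the site counts."""

    name: str
    rho_overall: float | None
    rho_p: float | None
    rho_premenopausal: float | None
    rho_postmenopausal: float | None
    auc_mom: float | None
    auc_mom_ci: tuple | None
    auc_mom_p: float | None
    auc_any: float | None
    auc_any_ci: tuple | None
    mp: MPCurve | None


@dataclass
class EvaluationReport:
    scores: dict = field(default_factory=dict)       # name -> ScoreEvaluation
    strata: dict = field(default_factory=dict)       # label -> (n, mean, sd)
    strata_anova_p: float | None = None
    mom_threshold: int = 3


def _stratum_rho(scores: np.ndarray, counts: np.ndarray, mask: np.ndarray):
    if mask.sum() < 3:
        return None
    s, c = scores[mask], counts[mask]
    if np.ptp(s) == 0 or np.ptp(c) == 0:
        return None
    return float(stats.spearmanr(s, c).statistic)


def _score_auc(scores: np.ndarray, labels: np.ndarray):
    if labels.sum() == 0 or labels.sum() == len(labels):
        return None, None, None
    auc, p = roc_auc(scores, labels)
    ci = hanley_mcneil_ci(auc, int(labels.sum()), int(len(labels) - labels.sum()))
    return auc, ci, p


def evaluate_scores(
    cohort: CohortDataset,
    score_sets: dict,
    mom_threshold: int = 3,
    normalized: dict | None = None,
) -> EvaluationReport:
    """Evaluate named score vectors (aligned to the cohort's records).

    ``normalized`` optionally maps score names to [0,1]-normalized versions
    for the M/P curve; scores already within [0,1] are used directly, any
    other score is min-max scaled for binning only (rank statistics are
    unaffected).
    """
    counts = cohort.site_counts().astype(float)
    menopause = cohort.column("menopause").astype(int)
    mom = np.array([label_multi_organ(int(c), mom_threshold) for c in counts])
    any_met = (counts >= 1).astype(int)

    report = EvaluationReport(mom_threshold=mom_threshold)
    for name, values in score_sets.items():
        scores = np.asarray(values, dtype=float)
        if scores.shape[0] != len(cohort):
            raise ValueError(f"score {name!r} not aligned to the cohort")
        rho = rho_p = None
        if np.ptp(scores) > 0 and np.ptp(counts) > 0:
            rho, rho_p = spearman_rho(scores, counts)
        auc_mom, ci_mom, p_mom = _score_auc(scores, mom)
        auc_any, ci_any, _ = _score_auc(scores, any_met)

        if normalized is not None and name in normalized:
            norm_scores = np.asarray(normalized[name], dtype=float)
        elif scores.min() >= 0 and scores.max() <= 1:
            norm_scores = scores
        elif np.ptp(scores) > 0:
            norm_scores = (scores - scores.min()) / np.ptp(scores)
        else:
            norm_scores = np.zeros_like(scores)
        curve = mp_curve(norm_scores, counts)

        report.scores[name] = ScoreEvaluation(
            name=name,
            rho_overall=rho,
            rho_p=rho_p,
            rho_premenopausal=_stratum_rho(scores, counts, menopause == 0),
            rho_postmenopausal=_stratum_rho(scores, counts, menopause == 1),
            auc_mom=auc_mom,
            auc_mom_ci=ci_mom,
            auc_mom_p=p_mom,
            auc_any=auc_any,
            auc_any_ci=ci_any,
            mp=curve,
        )

    report.strata = stratified_site_counts(cohort)
    groups = _strata_groups(cohort)
    filled = [g for g in groups.values() if len(g) >= 2]
    if len(filled) >= 2:
        report.strata_anova_p = float(stats.f_oneway(*filled).pvalue)
    return report


def _strata_groups(cohort: CohortDataset) -> dict:
    counts = cohort.site_counts().astype(float)
    lat = cohort.column("laterality").astype(int)
    asc = cohort.column("ascites").astype(int)
    masks = {
        "S/A-": (lat == 0) & (asc == 0),
        "S/A+": (lat == 0) & (asc == 1),
        "D/A-": (lat == 1) & (asc == 0),
        "D/A+": (lat == 1) & (asc == 1),
    }
    return {label: counts[m] for label, m in masks.items()}


def stratified_site_counts(cohort: CohortDataset) -> dict:
    """Per ascites x laterality stratum: (n, mean site count, SD).

    Empty strata report (0, nan, nan)."""
    out = {}
    for label, values in _strata_groups(cohort).items():
        if len(values) == 0:
            out[label] = (0, float("nan"), float("nan"))
        else:
            sd = float(values.std(ddof=1)) if len(values) > 1 else float("nan")
            out[label] = (int(len(values)), float(values.mean()), sd)
    return out


def report_to_dict(report: EvaluationReport) -> dict:
    """JSON-ready form of an evaluation report."""
    def _opt(x):
        return None if x is None else float(x)

    return {
        "mom_threshold": report.mom_threshold,
        "strata": {
            k: {"n": v[0], "mean": _opt(v[1]), "sd": _opt(v[2])} for k, v in report.strata.items()
        },
        "strata_anova_p": _opt(report.strata_anova_p),
        "scores": {
            name: {
                "rho_overall": _opt(ev.rho_overall),
                "rho_p": _opt(ev.rho_p),
                "rho_premenopausal": _opt(ev.rho_premenopausal),
                "rho_postmenopausal": _opt(ev.rho_postmenopausal),
                "auc_mom": _opt(ev.auc_mom),
                "auc_mom_ci": None if ev.auc_mom_ci is None else [float(c) for c in ev.auc_mom_ci],
                "auc_mom_p": _opt(ev.auc_mom_p),
                "auc_any": _opt(ev.auc_any),
                "auc_any_ci": None if ev.auc_any_ci is None else [float(c) for c in ev.auc_any_ci],
                "mp_slope": None if ev.mp is None else _opt(ev.mp.slope),
            }
            for name, ev in report.scores.items()
        },
    }
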