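"""Pairwise co-metastasis enrichment over the 15 surveyed sites.

For every unordered pair of sites the overlap between the two patient sets
is tested against the hypergeometric null (drawing the site-i positives at
random from the cohort), giving C(15,2) = 105 tests per cohort.  P-values
are adjusted by the Holm-Bonferroni step-down across all 105 tests; a pair
is called co-metastatic when the adjusted P is below 0.001 (-lgP > 3).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortDataset

#: -log10 cap substituted for infinities when the adjusted P underflows to 0.
NEG_LOG10_CAP = 300.0

#: Adjusted-P significance threshold on the -log10 scale (P < 0.001).
SIGNIFICANCE_NEG_LOG10 = 3.0

#: Display threshold used for network exports of the strongest pairs.
DISPLAY_NEG_LOG10 = 10.0


@dataclass(frozen=True)
class PairCounts:
    """Overlap counts for one site pair: ``N`` patients in the universe,
    ``M`` positive for site i, ``n`` positive for site j, ``m`` for both."""

    N: int
    M: int
    n: int
    m: int

    def validate(self) -> None:
        if min(self.N, self.M, self.n, self.m) < 0:
            raise ValueError(f"negative count in {self}")
        if self.M > self.N or self.n > self.N:
            raise ValueError(f"marginal exceeds universe in {self}")
        if self.m > min(self.M, self.n):
            raise ValueError(f"overlap exceeds a marginal in {self}")


def hypergeom_tail(counts: PairCounts, tail: str = "gt") -> float:
    """Upper-tail hypergeometric probability of the observed overlap.

    ``tail="gt"`` returns P(X > m) = 1 - sum_{k<=m} C(n,k) C(N-n,M-k)/C(N,M),
    the strictly-greater tail; ``tail="geq"`` returns the conventional
    P(X >= m).  Degenerate pairs with an empty marginal (M == 0 or n == 0)
    carry no co-occurrence evidence and return 1.0 by definition.
    """
    counts.validate()
    if counts.M == 0 or counts.n == 0:
        return 1.0
    dist = stats.hypergeom(counts.N, counts.M, counts.n)
    if tail == "gt":
        p = dist.sf(counts.m)
    elif tail == "geq":
        p = dist.sf(counts.m - 1)
    else:
        raise ValueError(f"tail must be 'gt' or 'geq', got {tail!r}")
    return float(min(1.0, max(0.0, p)))


def comet_matrix(cohort: CohortDataset, tail: str = "gt") -> tuple[pd.DataFrame, dict]:
    """Raw tail probabilities for all 105 site pairs.

    The universe N is the cohort size; M, n are the two per-site positive
    counts and m the co-positive count.  Returns a symmetric DataFrame
    (diagonal NaN) and the audit dict of :class:`PairCounts` per pair.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    sites = list(cohort.site_catalog)
    flags = cohort.site_matrix().to_numpy()
    N = flags.shape[0]
    positives = flags.sum(axis=0)
    overlap = flags.T @ flags

    raw = pd.DataFrame(np.nan, index=sites, columns=sites, dtype=float)
    pair_counts: dict[tuple[str, str], PairCounts] = {}
    for a, b in itertools.combinations(range(len(sites)), 2):
        counts = PairCounts(N=N, M=int(positives[a]), n=int(positives[b]), m=int(overlap[a, b]))
        p = hypergeom_tail(counts, tail=tail)
        raw.iloc[a, b] = raw.iloc[b, a] = p
        pair_counts[(sites[a], sites[b])] = counts
    return raw, pair_counts


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in input order.

    Sort ascending; adjusted(i) = max_{j<=i} (m - j) * p_(j) (0-based j),
    capped at 1.  Controls the family-wise error rate across the family.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m, dtype=float)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


@dataclass
class CoMetastasisResult:
    """Incidences plus raw/adjusted pairwise probabilities on 15 sites."""

    incidence: pd.Series
    raw_p: pd.DataFrame
    adjusted_p: pd.DataFrame
    neg_log10_p: pd.DataFrame
    pair_counts: dict
    significant_pairs: list  # (site_i, site_j, adjusted_p) with adj P < 0.001


def analyze_comet(cohort: CohortDataset, tail: str = "gt") -> CoMetastasisResult:
    """Full co-metastasis analysis: incidences, 105 raw tests, Holm
    adjustment across the family, -lg(adjusted P) matrix, significant pairs."""
    sites = list(cohort.site_catalog)
    flags = cohort.site_matrix()
    incidence = flags.mean(axis=0)
    raw, pair_counts = comet_matrix(cohort, tail=tail)

    pairs = list(pair_counts.keys())
    raw_vec = np.array([raw.loc[a, b] for a, b in pairs])
    adj_vec = holm_adjust(raw_vec)

    adjusted = pd.DataFrame(np.nan, index=sites, columns=sites, dtype=float)
    for (a, b), p in zip(pairs, adj_vec):
        adjusted.loc[a, b] = adjusted.loc[b, a] = p

    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(adjusted)
    neg_log10 = neg_log10.clip(upper=NEG_LOG10_CAP)

    threshold = 10.0 ** (-SIGNIFICANCE_NEG_LOG10)
    significant = [
        (a, b, float(p)) for (a, b), p in zip(pairs, adj_vec) if p < threshold
    ]
    return CoMetastasisResult(
        incidence=incidence,
        raw_p=raw,
        adjusted_p=adjusted,
        neg_log10_p=neg_log10,
        pair_counts=pair_counts,
        significant_pairs=significant,
    )


def comet_network(result: CoMetastasisResult, edge_threshold: float = DISPLAY_NEG_LOG10) -> list:
    """Edge list (site_i, site_j, -lgP) with -lgP strictly above the
    threshold; 3.0 selects adjusted-significant pairs, 10.0 the display set."""
    sites = list(result.neg_log10_p.index)
    edges = []
    for a, b in itertools.combinations(sites, 2):
        v = float(result.neg_log10_p.loc[a, b])
        if v > edge_threshold:
            edges.append((a, b, v))
    return edges
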