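"""ROC/Spearman MEI screening and collinearity filtering."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ocmi.screening import (
    collinearity_filter,
    intensity_label,
    normality_report,
    roc_auc,
    screen_meis,
    spearman_rho,
)

from conftest import cohort_with_counts, make_cohort


def pair_counting_auc(scores, labels):
    """Oracle: exhaustive concordant-pair count with ties worth one half."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum(1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def rank_pearson(x, y):
    """Oracle: Pearson correlation of average-ranked data."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestRocAuc:
    @pytest.mark.parametrize("scores, labels, expected", [
        ([10, 20, 1, 2], [1, 1, 0, 0], 1.0),     # perfect separation
        ([3, 5, 1, 4], [1, 1, 0, 0], 0.75),       # 3 of 4 concordant pairs
        ([2, 2], [1, 0], 0.5),                    # tie counts one half
    ])
    def test_known_values(self, scores, labels, expected):
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(expected, abs=1e-12)

    def test_one_class_empty_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_negation_symmetry(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = rng.normal(size=n).round(1)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            a, _ = roc_auc(scores, labels)
            b, _ = roc_auc(-scores, labels)
            assert a == pytest.approx(1.0 - b, abs=1e-12)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 21))
            scores = rng.integers(0, 8, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    def test_informative_marker_significant_p(self, rng):
        labels = np.repeat([0, 1], 100)
        scores = labels * 2.0 + rng.normal(size=200) * 0.5
        auc, p = roc_auc(scores, labels)
        assert auc > 0.9 and p < 1e-10


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.arange(1, 11, dtype=float)
        rho, _ = spearman_rho(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_hand_computed_example(self):
        rho, _ = spearman_rho([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 1.0, 1.0], [1, 2, 3])

    def test_matches_rank_pearson_oracle_with_ties(self, rng):
        for _ in range(500):
            n = int(rng.integers(3, 31))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman_rho(x, y)
            assert rho == pytest.approx(rank_pearson(x, y), abs=1e-12)


class TestIntensityBins:
    @pytest.mark.parametrize("rho, label", [
        (0.05, "none"), (0.1, "extremely weak"), (-0.25, "extremely weak"),
        (0.397, "weak"), (0.532, "moderate"), (0.673, "moderate"),
        (0.75, "strong"), (-0.95, "extremely strong"), (1.0, "extremely strong"),
    ])
    def test_bin_assignment(self, rho, label):
        assert intensity_label(rho) == label


class TestScreenMeis:
    def test_mei_equal_to_site_count_is_flagged_extremely_strong(self):
        counts = list(range(16)) * 3
        cohort = cohort_with_counts(counts, meis={"MIRROR": [float(c) for c in counts]})
        res = screen_meis(cohort)
        row = res.rows["MIRROR"]
        assert row.rho == pytest.approx(1.0)
        assert row.is_mom_related and row.is_metastasis_related
        assert row.intensity == "extremely strong"

    def test_inverse_marker_is_flagged(self):
        counts = list(range(16)) * 3
        cohort = cohort_with_counts(counts, meis={"INV": [-float(c) for c in counts]})
        row = screen_meis(cohort).rows["INV"]
        assert row.rho == pytest.approx(-1.0)
        assert row.is_mom_related

    def test_constant_mei_skipped_with_warning(self):
        counts = [0, 2, 4, 6]
        cohort = cohort_with_counts(counts, meis={"CONST": [5.0] * 4})
        with pytest.warns(UserWarning, match="CONST"):
            res = screen_meis(cohort)
        assert not res.rows["CONST"].is_metastasis_related

    def test_complete_cases_used_per_mei(self):
        counts = list(range(16)) * 2
        values = [float(c) for c in counts]
        values[0] = None
        cohort = cohort_with_counts(counts, meis={"PARTIAL": values})
        row = screen_meis(cohort).rows["PARTIAL"]
        assert row.n_complete == 31
        assert row.rho == pytest.approx(1.0)

    def test_output_invariant_to_mei_column_order(self):
        counts = list(range(16)) * 2
        a = [float(c) + 0.1 for c in counts]
        b = [float(-c) for c in counts]
        res_ab = screen_meis(cohort_with_counts(counts, meis={"A": a, "B": b}))
        res_ba = screen_meis(cohort_with_counts(counts, meis={"B": b, "A": a}))
        assert res_ab.rows["A"].rho == res_ba.rows["A"].rho
        assert res_ab.rows["B"].significant_sites == res_ba.rows["B"].significant_sites


class TestCollinearityFilter:
    def _chain_cohort(self, rng):
        """A, B, C with A~B and B~C collinear, A~C not; |rho| order A>B>C."""
        n = 400
        counts = rng.integers(0, 16, size=n)
        a = counts + rng.normal(0, 2.0, n)            # A: strongest vs outcome
        e_b = rng.normal(0, 4.0, n)
        b = a + e_b                                   # B: collinear with A
        c = e_b + 0.1 * counts + rng.normal(0, 1, n)  # C: collinear with B, not A
        return cohort_with_counts(counts, meis={"A": a, "B": b, "C": c})

    def test_duplicated_mei_lower_rho_eliminated(self, rng):
        counts = rng.integers(0, 16, size=200)
        strong = counts + rng.normal(0, 1, 200)
        weak = strong + rng.normal(0, 3, 200)
        cohort = cohort_with_counts(counts, meis={"WEAK": weak, "STRONG": strong})
        retained, elim = collinearity_filter(["WEAK", "STRONG"], cohort)
        assert retained == ["STRONG"]
        assert elim[0][0] == "WEAK" and elim[0][1] == "STRONG"

    def test_no_collinearity_is_a_no_op(self, rng):
        counts = rng.integers(0, 16, size=300)
        x = counts + rng.normal(0, 2, 300)
        y = rng.normal(size=300)
        cohort = cohort_with_counts(counts, meis={"X": x, "Y": y})
        retained, elim = collinearity_filter(["X", "Y"], cohort)
        assert set(retained) == {"X", "Y"} and elim == []

    def test_chain_drops_middle_then_keeps_ends(self, rng):
        cohort = self._chain_cohort(rng)
        from ocmi.screening import spearman_rho
        frame = cohort.mei_frame()
        counts = cohort.site_counts()
        # confirm the constructed fixture has the intended structure
        r_ab = abs(spearman_rho(frame["A"], frame["B"])[0])
        r_bc = abs(spearman_rho(frame["B"], frame["C"])[0])
        r_ac = abs(spearman_rho(frame["A"], frame["C"])[0])
        assert r_ab > 0.3 and r_bc > 0.3 and r_ac <= 0.3
        rhos = {m: abs(spearman_rho(frame[m], counts)[0]) for m in "ABC"}
        assert rhos["A"] > rhos["B"] > rhos["C"]
        retained, elim = collinearity_filter(["A", "B", "C"], cohort)
        assert retained == ["A", "C"]
        assert elim == [("B", "A", pytest.approx(r_ab))]


def test_normality_report_flags_lognormal_not_gaussian(rng):
    counts = rng.integers(0, 16, size=200)
    cohort = cohort_with_counts(counts, meis={
        "LOGN": np.exp(rng.normal(0, 1, 200)),
        "GAUSS": rng.normal(50, 5, 200),
    })
    rep = normality_report(cohort).set_index("mei")
    assert rep.loc["LOGN", "p"] < 0.001
    assert rep.loc["GAUSS", "p"] > 0.001
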