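"""Normalization, the 2:1:1 split, RBF sub-models, cascade, k-fold CV."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from ocmi.cascade import (
    Normalizer,
    RBFSubnet,
    apply_normalizer,
    build_cascade,
    cascade_predict,
    cascade_predict_cohort,
    fit_minmax,
    fit_rbf_subnet,
    holdout_split,
    kfold_cv,
    model_from_dict,
    model_to_dict,
)
from ocmi.synthetic import default_config, generate_cohort

from conftest import cohort_with_counts


class TestNormalizer:
    def _norm(self):
        counts = [0, 1, 2]
        return fit_minmax(cohort_with_counts(counts, meis={"X": [2.0, 4.0, 6.0]}), ["X"])

    def test_midpoint_maps_to_half(self):
        assert apply_normalizer(self._norm(), "X", 4.0) == pytest.approx(0.5)

    def test_out_of_range_values_clip(self):
        norm = self._norm()
        assert apply_normalizer(norm, "X", 1.0) == 0.0
        assert apply_normalizer(norm, "X", 9.0) == 1.0  # 1.5x training max
        assert apply_normalizer(norm, "X", 2.0) == 0.0
        assert apply_normalizer(norm, "X", 6.0) == 1.0

    def test_target_uses_fixed_theoretical_range(self):
        assert Normalizer.normalize_target([0, 15, 6]).tolist() == [0.0, 1.0, 0.4]

    def test_constant_mei_rejected_by_name(self):
        cohort = cohort_with_counts([0, 1, 2], meis={"FLAT": [3.0, 3.0, 3.0]})
        with pytest.raises(ValueError, match="FLAT"):
            fit_minmax(cohort, ["FLAT"])

    def test_unknown_mei_rejected(self):
        with pytest.raises(KeyError):
            apply_normalizer(self._norm(), "NOPE", 1.0)


class TestHoldoutSplit:
    @pytest.mark.parametrize("n, sizes", [
        (534, (267, 134, 133)),
        (4, (2, 1, 1)),
        (8, (4, 2, 2)),
        (9, (4, 3, 2)),
    ])
    def test_sizes(self, n, sizes):
        tr, ver, te = holdout_split(n, seed=0)
        assert (len(tr), len(ver), len(te)) == sizes

    def test_disjoint_and_exhaustive(self):
        tr, ver, te = holdout_split(101, seed=5)
        joined = np.concatenate([tr, ver, te])
        assert sorted(joined) == list(range(101))

    def test_deterministic_given_seed(self):
        a = holdout_split(50, seed=7)
        b = holdout_split(50, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            holdout_split(3, seed=0)


class TestRBFSubnet:
    def test_identity_target_learned_on_uniform_grid(self, rng):
        x = rng.uniform(0, 1, 200)[:, None]
        net = fit_rbf_subnet(x, x.ravel(), seed=1)
        assert net.r_tr >= 0.99 and net.r_te >= 0.99
        assert net.input_arity == 1 and len(net.centers) == 11

    def test_refit_of_realizable_target_is_near_perfect(self, rng):
        """Noise-free target drawn from a random same-architecture subnet
        (random output weights on a basis the fitted family can place)."""
        X = rng.uniform(0, 1, (300, 2))
        proto = fit_rbf_subnet(X, X[:, 0], seed=11)
        truth = RBFSubnet(
            input_arity=2,
            centers=proto.centers,
            widths=proto.widths,
            weights=rng.normal(0, 1, len(proto.centers)),
            bias=0.1, ridge=0.0, r_tr=0.0, r_te=0.0,
        )
        y = truth.predict(X)
        refit = fit_rbf_subnet(X, y, seed=2)
        assert refit.r_tr >= 0.999

    def test_constant_target_reports_zero_correlation_with_warning(self, rng):
        X = rng.uniform(0, 1, (60, 1))
        with pytest.warns(UserWarning, match="constant"):
            net = fit_rbf_subnet(X, np.full(60, 0.5), seed=0)
        assert net.r_tr == 0.0

    def test_hidden_layer_shrinks_on_tiny_data(self, rng):
        X = rng.uniform(0, 1, (16, 1))
        y = X.ravel()
        with pytest.warns(UserWarning, match="shrinking"):
            net = fit_rbf_subnet(X, y, seed=0)
        assert len(net.centers) == 4  # floor(8 training points / 2)

    def test_widths_positive(self, rng):
        X = rng.uniform(0, 1, (100, 2))
        net = fit_rbf_subnet(X, X.sum(axis=1) / 2, seed=3)
        assert np.all(net.widths > 0)


def _informative_cohort(n, seed, extra=None):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 16, size=n)
    meis = {"GOOD": counts + rng.normal(0, 4, n)}
    if extra:
        meis.update(extra(rng, counts))
    return cohort_with_counts(counts, meis=meis)


class TestBuildCascade:
    def test_exact_duplicate_of_seed_mei_is_rejected(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 16, size=400)
        good = counts + rng.normal(0, 4, 400)
        cohort = cohort_with_counts(counts, meis={"GOOD": good, "COPY": good.copy()})
        model = build_cascade(cohort, seed=1)
        assert model.used_meis == ["GOOD"]
        assert [n for n, _ in model.rejected] == ["COPY"]
        assert model.steps[0].subnet.input_arity == 1

    def test_complementary_mei_is_accepted_into_first_step(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 16, size=600)
        a = counts + rng.normal(0, 5, 600)
        b = counts + rng.normal(0, 5, 600)
        cohort = cohort_with_counts(counts, meis={"A": a, "B": b})
        model = build_cascade(cohort, seed=2)
        assert sorted(model.used_meis) == ["A", "B"]
        assert model.steps[0].subnet.input_arity == 2

    def test_accepted_steps_strictly_increase_rho(self):
        cohort, _ = generate_cohort(default_config(n_patients=1000, seed=21))
        model = build_cascade(cohort, ordered_meis=["CA125", "PLT", "NEUT_pct", "PA"], seed=3)
        rhos = [step.rho_after for step in model.steps]
        assert all(b > a + 0.005 for a, b in zip(rhos, rhos[1:]))
        assert model.rho_train == pytest.approx(rhos[-1])

    def test_serialization_round_trip_preserves_predictions(self):
        cohort, _ = generate_cohort(default_config(n_patients=300, seed=8))
        model = build_cascade(cohort, ordered_meis=["CA125", "PLT"], seed=4)
        back = model_from_dict(model_to_dict(model))
        a = cascade_predict_cohort(model, cohort)
        b = cascade_predict_cohort(back, cohort)
        assert np.allclose(a, b, atol=0)


class TestCascadePredict:
    def _model(self):
        cohort, _ = generate_cohort(default_config(n_patients=300, seed=5))
        return cohort, build_cascade(cohort, ordered_meis=["CA125", "PLT"], seed=5)

    def test_batch_equals_record_by_record(self):
        cohort, model = self._model()
        batch = cascade_predict_cohort(model, cohort)
        singles = [cascade_predict(model, r) for r in cohort.records[:20]]
        assert np.allclose(batch[:20], singles)

    def test_output_in_unit_interval(self):
        cohort, model = self._model()
        out = cascade_predict_cohort(model, cohort)
        assert np.all((out >= 0) & (out <= 1))

    def test_prediction_ignores_unused_meis(self):
        cohort, model = self._model()
        record = cohort.records[0]
        before = cascade_predict(model, record)
        record.mei_values["TT"] = 999.0
        assert cascade_predict(model, record) == before

    def test_missing_required_mei_named_in_error(self):
        cohort, model = self._model()
        record = cohort.records[0]
        record.mei_values["CA125"] = None
        with pytest.raises(ValueError, match="CA125"):
            cascade_predict(model, record)

    def test_zero_weight_model_predicts_zero(self):
        cohort, model = self._model()
        for step in model.steps:
            step.subnet.weights = np.zeros_like(step.subnet.weights)
            step.subnet.bias = 0.0
        out = cascade_predict_cohort(model, cohort)
        assert np.all(out == 0.0)


class TestKFoldCV:
    def test_fold_sizes_partition_534_into_10(self):
        cohort, _ = generate_cohort(default_config(n_patients=534, seed=6))
        report = kfold_cv(cohort, k=10, seed=1, ordered_meis=["CA125"])
        assert sorted(report.fold_sizes)[0] >= 53
        assert set(report.fold_sizes) <= {53, 54}
        assert sum(report.fold_sizes) == 534

    def test_perfectly_informative_mei_gives_near_unit_pooled_rho(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 16, size=300)
        cohort = cohort_with_counts(counts, meis={"MIRROR": counts.astype(float)})
        report = kfold_cv(cohort, k=10, seed=3, ordered_meis=["MIRROR"])
        assert report.pooled_rho >= 0.99

    def test_every_record_predicted_once(self):
        cohort, _ = generate_cohort(default_config(n_patients=120, seed=7))
        report = kfold_cv(cohort, k=10, seed=2, ordered_meis=["CA125"])
        assert np.all(np.isfinite(report.predictions))

    def test_too_few_records_rejected(self):
        cohort, _ = generate_cohort(default_config(n_patients=15, seed=7))
        with pytest.raises(ValueError):
            kfold_cv(cohort, k=10, seed=0)
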