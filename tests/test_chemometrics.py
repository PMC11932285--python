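"""Chemometric core: autoscaling, PCA, NIPALS PLS-DA, repeated double
cross-validation and sign-stability selection."""

import numpy as np
import pandas as pd
import pytest

from urinmr import (
    DcvConfig,
    DcvResult,
    SimulationConfig,
    autoscale,
    classify,
    double_cross_validate,
    figures_of_merit,
    pca,
    pls_da_fit,
    select_significant_variables,
    simulate_concentrations,
)
from urinmr.chemometrics import FoldRecord


def random_two_class(rng, n=10, p=5):
    X = rng.standard_normal((n, p))
    y = np.ones(n)
    y[: n // 2] = -1
    return X, y


class TestAutoscale:
    def test_fit_gives_zero_mean_unit_sd(self):
        X = np.random.default_rng(0).gamma(2.0, size=(30, 8))
        sc = autoscale(X)
        assert np.abs(sc.X.mean(axis=0)).max() < 1e-10
        assert np.abs(sc.X.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_constant_column_error_names_column(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            autoscale(X)

    def test_transform_with_own_stats_is_idempotent(self):
        X = np.random.default_rng(1).standard_normal((12, 4))
        fit = autoscale(X)
        applied = autoscale(X, fit.column_means, fit.column_sds)
        np.testing.assert_allclose(applied.X, fit.X, atol=1e-12)

    def test_transform_mode_applies_reference_stats_unchanged(self):
        rng = np.random.default_rng(2)
        train, test = rng.standard_normal((10, 3)), rng.standard_normal((4, 3))
        fit = autoscale(train)
        out = autoscale(test, fit.column_means, fit.column_sds)
        np.testing.assert_allclose(
            out.X, (test - fit.column_means) / fit.column_sds)


class TestPca:
    def test_explained_variance_fractions_sum_to_one(self):
        X = autoscale(np.random.default_rng(3).standard_normal((20, 6))).X
        res = pca(X)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert res.explained_variance_ratio.shape == (min(19, 6),)

    def test_scores_equal_projection_on_loadings(self):
        X = autoscale(np.random.default_rng(4).standard_normal((15, 5))).X
        res = pca(X)
        np.testing.assert_allclose(res.scores, X @ res.loadings, atol=1e-10)

    def test_matches_svd_oracle_up_to_sign(self):
        X = autoscale(np.random.default_rng(5).standard_normal((12, 7))).X
        res = pca(X)
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        for k in range(res.loadings.shape[1]):
            dot = abs(res.loadings[:, k] @ Vt[k])
            assert dot == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(
            np.abs(res.scores), np.abs(_ := (X @ Vt.T)[:, :res.scores.shape[1]]),
            atol=1e-8)

    def test_rank_one_data_first_component_explains_all(self):
        u = np.arange(1, 9, dtype=float)[:, None]
        v = np.array([[1.0, -2.0, 0.5]])
        res = pca(u @ v - (u @ v).mean(axis=0))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)


class TestPlsDaFit:
    def test_first_weight_vector_proportional_to_xty(self):
        rng = np.random.default_rng(6)
        X, y = random_two_class(rng, 14, 6)
        Xs = autoscale(X).X
        model = pls_da_fit(Xs, y, 3)
        w_direct = Xs.T @ (y - y.mean())
        w_direct /= np.linalg.norm(w_direct)
        assert abs(model.weights[:, 0] @ w_direct) == pytest.approx(1.0, abs=1e-10)

    def test_signal_column_dominates_weights(self):
        rng = np.random.default_rng(7)
        X, y = random_two_class(rng, 20, 6)
        X[:, 2] = y + 0.01 * rng.standard_normal(20)
        model = pls_da_fit(autoscale(X).X, y, 1)
        assert np.argmax(np.abs(model.weights[:, 0])) == 2

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(8)
        X, y = random_two_class(rng, 16, 8)
        model = pls_da_fit(autoscale(X).X, y, 4)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_full_complexity_reproduces_least_squares(self):
        rng = np.random.default_rng(9)
        X, y = random_two_class(rng, 12, 5)
        Xs = autoscale(X).X
        model = pls_da_fit(Xs, y, 5)
        beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(12), Xs]), y,
                                   rcond=None)
        np.testing.assert_allclose(model.predict_continuous(Xs),
                                   np.column_stack([np.ones(12), Xs]) @ beta,
                                   atol=1e-8)

    def test_single_class_rejected(self):
        X = np.random.default_rng(10).standard_normal((8, 3))
        with pytest.raises(ValueError, match="both classes"):
            pls_da_fit(X, np.ones(8), 1)

    def test_excessive_n_lv_rejected(self):
        rng = np.random.default_rng(11)
        X, y = random_two_class(rng, 6, 3)
        with pytest.raises(ValueError, match="n_lv"):
            pls_da_fit(autoscale(X).X, y, 4)

    def test_cv1_oriented_toward_exposed_centroid(self):
        rng = np.random.default_rng(12)
        X, y = random_two_class(rng, 20, 5)
        X[y > 0] += 2.0
        Xs = autoscale(X).X
        model = pls_da_fit(Xs, y, 2)
        gap = (Xs[y > 0].mean(axis=0) - Xs[y < 0].mean(axis=0)) @ model.cv1_weights
        assert gap > 0


class TestClassify:
    def test_separated_clusters_classified_perfectly(self):
        rng = np.random.default_rng(13)
        X, y = random_two_class(rng, 20, 5)
        X[y > 0] += 10.0
        Xs = autoscale(X).X
        model = pls_da_fit(Xs, y, 2)
        np.testing.assert_array_equal(classify(model, Xs), y)

    def test_tie_goes_to_positive_class(self):
        rng = np.random.default_rng(14)
        X, y = random_two_class(rng, 10, 4)
        Xs = autoscale(X).X
        model = pls_da_fit(Xs, y, 1)
        # craft a row whose continuous prediction lands exactly on threshold
        x_tie = np.zeros(4)
        model.y_mean = 0.0
        assert classify(model, x_tie[None, :])[0] == 1.0

    def test_column_mismatch_rejected(self):
        rng = np.random.default_rng(15)
        X, y = random_two_class(rng, 10, 4)
        model = pls_da_fit(autoscale(X).X, y, 1)
        with pytest.raises(ValueError, match="columns"):
            classify(model, np.zeros((2, 5)))


class TestFiguresOfMerit:
    def test_hand_computed_confusion_arithmetic(self):
        fom = figures_of_merit(tp=10, tn=12, fp=1, fn=2)
        assert fom["sensitivity"] == pytest.approx(83.3, abs=0.05)
        assert fom["specificity"] == pytest.approx(92.3, abs=0.05)
        assert fom["accuracy"] == pytest.approx(88.0, abs=0.05)

    def test_accuracy_consistent_with_pooled_confusion(self, effect_dcv):
        c = effect_dcv.confusion
        total = sum(c.values())
        pooled_acc = 100.0 * (c["TP"] + c["TN"]) / total
        assert effect_dcv.per_repetition["accuracy"].mean() == pytest.approx(
            pooled_acc, abs=1e-9)


class TestDoubleCrossValidation:
    def test_widely_separated_groups_classified_perfectly(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((25, 5))
        y = np.concatenate([np.ones(12), -np.ones(13)])
        X[y > 0] += 10.0   # 10 pooled sds apart
        res = double_cross_validate(X, y, DcvConfig(seed=0, n_repetitions=5))
        assert res.summary()["accuracy"]["mean"] == 100.0

    def test_permuted_labels_give_chance_level_accuracy(self):
        m = simulate_concentrations(SimulationConfig(seed=301, effects=[]))
        res = double_cross_validate(m.values, m.class_codes(), DcvConfig(seed=1))
        assert 35.0 <= res.summary()["accuracy"]["mean"] <= 65.0

    def test_bit_identical_rerun_under_fixed_seed(self):
        m = simulate_concentrations(SimulationConfig(seed=5, effects=[]))
        cfg = DcvConfig(seed=99, n_repetitions=3)
        a = double_cross_validate(m.values, m.class_codes(), cfg)
        b = double_cross_validate(m.values, m.class_codes(), cfg)
        pd.testing.assert_frame_equal(a.per_repetition, b.per_repetition)
        np.testing.assert_array_equal(a.cv1_weight_samples, b.cv1_weight_samples)
        np.testing.assert_array_equal(a.chosen_n_lv, b.chosen_n_lv)

    def test_held_out_subjects_never_influence_their_fold_model(self):
        """Leakage audit: perturbing a subject's data must not change the
        scaling statistics or latent-variable choice of any model that
        holds that subject out."""
        m = simulate_concentrations(SimulationConfig(seed=6, effects=[]))
        X = m.values.to_numpy().copy()
        y = m.class_codes()
        cfg = DcvConfig(seed=3, n_repetitions=3)
        ref = double_cross_validate(X, y, cfg)
        subject = 7
        X2 = X.copy()
        X2[subject] *= 13.7   # gross perturbation
        alt = double_cross_validate(X2, y, cfg)
        audited = 0
        for r_ref, r_alt in zip(ref.fold_records, alt.fold_records):
            if subject in r_ref.test_indices:
                np.testing.assert_array_equal(r_ref.test_indices,
                                              r_alt.test_indices)
                np.testing.assert_array_equal(r_ref.scaler_means,
                                              r_alt.scaler_means)
                np.testing.assert_array_equal(r_ref.scaler_sds,
                                              r_alt.scaler_sds)
                assert r_ref.chosen_n_lv == r_alt.chosen_n_lv
                audited += 1
        assert audited == cfg.n_repetitions   # subject held out once per rep

    def test_class_smaller_than_outer_folds_rejected(self):
        X = np.random.default_rng(17).standard_normal((7, 3))
        y = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0, -1.0])
        with pytest.raises(ValueError, match="outer_folds"):
            double_cross_validate(X, y, DcvConfig(seed=0, outer_folds=5))


class TestSelection:
    @staticmethod
    def _result_from_samples(samples, names):
        return DcvResult(per_repetition=pd.DataFrame(), chosen_n_lv=np.zeros((1, 1)),
                         cv1_weight_samples=samples, confusion={},
                         fold_records=[], variable_names=names)

    def test_consistently_positive_variable_selected(self):
        rng = np.random.default_rng(18)
        samples = np.column_stack([
            rng.uniform(0.4, 0.6, 100),           # stable positive
            rng.normal(0.0, 0.1, 100),            # symmetric around zero
        ])
        rep = select_significant_variables(
            self._result_from_samples(samples, ["stable", "noise"]))
        assert rep.table.loc["stable", "selected"]
        assert rep.table.loc["stable", "group"] == "Exposed"
        assert not rep.table.loc["noise", "selected"]

    def test_single_sign_flip_blocks_selection(self):
        samples = np.full((50, 1), 0.5)
        samples[13, 0] = -1e-4
        rep = select_significant_variables(
            self._result_from_samples(samples, ["almost"]))
        assert not rep.table.loc["almost", "selected"]
        assert rep.table.loc["almost", "sign_consistency"] == pytest.approx(0.98)

    def test_injected_effects_recovered_with_correct_direction(
            self, effect_matrix, effect_dcv):
        from urinmr import CTRL_SIGNIFICANT, EXPOSED_SIGNIFICANT
        rep = select_significant_variables(effect_dcv)
        sel = rep.table[rep.table.selected]
        recovered = set(sel.index) & (set(CTRL_SIGNIFICANT) | set(EXPOSED_SIGNIFICANT))
        assert len(recovered) >= 0.8 * 28
        for name in recovered:
            expected = "CTRL" if name in CTRL_SIGNIFICANT else "Exposed"
            assert sel.loc[name, "group"] == expected

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="2 weight samples"):
            select_significant_variables(
                self._result_from_samples(np.zeros((1, 3)), ["a", "b", "c"]))
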