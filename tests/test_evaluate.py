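import numpy as np
import pandas as pd
import pytest

from scarscreen import (
    auc_ci,
    cross_validate,
    delong_test,
    evaluate_panels,
    fit_logistic,
    normalize,
    roc_auc,
)
from scarscreen.evaluate import delong_variance

from _oracles import auc_pair_counting


def scores_labels(rng, m=80, n=120, shift=1.0):
    scores = np.concatenate([rng.normal(shift, 1, m), rng.normal(0, 1, n)])
    labels = np.array(["pathological"] * m + ["normal"] * n)
    return scores, labels


class TestNormalize:
    def test_min_max_arithmetic(self):
        out = normalize(pd.DataFrame({"m": [2.0, 4.0, 6.0]}))
        assert list(out["m"]) == [0.0, 0.5, 1.0]

    def test_idempotent_on_unit_interval(self):
        df = pd.DataFrame({"m": [0.0, 0.25, 1.0]})
        assert normalize(df).equals(normalize(normalize(df)))

    def test_constant_marker_named_in_error(self):
        with pytest.raises(ValueError, match="flat"):
            normalize(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))

    def test_probabilities_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a", "b"])
        y = np.where(
            rng.random(400) < 1 / (1 + np.exp(-(X["a"] - X["b"]))), "pathological", "normal"
        )
        fit_raw = fit_logistic(X, y)
        fit_scaled = fit_logistic(X * [10.0, 0.2] + [5.0, -3.0], y)
        assert np.max(np.abs(fit_raw.probabilities - fit_scaled.probabilities)) < 1e-8


class TestFitLogistic:
    def test_contingency_closed_form(self):
        # x=0: 10 events / 90 non-events; x=1: 40 / 60
        x = np.concatenate([np.zeros(100), np.ones(100)])
        y = np.array(
            ["pathological"] * 10 + ["normal"] * 90
            + ["pathological"] * 40 + ["normal"] * 60
        )
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.intercept == pytest.approx(np.log(10 / 90), abs=1e-6)
        assert fit.coefficients["x"] == pytest.approx(np.log(6), abs=1e-6)
        assert fit.odds_ratios["x"] == pytest.approx(6.0, rel=1e-6)

    def test_null_slope_within_three_se(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"x": rng.normal(size=4000)})
        y = np.where(rng.random(4000) < 0.3, "pathological", "normal")
        fit = fit_logistic(X, y)
        # SE of the slope under the null is ~ 1/sqrt(n p (1-p) var(x))
        se = 1.0 / np.sqrt(4000 * 0.3 * 0.7)
        assert abs(fit.coefficients["x"]) < 3 * se

    def test_single_class_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError, match="class"):
            fit_logistic(X, np.array(["normal"] * 10))

    def test_complete_separation_flagged(self):
        X = pd.DataFrame({"x": np.concatenate([np.zeros(20), np.ones(20)])})
        y = np.array(["normal"] * 20 + ["pathological"] * 20)
        fit = fit_logistic(X, y)
        assert fit.separation_flag

    def test_deviance_decreases_with_nesting(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
        y = np.where(
            rng.random(500) < 1 / (1 + np.exp(-(0.8 * X["a"] + 0.3 * X["b"]))),
            "pathological", "normal",
        )
        assert (
            fit_logistic(X[["a", "b"]], y).deviance
            <= fit_logistic(X[["a"]], y).deviance + 1e-9
        )


class TestRocAuc:
    def test_worked_pair_counting_example(self):
        scores = np.array([0.9, 0.4, 0.8, 0.2])
        labels = np.array(["pathological", "pathological", "normal", "normal"])
        _, _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.75)

    def test_perfect_separation_and_all_ties(self):
        labels = np.array(["pathological"] * 3 + ["normal"] * 3)
        assert roc_auc(np.array([3, 2.5, 2, 1, 0.5, 0]), labels)[2] == 1.0
        assert roc_auc(np.ones(6), labels)[2] == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            m, n = rng.integers(2, 30, 2)
            # discretized scores force ties to exercise the midrank path
            pos = rng.integers(0, 6, m).astype(float)
            neg = rng.integers(0, 6, n).astype(float)
            scores = np.concatenate([pos, neg])
            labels = np.array(["pathological"] * m + ["normal"] * n)
            _, _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_pair_counting(pos, neg), abs=1e-12)

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores, labels = scores_labels(rng)
        _, _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(
            roc_auc_score((labels == "pathological").astype(int), scores), abs=1e-12
        )

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        scores, labels = scores_labels(rng)
        _, _, auc = roc_auc(scores, labels)
        for f in (np.exp, lambda s: s**3 + 5 * s, lambda s: 1 / (1 + np.exp(-s))):
            assert roc_auc(f(scores), labels)[2] == pytest.approx(auc, abs=1e-12)

    def test_roc_curve_endpoints_monotone(self):
        rng = np.random.default_rng(11)
        scores, labels = scores_labels(rng)
        fpr, tpr, _ = roc_auc(scores, labels)
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.array(["normal"] * 4))


class TestAucCi:
    def test_perfect_separation_degenerate(self):
        labels = np.array(["pathological"] * 4 + ["normal"] * 4)
        auc, ci, degenerate = auc_ci(np.array([4, 3, 2.5, 2, 1, 0.8, 0.2, 0]), labels)
        assert auc == 1.0 and ci == (1.0, 1.0) and degenerate

    def test_interval_brackets_auc(self):
        rng = np.random.default_rng(13)
        scores, labels = scores_labels(rng, m=150, n=150)
        auc, (lo, hi), _ = auc_ci(scores, labels)
        assert 0.0 <= lo <= auc <= hi <= 1.0

    def test_delong_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(14)
        scores, labels = scores_labels(rng, m=200, n=200, shift=0.8)
        _, var = delong_variance(scores, labels)
        y01 = labels == "pathological"
        pos, neg = scores[y01], scores[~y01]
        boots = np.empty(2000)
        for b in range(2000):
            bp = rng.choice(pos, pos.size)
            bn = rng.choice(neg, neg.size)
            boots[b] = auc_pair_counting(bp, bn)
        assert var == pytest.approx(boots.var(ddof=1), rel=0.15)


class TestDeLongTest:
    def test_self_comparison_gives_p_one(self):
        rng = np.random.default_rng(15)
        scores, labels = scores_labels(rng)
        cmp_ = delong_test(scores, scores, labels)
        assert cmp_.diff == 0.0 and cmp_.p == 1.0 and cmp_.degenerate

    def test_antisymmetry_in_panel_order(self):
        rng = np.random.default_rng(16)
        scores_a, labels = scores_labels(rng)
        scores_b = scores_a + rng.normal(0, 0.8, scores_a.size)
        ab = delong_test(scores_a, scores_b, labels)
        ba = delong_test(scores_b, scores_a, labels)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p == pytest.approx(ba.p)

    def test_length_mismatch_rejected(self):
        labels = np.array(["pathological", "normal"])
        with pytest.raises(ValueError):
            delong_test(np.zeros(2), np.zeros(3), labels)


class TestCrossValidate:
    def _data(self, n=100, seed=17):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = np.where(
            rng.random(n) < 1 / (1 + np.exp(-2 * X["x"])), "pathological", "normal"
        )
        return X, y

    def test_every_sample_scored_once(self):
        X, y = self._data()
        result = cross_validate(X, y, k=10, seed=1)
        assert result.cross_validated
        assert len(result.fpr) >= 2 and 0.0 <= result.auc <= 1.0

    def test_seeded_determinism(self):
        X, y = self._data()
        a = cross_validate(X, y, k=10, seed=5)
        b = cross_validate(X, y, k=10, seed=5)
        assert a.auc == b.auc

    def test_rare_class_rejected_with_minimum(self):
        X = pd.DataFrame({"x": np.arange(30.0)})
        y = np.array(["pathological"] * 3 + ["normal"] * 27)
        with pytest.raises(ValueError, match="at least"):
            cross_validate(X, y, k=10, seed=0)


class TestEvaluatePanels:
    @pytest.fixture(scope="class")
    def panel_inputs(self):
        rng = np.random.default_rng(18)
        n = 600
        latent = rng.normal(size=n)
        table = pd.DataFrame({"draw_id": np.arange(n)})
        for day, gain in ((14, 0.8), (21, 1.6)):
            for mk, w in (("I10", 0.4), ("T1", 0.8), ("FN", 1.0)):
                table[f"{mk}_d{day}"] = np.exp(
                    gain * w * latent + rng.normal(0, 1, n)
                )
        labels = pd.DataFrame(
            {
                "draw_id": np.arange(n),
                "binary": np.where(latent + rng.normal(0, 0.7, n) > 0.8,
                                   "pathological", "normal"),
            }
        )
        return table, labels

    def test_panel_and_comparison_counts(self, panel_inputs):
        table, labels = panel_inputs
        evals = evaluate_panels(table, labels, days=(14, 21), seed=2)
        for day in (14, 21):
            assert len(evals[day].panels) == 7
            assert len(evals[day].comparisons) == 21
            assert evals[day].cv.cross_validated

    def test_triple_deviance_nested_below_subpanels(self, panel_inputs):
        table, labels = panel_inputs
        evals = evaluate_panels(table, labels, days=(21,), seed=2)
        triple = evals[21].panel("I10", "T1", "FN")
        for p in evals[21].panels:
            if p.panel != triple.panel:
                assert triple.deviance <= p.deviance + 1e-9
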