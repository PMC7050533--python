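"""Phenotype-stage training, mean-field prediction and the exact
exponential-time marginalization oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

import targetdecon as td
from targetdecon._glm import fit_logistic


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, float)))


def make_phenotype_model(v, c, reg="l2"):
    v = np.asarray(v, float)
    lm = td.LogisticModel(
        weights=v,
        bias=float(c),
        reg_type=reg,
        penalty_C=1.0,
        feature_order=[f"P{k}" for k in range(len(v))],
    )
    return td.PhenotypeModel(model=lm, phenotype_id="AID0")


def exact_by_itertools(v, c, marginals):
    """Independent enumeration oracle over all binary target states."""
    v = np.asarray(v, float)
    total = 0.0
    for t in itertools.product([0, 1], repeat=len(v)):
        t = np.asarray(t)
        w = np.prod([m if b else 1 - m for m, b in zip(marginals, t)])
        total += w * float(sigmoid(v @ t + c))
    return total


def profiles_from(values, mode="predicted_prob"):
    values = np.asarray(values, float)
    n, K = values.shape
    return td.TargetProfileSet(
        compound_ids=[f"c{i}" for i in range(n)],
        protein_ids=[f"P{k}" for k in range(K)],
        values=values,
        mode=mode,
    )


def phenotype_table(labels, phenotype_id="AID0"):
    return td.PhenotypeTable(
        pd.DataFrame(
            dict(
                compound_id=[f"c{i}" for i in range(len(labels))],
                phenotype_id=phenotype_id,
                label=np.asarray(labels, int),
            )
        )
    )


class TestTrainCpaModel:
    def test_planted_single_cause_gets_largest_positive_weight(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            vals = rng.integers(0, 2, size=(200, 6)).astype(float)
            labels = vals[:, 3].astype(int)  # phenotype equals coordinate 3
            profs = profiles_from(vals, mode="binary_known")
            cfg = td.TrainingConfig(reg_type="l1", seed=seed, standardize=False)
            pm, _ = td.train_cpa_model(profs, phenotype_table(labels), "AID0", cfg)
            assert int(np.argmax(pm.weights)) == 3
            assert pm.weights[3] > 0

    def test_labels_independent_of_profiles_score_near_chance(self):
        rng = np.random.default_rng(11)
        vals = rng.random((500, 5))
        labels = rng.integers(0, 2, 500)
        profs = profiles_from(vals)
        pm, report = td.train_cpa_model(profs, phenotype_table(labels), "AID0")
        assert report.loc[report["selected"], "cv_auc"].iloc[0] == pytest.approx(
            0.5, abs=0.1
        )

    def test_duplicating_rows_with_halved_c_leaves_fit_unchanged(self):
        """liblinear objective: penalty + C * sum of losses, so doubling
        every row while halving C reproduces the same optimum."""
        rng = np.random.default_rng(5)
        X = rng.random((120, 4))
        y = (rng.random(120) < sigmoid(3 * X[:, 0] - 1.5)).astype(int)
        names = [f"P{k}" for k in range(4)]
        cfg = td.TrainingConfig(reg_type="l2", standardize=False, tol=1e-12, seed=0)
        m1 = fit_logistic(X, y, names, C=1.0, config=cfg)
        m2 = fit_logistic(
            np.vstack([X, X]), np.concatenate([y, y]), names, C=0.5, config=cfg
        )
        np.testing.assert_allclose(m2.weights, m1.weights, atol=1e-8, rtol=0)
        assert m2.bias == pytest.approx(m1.bias, abs=1e-8)

    def test_single_class_phenotype_is_an_error(self):
        vals = np.random.default_rng(0).random((20, 3))
        with pytest.raises(ValueError, match="single class"):
            td.train_cpa_model(profiles_from(vals), phenotype_table([1] * 20), "AID0")


class TestPredictionTable:
    def test_long_table_matches_direct_meanfield_scores(self, rng):
        vals = rng.random((15, 4))
        profs = profiles_from(vals)
        models = [make_phenotype_model(rng.standard_normal(4), 0.1) for _ in range(2)]
        models[1].phenotype_id = "AID1"
        table = td.phenotype_prediction_table(models, profs)
        assert len(table) == 30
        for pm in models:
            sub = table[table["phenotype_id"] == pm.phenotype_id]
            expected = td.predict_phenotype_meanfield(pm, profs)
            np.testing.assert_array_equal(sub["score"].to_numpy(), expected)


class TestMeanField:
    def test_zero_model_gives_half(self):
        pm = make_phenotype_model([0.0, 0.0], 0.0)
        assert td.predict_phenotype_meanfield(pm, [0.3, 0.9]) == 0.5

    def test_degenerate_profile_direct_value(self):
        pm = make_phenotype_model([2.0, -1.0], 0.0)
        p = td.predict_phenotype_meanfield(pm, [1.0, 0.0])
        assert p == pytest.approx(float(sigmoid(2.0)), abs=1e-12)
        assert p == pytest.approx(0.8807970779778823, abs=1e-12)

    def test_strictly_increasing_in_positive_weight_coordinate(self, rng):
        pm = make_phenotype_model([1.5, -0.5, 0.7], 0.1)
        for _ in range(100):
            t = rng.random(3)
            lo = td.predict_phenotype_meanfield(pm, t)
            t2 = t.copy()
            t2[0] = min(1.0, t2[0] + rng.random() * (1 - t2[0]) + 1e-9)
            hi = td.predict_phenotype_meanfield(pm, t2)
            assert hi > lo

    def test_misaligned_profile_is_an_error(self):
        pm = make_phenotype_model([1.0, 1.0], 0.0)
        with pytest.raises(ValueError, match="coordinates"):
            td.predict_phenotype_meanfield(pm, [0.1, 0.2, 0.3])


class TestExactMarginalization:
    def test_degenerate_marginals_collapse_to_mean_field(self, rng):
        for _ in range(200):
            K = int(rng.integers(1, 11))
            pm = make_phenotype_model(rng.standard_normal(K) * 3, rng.standard_normal())
            m = rng.integers(0, 2, K).astype(float)
            exact = td.predict_phenotype_exact(pm, m)
            mf = td.predict_phenotype_meanfield(pm, m)
            assert exact == pytest.approx(mf, abs=1e-12)

    def test_k1_half_marginal_shows_approximation_gap(self):
        pm = make_phenotype_model([10.0], 0.0)
        exact = td.predict_phenotype_exact(pm, [0.5])
        mf = td.predict_phenotype_meanfield(pm, [0.5])
        # exact: 0.5*sigma(10) + 0.5*sigma(0); mean-field: sigma(5)
        assert exact == pytest.approx(0.5 * float(sigmoid(10)) + 0.25, abs=1e-12)
        assert exact == pytest.approx(0.7499773010656488, abs=1e-9)
        assert mf == pytest.approx(0.9933071490757153, abs=1e-9)
        assert abs(exact - mf) > 0.2

    def test_weight_free_limit(self, rng):
        pm = make_phenotype_model([0.0, 0.0, 0.0], 0.7)
        m = rng.random(3)
        assert td.predict_phenotype_exact(pm, m) == pytest.approx(
            float(sigmoid(0.7)), abs=1e-12
        )
        assert td.predict_phenotype_meanfield(pm, m) == pytest.approx(
            float(sigmoid(0.7)), abs=1e-12
        )

    def test_matches_independent_enumeration(self, rng):
        for _ in range(50):
            K = int(rng.integers(1, 9))
            v = rng.standard_normal(K) * 2
            c = float(rng.standard_normal())
            m = rng.random(K)
            pm = make_phenotype_model(v, c)
            assert td.predict_phenotype_exact(pm, m) == pytest.approx(
                exact_by_itertools(v, c, m), abs=1e-12
            )

    def test_output_is_convex_combination_of_sigmas(self, rng):
        for _ in range(30):
            K = int(rng.integers(1, 10))
            v = rng.standard_normal(K) * 3
            c = float(rng.standard_normal())
            m = rng.random(K)
            pm = make_phenotype_model(v, c)
            exact = td.predict_phenotype_exact(pm, m)
            sig_all = [
                float(sigmoid(np.asarray(t) @ v + c))
                for t in itertools.product([0, 1], repeat=K)
            ]
            assert min(sig_all) - 1e-12 <= exact <= max(sig_all) + 1e-12

    def test_near_linear_regime_closes_the_gap(self, rng):
        for _ in range(30):
            K = int(rng.integers(1, 10))
            v = rng.standard_normal(K) * 1e-6
            c = float(rng.standard_normal())
            m = rng.random(K)
            pm = make_phenotype_model(v, c)
            exact = td.predict_phenotype_exact(pm, m)
            mf = td.predict_phenotype_meanfield(pm, m)
            assert abs(exact - mf) <= 1e-9

    def test_k_over_cap_is_an_error(self, rng):
        pm = make_phenotype_model(rng.standard_normal(25), 0.0)
        with pytest.raises(ValueError, match="mean"):
            td.predict_phenotype_exact(pm, rng.random(25))
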