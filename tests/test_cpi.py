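"""Stage-1 interaction models, C-grid selection and target profiles."""

import numpy as np
import pandas as pd
import pytest

import targetdecon as td
from targetdecon._glm import fit_logistic


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def toy_family(rng, n_pairs=20, separable=True):
    """A one-family interaction problem separated along one compound feature."""
    comp_ids = [f"c{i}" for i in range(n_pairs)]
    x0 = np.concatenate([rng.uniform(1, 2, n_pairs // 2), rng.uniform(-2, -1, n_pairs // 2)])
    comp = td.DescriptorMatrix(
        entity_ids=comp_ids,
        feature_names=["f0", "f1"],
        values=np.column_stack([x0, rng.standard_normal(n_pairs)]),
    )
    prot = td.DescriptorMatrix(
        entity_ids=["p0"], feature_names=["g0"], values=rng.standard_normal((1, 1))
    )
    labels = (x0 > 0).astype(int)
    records = pd.DataFrame(
        dict(compound_id=comp_ids, protein_id="p0", label=labels)
    )
    return comp, prot, td.InteractionTable(records)


class TestTrainCpiModel:
    def test_separable_toy_reaches_auc_one(self, rng):
        comp, prot, inter = toy_family(rng)
        cfg = td.TrainingConfig(reg_type="l2", cv_folds=2, seed=0)
        model, report = td.train_cpi_model(inter, comp, prot, cfg)
        X = np.hstack([comp.values, np.tile(prot.values[0], (len(inter), 1))])
        scores = model.predict_proba(X)
        assert td.auc(scores, inter.records["label"]) == 1.0

    def test_cv_auc_ties_resolve_to_smallest_c(self, rng):
        # clean separation: several C values reach identical CV AUC
        comp, prot, inter = toy_family(rng, n_pairs=40)
        cfg = td.TrainingConfig(reg_type="l2", cv_folds=2, seed=0, c_grid=(1.0, 10.0, 100.0))
        model, report = td.train_cpi_model(inter, comp, prot, cfg)
        best = report.loc[report["selected"], "C"].iloc[0]
        tied = report[report["cv_auc"] == report["cv_auc"].max()]["C"]
        assert best == tied.min()
        assert model.penalty_C == best

    def test_single_class_family_is_an_error(self, rng):
        comp, prot, inter = toy_family(rng)
        rec = inter.records.copy()
        rec["label"] = 1
        cfg = td.TrainingConfig()
        with pytest.raises(ValueError, match="single"):
            td.train_cpi_model(td.InteractionTable(rec), comp, prot, cfg)

    def test_l1_recovers_planted_weight_signs(self):
        """Data drawn from a sparse logistic truth: L1 refits recover the
        sign of every planted nonzero coefficient."""
        planted = np.zeros(10)
        planted[[0, 3, 7]] = [2.0, -2.0, 1.5]
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((2000, 10))
            y = (rng.random(2000) < sigmoid(X @ planted)).astype(int)
            cfg = td.TrainingConfig(reg_type="l1", seed=seed)
            model = fit_logistic(X, y, [f"f{i}" for i in range(10)], C=1.0, config=cfg)
            for idx in (0, 3, 7):
                assert np.sign(model.weights[idx]) == np.sign(planted[idx])


class TestPredictInteraction:
    def make_model(self, w, b):
        return td.LogisticModel(
            weights=np.asarray(w, float),
            bias=b,
            reg_type="l2",
            penalty_C=1.0,
            feature_order=[f"x{i}" for i in range(len(w))],
        )

    def test_zero_model_gives_half(self):
        m = self.make_model([0.0, 0.0, 0.0], 0.0)
        assert td.predict_interaction(m, [1.0, 2.0], [3.0]) == 0.5

    def test_unit_logit(self):
        m = self.make_model([1.0, 0.0], 0.0)
        p = td.predict_interaction(m, [1.0], [5.0])
        assert p == pytest.approx(0.7310585786300049, abs=1e-12)

    def test_monotone_in_positive_weight_coordinate(self, rng):
        m = self.make_model(rng.standard_normal(4), 0.3)
        m.weights[1] = abs(m.weights[1]) + 0.1
        for _ in range(100):
            c = rng.standard_normal(2)
            p = rng.standard_normal(2)
            lo = td.predict_interaction(m, c, p)
            c2 = c.copy()
            c2[1] += abs(rng.standard_normal())
            hi = td.predict_interaction(m, c2, p)
            assert hi >= lo

    def test_length_mismatch_is_an_error(self):
        m = self.make_model([1.0, 1.0], 0.0)
        with pytest.raises(ValueError, match="features"):
            td.predict_interaction(m, [1.0, 2.0], [3.0])


def tiny_panel(rng, K=6, with_desc=True):
    pids = [f"P{k}" for k in range(K)]
    fams = {p: td.io.PROTEIN_FAMILIES[k % 6] for k, p in enumerate(pids)}
    desc = td.DescriptorMatrix(
        entity_ids=pids,
        feature_names=["q0", "q1"],
        values=rng.standard_normal((K, 2)),
    ) if with_desc else None
    return td.ProteinPanel(protein_ids=pids, families=fams, descriptors=desc)


class TestTargetProfiles:
    def test_binary_known_places_actives(self, rng):
        panel = tiny_panel(rng, K=6, with_desc=False)
        known = td.InteractionTable(
            pd.DataFrame(
                dict(
                    compound_id=["c1", "c1"],
                    protein_id=["P1", "P4"],  # panel positions 2 and 5 (1-based)
                    label=[1, 1],
                )
            )
        )
        comp = td.DescriptorMatrix(["c1"], ["f0"], np.zeros((1, 1)))
        profs = td.build_target_profiles(None, panel, comp, known, "binary_known")
        np.testing.assert_array_equal(profs.profile("c1"), [0, 1, 0, 0, 1, 0])

    def _trained_setup(self, seed=3, n=10, K=8):
        rng = np.random.default_rng(seed)
        panel = tiny_panel(rng, K=K)
        comp = td.DescriptorMatrix(
            [f"c{i}" for i in range(n)], ["f0", "f1", "f2"], rng.standard_normal((n, 3))
        )
        pairs = [(c, p) for c in comp.entity_ids for p in panel.protein_ids]
        labels = rng.integers(0, 2, len(pairs))
        labels[: len(pairs) // 2] = rng.integers(0, 2, len(pairs) // 2)
        inter = td.InteractionTable(
            pd.DataFrame(
                dict(
                    compound_id=[c for c, _ in pairs],
                    protein_id=[p for _, p in pairs],
                    label=labels,
                )
            )
        )
        # measured subset: first 60% of pairs
        cut = int(0.6 * len(pairs))
        known = td.InteractionTable(inter.records.iloc[:cut].reset_index(drop=True))
        cfg = td.TrainingConfig(cv_folds=2, seed=seed, c_grid=(0.1, 1.0))
        models, _ = td.train_family_models(inter, panel, comp, panel.descriptors, cfg)
        return panel, comp, known, models

    def test_predicted_prob_bounded(self):
        panel, comp, known, models = self._trained_setup()
        profs = td.build_target_profiles(models, panel, comp, None, "predicted_prob")
        assert profs.values.min() > 0 and profs.values.max() < 1

    def test_predicted_binary_is_thresholded_probability(self):
        panel, comp, known, models = self._trained_setup()
        prob = td.build_target_profiles(models, panel, comp, None, "predicted_prob")
        binary = td.build_target_profiles(models, panel, comp, None, "predicted_binary")
        np.testing.assert_array_equal(binary.values, (prob.values > 0.5).astype(float))

    def test_hybrid_mixes_known_and_predicted_coordinatewise(self):
        panel, comp, known, models = self._trained_setup()
        hybrid = td.build_target_profiles(models, panel, comp, known, "hybrid")
        prob = td.build_target_profiles(models, panel, comp, None, "predicted_prob")
        measured = known.pair_labels()
        for i, c in enumerate(hybrid.compound_ids):
            for k, p in enumerate(hybrid.protein_ids):
                if (c, p) in measured:
                    assert hybrid.values[i, k] == float(measured[(c, p)])
                else:
                    assert hybrid.values[i, k] == prob.values[i, k]

    def test_permuting_panel_permutes_profile_coordinates(self):
        panel, comp, known, models = self._trained_setup()
        profs = td.build_target_profiles(models, panel, comp, None, "predicted_prob")
        perm = list(reversed(range(panel.size)))
        panel2 = td.ProteinPanel(
            protein_ids=[panel.protein_ids[k] for k in perm],
            families=panel.families,
            descriptors=panel.descriptors,
        )
        profs2 = td.build_target_profiles(models, panel2, comp, None, "predicted_prob")
        np.testing.assert_array_equal(profs2.values, profs.values[:, perm])

    def test_missing_descriptor_in_prediction_mode_is_an_error(self):
        panel, comp, known, models = self._trained_setup()
        with pytest.raises(KeyError, match="descriptor"):
            td.build_target_profiles(
                models, panel, comp, None, "predicted_prob",
                compound_ids=["c0", "zzz"],
            )

    def test_profile_round_trip(self, tmp_path):
        panel, comp, known, models = self._trained_setup()
        profs = td.build_target_profiles(models, panel, comp, known, "hybrid")
        td.write_profiles(profs, tmp_path / "profiles.tsv")
        back = td.read_profiles(tmp_path / "profiles.tsv")
        assert back.mode == "hybrid"
        assert back.protein_ids == profs.protein_ids
        np.testing.assert_allclose(back.values, profs.values, rtol=0, atol=1e-15)


class TestSparsity:
    def test_l1_no_denser_than_l2_at_same_c(self):
        """On a separable toy, the L1 fit should not have more nonzero
        weights than the L2 fit at the same C (aggregated over seeds)."""
        nnz_l1 = nnz_l2 = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((60, 8))
            y = (X[:, 0] > 0).astype(int)
            names = [f"f{i}" for i in range(8)]
            m1 = fit_logistic(X, y, names, 1.0, td.TrainingConfig(reg_type="l1", seed=seed))
            m2 = fit_logistic(X, y, names, 1.0, td.TrainingConfig(reg_type="l2", seed=seed))
            nnz_l1 += int((np.abs(m1.weights) > 1e-10).sum())
            nnz_l2 += int((np.abs(m2.weights) > 1e-10).sum())
        assert nnz_l1 <= nnz_l2
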