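"""Predictor forward pass, two-phase training, LM bank, and imputation."""

import numpy as np
import pytest

from bronte._nn import MLP
from bronte.embeddings import GeneEmbedding, TissueEmbeddingNet
from bronte.model import (BronteImputer, BronteModel, LinearTissueImputer,
                          aggregate_to_composites, fit_lm_bank, impute_profile,
                          predict_composite, predict_expression, train_bronte,
                          train_extended_bronte)
from bronte.ontology import subordinate_leaves
from bronte.preprocess import ExpressionTensor
from bronte.simdata import SimConfig, mask_tissues, simulate_expression

from conftest import MODEL_CONFIG


def toy_model(ontology, n_genes=4, dim_t=3, dim_g=4, seed=0, zero=False,
              n_slots=None):
    rng = np.random.default_rng(seed)
    n_slots = len(ontology.composite_ids) if n_slots is None else n_slots
    gcn = [rng.normal(size=(ontology.n_nodes, 8)), rng.normal(size=(8, dim_t))]
    dim_in = dim_t + dim_g + n_slots
    sizes = [dim_in, 6, 5, 1]
    w = [rng.normal(size=(sizes[i], sizes[i + 1])) for i in range(3)]
    b = [rng.normal(size=s) for s in sizes[1:]]
    if zero:
        w = [np.zeros_like(x) for x in w]
        b = [np.zeros_like(x) for x in b]
        gcn = [np.zeros_like(x) for x in gcn]
    emb = GeneEmbedding(rng.normal(size=(n_genes, dim_g)),
                        [f"g{i}" for i in range(n_genes)])
    return BronteModel(TissueEmbeddingNet(gcn), emb, MLP(w, b), ontology,
                       n_profile_slots=n_slots)


class TestForwardPass:
    def test_zero_weights_predict_zero(self, ontology):
        m = toy_model(ontology, zero=True)
        p = np.ones(len(ontology.composite_ids))
        assert predict_expression(m, p, "g0", ontology.leaf_ids[0]) == 0.0

    def test_matches_dense_oracle(self, ontology):
        m = toy_model(ontology, seed=3)
        profile = np.array([0.3, -1.2, 0.8, 0.0, 2.0, -0.5])
        leaf = ontology.leaf_ids[2]
        node_emb = m.node_embeddings()
        x = np.concatenate([node_emb[ontology.node_index(leaf)],
                            m.gene_embedding.matrix[1], profile])
        for w, b in zip(m.mlp.weights[:-1], m.mlp.biases[:-1]):
            x = np.maximum(x @ w + b, 0.0)
        expected = float((x @ m.mlp.weights[-1] + m.mlp.biases[-1])[0])
        got = predict_expression(m, profile, "g1", leaf)
        assert np.isclose(got, expected, atol=1e-6)

    def test_swapping_gene_rows_swaps_predictions(self, ontology):
        m = toy_model(ontology, seed=4)
        p = np.zeros(len(ontology.composite_ids))
        leaf = ontology.leaf_ids[0]
        a, b = (predict_expression(m, p, g, leaf) for g in ("g0", "g1"))
        m.gene_embedding.matrix[[0, 1]] = m.gene_embedding.matrix[[1, 0]]
        assert np.isclose(predict_expression(m, p, "g0", leaf), b)
        assert np.isclose(predict_expression(m, p, "g1", leaf), a)

    def test_input_validation(self, ontology):
        m = toy_model(ontology)
        p = np.zeros(len(ontology.composite_ids))
        with pytest.raises(KeyError):
            predict_expression(m, p, "ghost", ontology.leaf_ids[0])
        with pytest.raises(KeyError):
            predict_expression(m, p, "g0", "ghost")
        with pytest.raises(ValueError):
            predict_expression(m, p * np.nan, "g0", ontology.leaf_ids[0])


class TestCompositePrediction:
    def test_equals_mean_of_leaves(self, ontology):
        m = toy_model(ontology, seed=5)
        p = np.array([0.1, 0.2, -0.3, 1.0, 0.0, -1.0])
        for comp in ontology.composite_ids:
            leaves = subordinate_leaves(ontology, comp)
            expected = np.mean([predict_expression(m, p, "g2", l)
                                for l in leaves])
            assert np.isclose(predict_composite(m, p, "g2", comp), expected)

    def test_structural_identity_on_trained_model(self, base_model, ontology):
        p = np.linspace(-1, 1, len(ontology.composite_ids))
        comp = ontology.composite_ids[0]
        leaves = subordinate_leaves(ontology, comp)
        expected = np.mean([predict_expression(base_model, p, "g0", l)
                            for l in leaves])
        assert np.isclose(predict_composite(base_model, p, "g0", comp), expected)


class TestTraining:
    def test_phase1_loss_decreases(self, base_model):
        trace = base_model.loss_trace["atlas"]
        assert trace[-1] < 0.5 * trace[0]

    def test_constant_target_learned(self, ontology, gene_embedding):
        c = 1.7
        n_g = len(gene_embedding.gene_ids)
        atlas_vals = np.full((3, ontology.n_leaves, n_g), c)
        atlas = ExpressionTensor(atlas_vals, np.ones_like(atlas_vals, bool),
                                 ["a0", "a1", "a2"], list(ontology.leaf_ids),
                                 list(gene_embedding.gene_ids))
        cohort_vals = np.full((5, len(ontology.composite_ids), n_g), c)
        cohort = ExpressionTensor(cohort_vals, np.ones_like(cohort_vals, bool),
                                  [f"c{i}" for i in range(5)],
                                  ontology.composite_ids,
                                  list(gene_embedding.gene_ids))
        m = train_bronte(atlas, cohort, ontology, gene_embedding,
                         dict(MODEL_CONFIG, epochs_atlas=15, epochs_cohort=5),
                         seed=0)
        p = np.full(len(ontology.composite_ids), c)
        preds = [predict_expression(m, p, g, l)
                 for g in ["g0", "g50", "g150"] for l in ontology.leaf_ids[:3]]
        assert np.allclose(preds, c, atol=0.05)

    def test_same_seed_same_loss_trace(self, atlas_expr, cohort_data, ontology,
                                       gene_embedding):
        cfg = dict(MODEL_CONFIG, epochs_atlas=2, epochs_cohort=1)
        m1 = train_bronte(atlas_expr, cohort_data[1], ontology, gene_embedding,
                          cfg, seed=11)
        m2 = train_bronte(atlas_expr, cohort_data[1], ontology, gene_embedding,
                          cfg, seed=11)
        assert m1.loss_trace == m2.loss_trace
        assert all(np.array_equal(a, b) for a, b in
                   zip(m1.mlp.weights, m2.mlp.weights))

    def test_empty_training_set_rejected(self, ontology, gene_embedding,
                                         atlas_expr):
        empty = atlas_expr.subset_subjects([])
        with pytest.raises(ValueError):
            train_bronte(empty, empty, ontology, gene_embedding)

    def test_estimator_params_round_trip(self):
        est = BronteImputer(seed=5)
        est2 = BronteImputer().set_params(**est.get_params())
        assert est2.get_params() == est.get_params()


class TestExtendedModel:
    def test_profile_excludes_target_slot(self, extended_models, ontology):
        n_comp = len(ontology.composite_ids)
        for comp, m in extended_models.items():
            assert m.n_profile_slots == n_comp - 1
            assert comp not in m.profile_slot_ids
            assert m.profile_slot_ids == [c for c in ontology.composite_ids
                                          if c != comp]

    def test_nine_slots_with_ten_composites(self, big_ontology):
        """With a 10-composite atlas-scale ontology, the extended model's
        profile carries the 9 remaining composite tissues."""
        rng = np.random.default_rng(0)
        n_g = 5
        genes = [f"g{i}" for i in range(n_g)]
        av = rng.normal(size=(2, big_ontology.n_leaves, n_g))
        atlas = ExpressionTensor(av, np.ones_like(av, bool), ["a0", "a1"],
                                 list(big_ontology.leaf_ids), genes)
        cv = rng.normal(size=(13, 10, n_g))
        cohort = ExpressionTensor(cv, np.ones_like(cv, bool),
                                  [f"s{i}" for i in range(13)],
                                  big_ontology.composite_ids, genes)
        emb = GeneEmbedding(rng.normal(size=(n_g, 4)), genes)
        m = train_extended_bronte(
            "region0", atlas, cohort, big_ontology, emb,
            dict(gcn_sizes=(8, 4), mlp_hidden=(8, 8), epochs_atlas=1,
                 epochs_cohort=1), seed=0)
        assert m.n_profile_slots == 9

    def test_recovers_mean_structure(self, ontology, gene_embedding):
        """When the target composite equals the mean of the others, held-out
        predictions should rank subjects almost perfectly per gene."""
        from bronte.evaluation import per_gene_spearman
        rng = np.random.default_rng(1)
        n_g = len(gene_embedding.gene_ids)
        comps = ontology.composite_ids
        target = comps[0]
        t_leaves = subordinate_leaves(ontology, target)

        def build(n_subj, seed):
            r = np.random.default_rng(seed)
            vals = r.normal(size=(n_subj, ontology.n_leaves, n_g))
            leaf_idx = {l: i for i, l in enumerate(ontology.leaf_ids)}
            others = [l for c in comps[1:] for l in subordinate_leaves(ontology, c)]
            other_mean = vals[:, [leaf_idx[l] for l in others], :].mean(axis=1)
            for l in t_leaves:
                vals[:, leaf_idx[l], :] = other_mean
            return ExpressionTensor(vals, np.ones_like(vals, bool),
                                    [f"s{seed}_{i}" for i in range(n_subj)],
                                    list(ontology.leaf_ids),
                                    list(gene_embedding.gene_ids))

        atlas = build(4, 10)
        cohort = aggregate_to_composites(build(30, 11), ontology)
        held = aggregate_to_composites(build(20, 12), ontology)
        m = train_extended_bronte(target, atlas, cohort, ontology,
                                  gene_embedding, MODEL_CONFIG, seed=2)
        slot_cols = [held.tissue_ids.index(c) for c in m.profile_slot_ids]
        gi = {g: i for i, g in enumerate(m.gene_embedding.gene_ids)}
        node_emb = m.node_embeddings()
        preds = np.zeros((20, n_g))
        for s in range(20):
            prof = held.values[s][slot_cols, :].T
            rows = np.array([gi[g] for g in held.gene_ids])
            leaf_p = [m.predict_batch(prof, rows,
                                      np.full(n_g, ontology.node_index(l)),
                                      node_emb) for l in t_leaves]
            preds[s] = np.mean(leaf_p, axis=0)
        truth = held.values[:, held.tissue_ids.index(target), :]
        rho = per_gene_spearman(preds, truth)
        assert np.nanmedian(rho) > 0.8

    def test_unknown_composite_rejected(self, atlas_expr, cohort_data,
                                        ontology, gene_embedding):
        with pytest.raises(KeyError):
            train_extended_bronte("ghost", atlas_expr, cohort_data[1],
                                  ontology, gene_embedding)


class TestLmBank:
    def make_cohort(self, values, comps):
        s, t, g = values.shape
        return ExpressionTensor(values, np.ones_like(values, dtype=bool),
                                [f"s{i}" for i in range(s)], comps,
                                [f"g{i}" for i in range(g)])

    def test_identity_predictor(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 3, 2))
        vals[:, 0, :] = vals[:, 1, :]  # target == predictor c1
        bank = fit_lm_bank(self.make_cohort(vals, ["c0", "c1", "c2"]))
        intercept, coefs = bank.coefficients("c0", ("c1", "c2"))
        assert np.allclose(coefs[0], 1.0, atol=1e-8)
        assert np.allclose(coefs[1], 0.0, atol=1e-8)
        assert np.allclose(intercept, 0.0, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5, 3, 1))
        bank = fit_lm_bank(self.make_cohort(vals, ["c0", "c1", "c2"]))
        intercept, coefs = bank.coefficients("c2", ("c0", "c1"))
        X = np.hstack([np.ones((5, 1)), vals[:, 0, 0:1], vals[:, 1, 0:1]])
        y = vals[:, 2, 0]
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose([intercept[0], *coefs[:, 0]], beta, atol=1e-8)

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(3, 3, 1))
        bank = fit_lm_bank(self.make_cohort(vals, ["c0", "c1", "c2"]))
        with pytest.raises(ValueError, match="complete subjects"):
            bank.coefficients("c0", ("c1", "c2"))

    def test_cache_reused(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(8, 3, 2))
        bank = fit_lm_bank(self.make_cohort(vals, ["c0", "c1", "c2"]))
        a = bank.coefficients("c0", ("c1",))
        assert bank.coefficients("c0", ("c1",)) is a


class TestImputeProfile:
    def test_fully_observed_unchanged(self, extended_models, lm_bank,
                                      cohort_data, ontology):
        cohort = cohort_data[1]
        prof = cohort.values[0].T
        obs = np.ones(len(ontology.composite_ids), bool)
        completed, leaf_preds, imputed = impute_profile(
            prof, obs, cohort.gene_ids, extended_models, lm_bank, ontology)
        assert np.array_equal(completed, prof)
        assert not imputed.any()
        assert set(leaf_preds) == set(ontology.composite_ids)

    def test_single_missing_equals_direct_extended_prediction(
            self, extended_models, lm_bank, cohort_data, ontology):
        cohort = cohort_data[1]
        comps = ontology.composite_ids
        target = comps[2]
        m = extended_models[target]
        prof = cohort.values[1].T
        obs = np.ones(len(comps), bool)
        obs[2] = False
        completed, _, _ = impute_profile(prof, obs, cohort.gene_ids,
                                         {target: m}, lm_bank, ontology)
        # direct: extended model on the 5 remaining slots, no LM step
        slot_cols = [comps.index(c) for c in m.profile_slot_ids]
        gi = {g: i for i, g in enumerate(m.gene_embedding.gene_ids)}
        rows = np.array([gi[g] for g in cohort.gene_ids])
        node_emb = m.node_embeddings()
        leaves = subordinate_leaves(ontology, target)
        direct = np.mean([m.predict_batch(prof[:, slot_cols], rows,
                                          np.full(len(rows),
                                                  ontology.node_index(l)),
                                          node_emb) for l in leaves], axis=0)
        assert np.allclose(completed[:, 2], direct)

    def test_two_missing_uses_lm_fill(self, extended_models, lm_bank,
                                      cohort_data, ontology):
        cohort = cohort_data[1]
        comps = ontology.composite_ids
        prof = cohort.values[2].T
        obs = np.ones(len(comps), bool)
        obs[[0, 1]] = False
        completed, _, _ = impute_profile(prof, obs, cohort.gene_ids,
                                         extended_models, lm_bank, ontology,
                                         min_observed=4)
        # manual trace for target c0: first fill c1 by LM from observed, then
        # run the extended model for c0
        observed_comps = tuple(comps[i] for i in range(len(comps)) if obs[i])
        fill = lm_bank.predict("c1", observed_comps,
                               prof[:, [comps.index(c) for c in observed_comps]])
        work = prof.copy()
        work[:, 1] = fill
        m = extended_models["c0"]
        slot_cols = [comps.index(c) for c in m.profile_slot_ids]
        gi = {g: i for i, g in enumerate(m.gene_embedding.gene_ids)}
        rows = np.array([gi[g] for g in cohort.gene_ids])
        node_emb = m.node_embeddings()
        leaves = subordinate_leaves(ontology, "c0")
        manual = np.mean([m.predict_batch(work[:, slot_cols], rows,
                                          np.full(len(rows),
                                                  ontology.node_index(l)),
                                          node_emb) for l in leaves], axis=0)
        assert np.allclose(completed[:, 0], manual)

    def test_observed_values_never_altered(self, extended_models, lm_bank,
                                           cohort_data, ontology):
        cohort = cohort_data[1]
        rng = np.random.default_rng(0)
        for trial in range(5):
            obs = np.ones(len(ontology.composite_ids), bool)
            drop = rng.choice(len(obs), size=rng.integers(1, 3), replace=False)
            obs[drop] = False
            s = int(rng.integers(0, len(cohort.subject_ids)))
            prof = cohort.values[s].T
            completed, _, imputed = impute_profile(
                prof, obs, cohort.gene_ids, extended_models, lm_bank, ontology,
                min_observed=4)
            assert np.array_equal(completed[:, obs], prof[:, obs])
            assert np.array_equal(imputed, ~obs)

    def test_below_minimum_refused(self, extended_models, lm_bank,
                                   cohort_data, ontology):
        cohort = cohort_data[1]
        obs = np.zeros(len(ontology.composite_ids), bool)
        obs[:2] = True
        with pytest.raises(ValueError, match="below the minimum"):
            impute_profile(cohort.values[0].T, obs, cohort.gene_ids,
                           extended_models, lm_bank, ontology, min_observed=5)

    def test_missing_model_named_in_error(self, lm_bank, cohort_data, ontology):
        cohort = cohort_data[1]
        obs = np.ones(len(ontology.composite_ids), bool)
        obs[3] = False
        with pytest.raises(KeyError, match="c3"):
            impute_profile(cohort.values[0].T, obs, cohort.gene_ids, {},
                           lm_bank, ontology)


class TestCheckpoint:
    def test_save_load_round_trip(self, base_model, tmp_path, ontology):
        path = tmp_path / "model.npz"
        base_model.save(path)
        back = base_model.load(path)
        p = np.linspace(-1, 1, len(ontology.composite_ids))
        leaf = ontology.leaf_ids[3]
        assert np.isclose(predict_expression(back, p, "g7", leaf),
                          predict_expression(base_model, p, "g7", leaf))
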