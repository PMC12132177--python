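"""Ontology-guided cross-tissue expression predictor.

The predictor scores one (subject, gene, fine-grained tissue) triple at a
time: it concatenates the tissue's graph-convolution embedding, the gene's
frozen pretrained embedding, and the subject's per-composite expression
profile for that gene, and passes the vector through a ReLU MLP with two
blocks of hidden layers and a linear scalar head.  Composite (coarse)
tissue predictions are the arithmetic mean of the predictions for the
composite's subordinate leaves.

Training is two-phase: first on the atlas subjects (all leaves observed,
profiles constructed by averaging each composite's subordinate leaves),
then fine-tuned on the cohort subjects' measured composite profiles at a
10x lower learning rate.  Gene embeddings stay frozen throughout; the
graph-convolution weights train jointly with the MLP.

Missing composites are imputed with per-composite "extended" models whose
profile excludes the target composite; when a subject misses several
composites, a bank of per-gene ordinary-least-squares models first fills
the other missing slots (two-step imputation).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from ._nn import MLP, Adam, GcnStack
from .embeddings import GeneEmbedding, TissueEmbeddingNet
from .ontology import BrainOntology, normalized_adjacency, subordinate_leaves
from .preprocess import ExpressionTensor

log = logging.getLogger(__name__)

__all__ = [
    "BronteModel",
    "BronteImputer",
    "LinearTissueImputer",
    "predict_expression",
    "predict_composite",
    "train_bronte",
    "train_extended_bronte",
    "fit_lm_bank",
    "impute_profile",
    "aggregate_to_composites",
]


# ---------------------------------------------------------------------------
# model container

@dataclass
class BronteModel:
    """Trained predictor weights plus the structures they are bound to."""

    tissue_net: TissueEmbeddingNet
    gene_embedding: GeneEmbedding
    mlp: MLP
    ont: BrainOntology
    n_profile_slots: int
    target_composite: str | None = None
    profile_slot_ids: list[str] = field(default_factory=list)
    train_config: dict = field(default_factory=dict)
    loss_trace: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expect = self.tissue_net.dim_out + self.gene_embedding.dim_g + self.n_profile_slots
        got = self.mlp.weights[0].shape[0]
        if got != expect:
            raise ValueError(f"MLP input width {got} != embeddings+profile {expect}")
        if self.target_composite is not None:
            want = [c for c in self.ont.composite_ids if c != self.target_composite]
            if self.profile_slot_ids != want:
                raise ValueError("extended model slot order must be the canonical "
                                 "composite order minus the target")

    # cached per-weight-state node embeddings
    def node_embeddings(self) -> np.ndarray:
        adj = normalized_adjacency(self.ont)
        return GcnStack(self.tissue_net.layer_weights).forward(adj)[0]

    def _gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_embedding.gene_ids)}

    def predict_batch(self, profiles: np.ndarray, gene_rows: np.ndarray,
                      node_rows: np.ndarray,
                      node_emb: np.ndarray | None = None) -> np.ndarray:
        """Vectorized forward pass over aligned (profile, gene, leaf) triples."""
        if node_emb is None:
            node_emb = self.node_embeddings()
        x = np.concatenate(
            [node_emb[node_rows], self.gene_embedding.matrix[gene_rows], profiles],
            axis=1)
        return self.mlp(x)[:, 0]

    def save(self, path) -> None:
        """Single-file npz checkpoint (weights + config + ontology hash)."""
        import hashlib
        ont_hash = hashlib.sha256(
            json.dumps({"nodes": self.ont.nodes, "leaves": self.ont.leaf_ids,
                        "composites": self.ont.composite_map}, sort_keys=True).encode()
        ).hexdigest()
        arrays = {f"gcn_{i}": w for i, w in enumerate(self.tissue_net.layer_weights)}
        arrays |= {f"mlp_w_{i}": w for i, w in enumerate(self.mlp.weights)}
        arrays |= {f"mlp_b_{i}": b for i, b in enumerate(self.mlp.biases)}
        arrays["gene_emb"] = self.gene_embedding.matrix
        header = {
            "gene_ids": self.gene_embedding.gene_ids,
            "n_profile_slots": self.n_profile_slots,
            "target_composite": self.target_composite,
            "profile_slot_ids": self.profile_slot_ids,
            "train_config": self.train_config,
            "ontology_hash": ont_hash,
            "ontology": {"nodes": self.ont.nodes, "leaves": self.ont.leaf_ids,
                         "composites": self.ont.composite_map},
        }
        arrays["header_json"] = np.frombuffer(
            json.dumps(header, default=float).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "BronteModel":
        with np.load(path) as z:
            header = json.loads(bytes(z["header_json"]).decode())
            gcn = [z[f"gcn_{i}"] for i in range(len([k for k in z if k.startswith("gcn_")]))]
            n_mlp = len([k for k in z.files if k.startswith("mlp_w_")])
            mlp = MLP([z[f"mlp_w_{i}"] for i in range(n_mlp)],
                      [z[f"mlp_b_{i}"] for i in range(n_mlp)])
            gene_emb = GeneEmbedding(z["gene_emb"], header["gene_ids"])
        od = header["ontology"]
        ont = BrainOntology(nodes=od["nodes"], leaf_ids=od["leaves"],
                            composite_map=od["composites"])
        return cls(TissueEmbeddingNet(gcn), gene_emb, mlp, ont,
                   header["n_profile_slots"], header["target_composite"],
                   header["profile_slot_ids"], header["train_config"])


def predict_expression(model: BronteModel, profile, gene: str, leaf: str) -> float:
    """Predicted expression of one gene in one fine-grained tissue."""
    gi = model._gene_index()
    if gene not in gi:
        raise KeyError(f"unknown gene {gene!r}")
    if leaf not in model.ont.leaf_ids:
        raise KeyError(f"unknown leaf tissue {leaf!r}")
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (model.n_profile_slots,):
        raise ValueError(f"profile must have {model.n_profile_slots} slots")
    if not np.isfinite(profile).all():
        raise ValueError("profile contains non-finite values")
    node = model.ont.node_index(leaf)
    out = model.predict_batch(profile[None, :], np.array([gi[gene]]),
                              np.array([node]))
    return float(out[0])


def predict_composite(model: BronteModel, profile, gene: str, composite: str,
                      ont: BrainOntology | None = None) -> float:
    """Mean of the leaf predictions subordinate to a composite tissue."""
    ont = ont or model.ont
    leaves = subordinate_leaves(ont, composite)
    return float(np.mean([predict_expression(model, profile, gene, l)
                          for l in leaves]))


# ---------------------------------------------------------------------------
# training

def _atlas_profiles(atlas: ExpressionTensor, ont: BrainOntology,
                    slot_ids: list[str]) -> np.ndarray:
    """(subject, gene, slot) profiles from averaging subordinate leaves."""
    n_s, _, n_g = atlas.shape
    out = np.zeros((n_s, n_g, len(slot_ids)))
    for k, comp in enumerate(slot_ids):
        idx = [atlas.tissue_ids.index(l) for l in subordinate_leaves(ont, comp)]
        out[:, :, k] = atlas.values[:, idx, :].mean(axis=1)
    return out


def aggregate_to_composites(expr: ExpressionTensor, ont: BrainOntology) -> ExpressionTensor:
    """Collapse a leaf-level tensor to composite tissues by leaf averaging."""
    n_s, _, n_g = expr.shape
    comps = ont.composite_ids
    values = np.zeros((n_s, len(comps), n_g))
    observed = np.zeros_like(values, dtype=bool)
    for k, comp in enumerate(comps):
        idx = [expr.tissue_ids.index(l) for l in subordinate_leaves(ont, comp)]
        values[:, k, :] = expr.values[:, idx, :].mean(axis=1)
        observed[:, k, :] = expr.observed[:, idx, :].all(axis=1)
    return ExpressionTensor(values, observed, list(expr.subject_ids), comps,
                            list(expr.gene_ids))


class BronteImputer(BaseEstimator):
    """Cross-tissue expression predictor (sklearn-style estimator).

    Set ``target_composite`` to train the "extended" variant whose subject
    profile excludes that composite and whose prediction targets are the
    composite's subordinate leaves.

    Parameters
    ----------
    gcn_sizes : widths of the graph-convolution layers (last = tissue
        embedding width).
    mlp_hidden : hidden widths of the two MLP blocks, concatenated.
    lr, fine_tune_lr : Adam learning rates for the two phases.
    epochs_atlas, epochs_cohort : passes over the atlas / cohort samples.
    batch_size : minibatch size over (subject, gene, tissue) triples.
    seed : RNG seed; identical seed and config give identical weights.
    """

    def __init__(self, gcn_sizes=(64, 32), mlp_hidden=(256, 128, 64, 32),
                 lr: float = 1e-3, fine_tune_lr: float | None = None,
                 epochs_atlas: int = 30, epochs_cohort: int = 15,
                 batch_size: int = 1024, seed: int = 0,
                 target_composite: str | None = None):
        self.gcn_sizes = tuple(gcn_sizes)
        self.mlp_hidden = tuple(mlp_hidden)
        self.lr = lr
        self.fine_tune_lr = fine_tune_lr
        self.epochs_atlas = epochs_atlas
        self.epochs_cohort = epochs_cohort
        self.batch_size = batch_size
        self.seed = seed
        self.target_composite = target_composite

    # -- internals -------------------------------------------------------
    def _forward_backward(self, gcn: GcnStack, mlp: MLP, adj, profiles,
                          gene_mat, node_rows, y, group: np.ndarray | None):
        """One minibatch loss + gradients for all trainable weights.

        ``group`` aggregates expanded leaf rows into composite predictions
        by averaging (None for leaf-level targets).
        """
        node_emb, gcn_cache = gcn.forward(adj)
        x = np.concatenate([node_emb[node_rows], gene_mat, profiles], axis=1)
        out, mlp_cache = mlp.forward(x)
        pred = out[:, 0]
        if group is None:
            resid = pred - y
            n = y.size
            loss = float(np.mean(resid ** 2))
            dpred = 2.0 * resid / n
        else:
            n_groups = int(group.max()) + 1
            sums = np.bincount(group, weights=pred, minlength=n_groups)
            cnts = np.bincount(group, minlength=n_groups).astype(float)
            gpred = sums / cnts
            resid = gpred - y
            loss = float(np.mean(resid ** 2))
            dpred = (2.0 * resid / n_groups)[group] / cnts[group]
        mlp_grads, dx = mlp.backward(mlp_cache, dpred[:, None])
        dim_t = gcn.weights[-1].shape[1]
        d_node = np.zeros_like(node_emb)
        np.add.at(d_node, node_rows, dx[:, :dim_t])
        gcn_grads = gcn.backward(gcn_cache, d_node)
        return loss, gcn_grads, mlp_grads

    def _run_phase(self, gcn, mlp, adj, profiles, gene_rows, node_rows, y,
                   groups, gene_matrix, epochs, lr, rng):
        """SGD over shuffled minibatches; returns per-epoch mean losses."""
        opt = Adam([*gcn.params, *mlp.params], lr=lr)
        n_gcn = len(gcn.params)
        n = y.size if groups is None else int(groups.max()) + 1
        trace = []
        idx_all = np.arange(n)
        for _ in range(epochs):
            rng.shuffle(idx_all)
            losses = []
            for start in range(0, n, self.batch_size):
                take = idx_all[start:start + self.batch_size]
                if groups is None:
                    rows = take
                    grp = None
                    yb = y[rows]
                else:
                    # expand the selected groups into their member rows
                    mem = [self._members[g] for g in take]
                    rows = np.concatenate(mem)
                    grp = np.repeat(np.arange(take.size), [m.size for m in mem])
                    yb = y[take]
                loss, g_gcn, g_mlp = self._forward_backward(
                    gcn, mlp, adj, profiles[rows], gene_matrix[gene_rows[rows]],
                    node_rows[rows], yb, grp)
                opt.step([*g_gcn, *g_mlp])
                losses.append(loss)
            trace.append(float(np.mean(losses)))
        return trace

    # -- fitting ---------------------------------------------------------
    def fit(self, atlas_expr: ExpressionTensor, cohort_expr: ExpressionTensor,
            ont: BrainOntology, gene_emb: GeneEmbedding) -> "BronteImputer":
        if len(atlas_expr.subject_ids) == 0 or len(cohort_expr.subject_ids) == 0:
            raise ValueError("empty training set")
        if not atlas_expr.observed.all():
            raise ValueError("atlas subjects must have all leaf tissues observed")
        if not cohort_expr.observed.all():
            raise ValueError("cohort subjects must have complete composite profiles")
        if atlas_expr.gene_ids != gene_emb.gene_ids or \
           cohort_expr.gene_ids != gene_emb.gene_ids:
            raise ValueError("gene order mismatch between tensors and embedding")

        comps = ont.composite_ids
        if self.target_composite is not None and self.target_composite not in comps:
            raise KeyError(f"unknown composite {self.target_composite!r}")
        slot_ids = [c for c in comps if c != self.target_composite]
        target_leaves = (ont.leaf_ids if self.target_composite is None
                         else subordinate_leaves(ont, self.target_composite))

        adj = normalized_adjacency(ont)
        rng = np.random.default_rng(self.seed)
        gcn = GcnStack.create(ont.n_nodes, list(self.gcn_sizes), rng)
        dim_in = self.gcn_sizes[-1] + gene_emb.dim_g + len(slot_ids)
        mlp = MLP.create([dim_in, *self.mlp_hidden, 1], rng)

        n_g = len(gene_emb.gene_ids)
        gene_matrix = gene_emb.matrix

        # ---- phase 1: atlas leaves --------------------------------------
        prof_atlas = _atlas_profiles(atlas_expr, ont, slot_ids)
        leaf_nodes = np.array([ont.node_index(l) for l in target_leaves])
        leaf_cols = np.array([atlas_expr.tissue_ids.index(l) for l in target_leaves])
        n_s = len(atlas_expr.subject_ids)
        s_idx, g_idx, l_idx = np.meshgrid(
            np.arange(n_s), np.arange(n_g), np.arange(len(target_leaves)),
            indexing="ij")
        s_idx, g_idx, l_idx = s_idx.ravel(), g_idx.ravel(), l_idx.ravel()
        profiles1 = prof_atlas[s_idx, g_idx]
        gene_rows1 = g_idx
        node_rows1 = leaf_nodes[l_idx]
        y1 = atlas_expr.values[s_idx, leaf_cols[l_idx], g_idx]
        self._members = None
        trace1 = self._run_phase(gcn, mlp, adj, profiles1, gene_rows1,
                                 node_rows1, y1, None, gene_matrix,
                                 self.epochs_atlas, self.lr, rng)

        # ---- phase 2: cohort composites ---------------------------------
        slot_cols = [cohort_expr.tissue_ids.index(c) for c in slot_ids]
        targets = comps if self.target_composite is None else [self.target_composite]
        comp_leaf_nodes = {c: np.array([ont.node_index(l)
                                        for l in subordinate_leaves(ont, c)])
                           for c in targets}
        n_c = len(cohort_expr.subject_ids)
        samp_s, samp_g, samp_c = [], [], []
        for ci, c in enumerate(targets):
            ss, gg = np.meshgrid(np.arange(n_c), np.arange(n_g), indexing="ij")
            samp_s.append(ss.ravel())
            samp_g.append(gg.ravel())
            samp_c.append(np.full(ss.size, ci))
        samp_s = np.concatenate(samp_s)
        samp_g = np.concatenate(samp_g)
        samp_c = np.concatenate(samp_c)
        tcols = [cohort_expr.tissue_ids.index(c) for c in targets]
        y2 = cohort_expr.values[samp_s, np.array(tcols)[samp_c], samp_g]
        prof_cohort = cohort_expr.values[:, slot_cols, :].transpose(0, 2, 1)

        # expanded member rows per (subject, gene, composite) sample
        members = []
        exp_prof, exp_gene, exp_node = [], [], []
        pos = 0
        for s, g, ci in zip(samp_s, samp_g, samp_c):
            nodes = comp_leaf_nodes[targets[ci]]
            k = nodes.size
            members.append(np.arange(pos, pos + k))
            exp_node.append(nodes)
            exp_gene.append(np.full(k, g))
            exp_prof.append(np.repeat(prof_cohort[s, g][None, :], k, axis=0))
            pos += k
        self._members = members
        profiles2 = np.concatenate(exp_prof, axis=0)
        gene_rows2 = np.concatenate(exp_gene)
        node_rows2 = np.concatenate(exp_node)
        ft_lr = self.fine_tune_lr if self.fine_tune_lr is not None else self.lr / 10.0
        trace2 = self._run_phase(gcn, mlp, adj, profiles2, gene_rows2,
                                 node_rows2, y2, np.arange(len(members)),
                                 gene_matrix, self.epochs_cohort, ft_lr, rng)
        self._members = None

        self.model_ = BronteModel(
            TissueEmbeddingNet(gcn.weights), gene_emb, mlp, ont,
            n_profile_slots=len(slot_ids), target_composite=self.target_composite,
            profile_slot_ids=slot_ids,
            train_config=self.get_params() | {"fine_tune_lr": ft_lr},
            loss_trace={"atlas": trace1, "cohort": trace2},
        )
        return self

    def predict(self, profiles: np.ndarray, genes: list[str],
                tissue: str) -> np.ndarray:
        """Predict one tissue (leaf or composite) for aligned profile rows."""
        m = self.model_
        gi = m._gene_index()
        gene_rows = np.array([gi[g] for g in genes])
        profiles = np.asarray(profiles, dtype=float)
        node_emb = m.node_embeddings()
        if tissue in m.ont.composite_map:
            leaves = subordinate_leaves(m.ont, tissue)
            preds = [m.predict_batch(profiles, gene_rows,
                                     np.full(len(genes), m.ont.node_index(l)),
                                     node_emb)
                     for l in leaves]
            return np.mean(preds, axis=0)
        return m.predict_batch(profiles, gene_rows,
                               np.full(len(genes), m.ont.node_index(tissue)),
                               node_emb)


def train_bronte(atlas_expr, cohort_expr, ont, gene_emb, config: dict | None = None,
                 seed: int = 0) -> BronteModel:
    """Two-phase training of the full predictor (functional wrapper)."""
    est = BronteImputer(seed=seed, **(config or {}))
    return est.fit(atlas_expr, cohort_expr, ont, gene_emb).model_


def train_extended_bronte(target_composite: str, atlas_expr, cohort_expr, ont,
                          gene_emb, config: dict | None = None,
                          seed: int = 0) -> BronteModel:
    """Train the per-composite extended predictor (profile excludes target)."""
    est = BronteImputer(seed=seed, target_composite=target_composite,
                        **(config or {}))
    return est.fit(atlas_expr, cohort_expr, ont, gene_emb).model_


# ---------------------------------------------------------------------------
# linear-model bank

class LinearTissueImputer(BaseEstimator):
    """Per-gene OLS models predicting one composite from a predictor subset.

    Fitted lazily per requested (target, predictors) pair on the
    complete-profile cohort subjects and cached; a shared design matrix
    across genes makes each request a single least-squares solve.
    """

    def __init__(self, ridge_fallback: float = 1e-6):
        self.ridge_fallback = ridge_fallback

    def fit(self, cohort_expr: ExpressionTensor, y=None) -> "LinearTissueImputer":
        if not cohort_expr.observed.all():
            raise ValueError("LM bank requires complete-profile subjects")
        self.cohort_ = cohort_expr
        self.cache_: dict[tuple[str, tuple[str, ...]], tuple[np.ndarray, np.ndarray]] = {}
        return self

    def coefficients(self, target: str, predictors: tuple[str, ...]):
        """(intercept: genes, coefs: predictors x genes) for one request."""
        predictors = tuple(predictors)
        key = (target, predictors)
        if key in self.cache_:
            return self.cache_[key]
        expr = self.cohort_
        for t in (target, *predictors):
            if t not in expr.tissue_ids:
                raise KeyError(f"unknown tissue {t!r} in LM bank cohort")
        n = len(expr.subject_ids)
        p = len(predictors)
        if n < p + 2:
            raise ValueError(
                f"LM bank needs >= {p + 2} complete subjects for {p} predictors, have {n}")
        ti = expr.tissue_ids.index
        X = expr.values[:, [ti(c) for c in predictors], :]  # n x p x genes
        Y = expr.values[:, ti(target), :]                   # n x genes
        n_genes = Y.shape[1]
        coefs = np.zeros((p, n_genes))
        intercept = np.zeros(n_genes)
        ones = np.ones((n, 1))
        for g in range(n_genes):
            design = np.hstack([ones, X[:, :, g]])
            gram = design.T @ design
            if np.linalg.matrix_rank(gram) < gram.shape[0]:
                log.warning("rank-deficient design for gene %s target %s; "
                            "ridge fallback", expr.gene_ids[g], target)
                gram = gram + self.ridge_fallback * np.eye(gram.shape[0])
            beta = np.linalg.solve(gram, design.T @ Y[:, g])
            intercept[g] = beta[0]
            coefs[:, g] = beta[1:]
        self.cache_[key] = (intercept, coefs)
        return self.cache_[key]

    def predict(self, target: str, predictors: tuple[str, ...],
                profile_values: np.ndarray) -> np.ndarray:
        """Impute the target for all genes: profile_values is genes x p."""
        intercept, coefs = self.coefficients(target, tuple(predictors))
        return intercept + np.einsum("gp,pg->g", profile_values, coefs)


def fit_lm_bank(cohort_expr: ExpressionTensor,
                requests: list[tuple[str, tuple[str, ...]]] | None = None
                ) -> LinearTissueImputer:
    """Fit (and optionally pre-warm) the per-gene OLS bank."""
    bank = LinearTissueImputer().fit(cohort_expr)
    for target, preds in requests or []:
        bank.coefficients(target, tuple(preds))
    return bank


# ---------------------------------------------------------------------------
# two-step imputation

def impute_profile(profile_values: np.ndarray, observed: np.ndarray,
                   gene_ids: list[str], models: dict[str, BronteModel],
                   lm_bank: LinearTissueImputer, ont: BrainOntology,
                   min_observed: int = 5, allow_below_min: bool = False):
    """Complete one subject's per-gene composite profile.

    Parameters
    ----------
    profile_values : genes x composites array (canonical composite order);
        entries of unobserved composites are ignored.
    observed : boolean vector over composites.
    models : extended predictor per composite (needed for every composite
        whose leaves are to be predicted).
    lm_bank : step-1 per-gene OLS bank.
    min_observed : refuse subjects with fewer observed composites (override
        with ``allow_below_min``).

    Returns
    -------
    completed : genes x composites array; observed entries unchanged.
    leaf_preds : dict composite -> genes x (its leaves) predictions from
        that composite's extended model.
    imputed : boolean vector marking the composites that were imputed.
    """
    comps = ont.composite_ids
    profile_values = np.asarray(profile_values, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if profile_values.shape != (len(gene_ids), len(comps)):
        raise ValueError("profile_values must be genes x composites in canonical order")
    n_obs = int(observed.sum())
    if n_obs < min_observed and not allow_below_min:
        raise ValueError(
            f"subject has {n_obs} observed composites, below the minimum "
            f"{min_observed} (pass allow_below_min=True to override)")
    missing = [c for c, o in zip(comps, observed) if not o]
    obs_comps = tuple(c for c, o in zip(comps, observed) if o)
    for m in missing:
        if m not in models:
            raise KeyError(f"no extended model supplied for missing composite {m!r}")

    completed = profile_values.copy()
    leaf_preds: dict[str, np.ndarray] = {}

    for target in comps:
        model = models.get(target)
        if model is None:
            continue  # leaf predictions only for composites with a model
        # step 1: fill every OTHER missing composite from the observed ones
        work = profile_values.copy()
        for other in missing:
            if other == target:
                continue
            work[:, comps.index(other)] = lm_bank.predict(
                other, obs_comps,
                profile_values[:, [comps.index(c) for c in obs_comps]])
        # step 2: extended model on the 9-slot profile
        slot_cols = [comps.index(c) for c in model.profile_slot_ids]
        prof = work[:, slot_cols]
        gi = model._gene_index()
        gene_rows = np.array([gi[g] for g in gene_ids])
        node_emb = model.node_embeddings()
        leaves = subordinate_leaves(ont, target)
        preds = np.stack([
            model.predict_batch(prof, gene_rows,
                                np.full(len(gene_ids), ont.node_index(l)),
                                node_emb)
            for l in leaves], axis=1)
        leaf_preds[target] = preds
        if target in missing:
            completed[:, comps.index(target)] = preds.mean(axis=1)

    imputed = ~observed
    return completed, leaf_preds, imputed
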