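"""Tissue and gene embeddings.

Tissue embeddings come from a graph-convolution stack over the ontology
tree (one-hot node features, so the first weight matrix doubles as a free
per-node embedding table smoothed by the graph operator); they are trained
jointly with the predictor.  Gene embeddings are pretrained so that the
Pearson correlation between two genes' embedding vectors approximates the
Pearson correlation of their expression profiles across the atlas leaf
tissues, averaged over atlas subjects, and are then frozen.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._nn import Adam, GcnStack
from .preprocess import ExpressionTensor

log = logging.getLogger(__name__)

__all__ = [
    "TissueEmbeddingNet",
    "GeneEmbedding",
    "gcn_forward",
    "train_gene_embeddings",
    "GeneEmbedder",
]


@dataclass
class TissueEmbeddingNet:
    """Graph-convolution weights producing node embeddings from one-hot features."""

    layer_weights: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.layer_weights:
            raise ValueError("need at least one layer")
        if self.layer_weights[-1].shape[1] <= 0:
            raise ValueError("dim_out must be positive")

    @property
    def n_nodes(self) -> int:
        return self.layer_weights[0].shape[0]

    @property
    def dim_out(self) -> int:
        return self.layer_weights[-1].shape[1]

    @classmethod
    def create(cls, n_nodes: int, sizes: list[int], seed: int) -> "TissueEmbeddingNet":
        rng = np.random.default_rng(seed)
        return cls(GcnStack.create(n_nodes, sizes, rng).weights)


@dataclass
class GeneEmbedding:
    """Genes x dim_g embedding matrix with its gene order."""

    matrix: np.ndarray
    gene_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.gene_ids):
            raise ValueError("row count != gene count")
        if self.matrix.shape[1] < 2:
            raise ValueError("dim_g must be >= 2 for Pearson correlation")
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite embedding entries")

    @property
    def dim_g(self) -> int:
        return self.matrix.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.matrix[self.gene_ids.index(gene_id)]

    def save(self, tsv_path, meta_path=None) -> None:
        df = pd.DataFrame(self.matrix, index=pd.Index(self.gene_ids, name="id"))
        df.columns = [f"e{i}" for i in range(self.dim_g)]
        df.to_csv(tsv_path, sep="\t", float_format="%.17g")
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(self.meta, fh, indent=1, default=float)

    @classmethod
    def load(cls, tsv_path, meta_path=None) -> "GeneEmbedding":
        df = pd.read_csv(tsv_path, sep="\t", index_col=0)
        meta = {}
        if meta_path is not None:
            with open(meta_path) as fh:
                meta = json.load(fh)
        return cls(df.to_numpy(), [str(i) for i in df.index], meta)


def gcn_forward(adj: np.ndarray, net: TissueEmbeddingNet) -> np.ndarray:
    """Deterministic forward pass: relu graph convolutions, linear last layer."""
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    return GcnStack(net.layer_weights).forward(adj)[0]


# ---------------------------------------------------------------------------
# gene-embedding pretraining

def _row_center_norm(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rows centered and scaled to unit norm; also return centered rows and norms."""
    c = m - m.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return c / safe[:, None], c, norms


class GeneEmbedder(BaseEstimator):
    """Pretrains gene embeddings by correlation matching (sklearn-style).

    Minimizes, over sampled gene pairs (g, h) and atlas subjects s cycled
    round-robin, the squared difference between the embedding correlation
    rho(e_g, e_h) (Pearson across the dim_g coordinates) and the expression
    correlation rho(x_g, x_h) across the atlas leaf tissues of subject s.

    Parameters
    ----------
    dim_g : embedding width (>= 2).
    pairs_per_step : gene pairs sampled per gradient step.
    steps : Adam steps; 0 returns the seeded random initialization.
    lr : Adam learning rate.
    seed : RNG seed; identical seeds give bitwise-identical embeddings.
    """

    def __init__(self, dim_g: int = 64, pairs_per_step: int = 4096,
                 steps: int = 200, lr: float = 1e-3, seed: int = 0):
        self.dim_g = dim_g
        self.pairs_per_step = pairs_per_step
        self.steps = steps
        self.lr = lr
        self.seed = seed

    def fit(self, expr: ExpressionTensor, y=None) -> "GeneEmbedder":
        if self.dim_g < 2:
            raise ValueError("dim_g must be >= 2")
        if not expr.observed.all():
            raise ValueError("atlas tensor must be fully observed on all leaf tissues")
        rng = np.random.default_rng(self.seed)
        n_genes = len(expr.gene_ids)
        n_subj = len(expr.subject_ids)
        emb = rng.normal(0.0, 1.0, size=(n_genes, self.dim_g))

        # per-subject standardized expression rows (gene x tissue), so the
        # target correlation for a pair is a row dot product
        std_expr = []
        degenerate: list[set[int]] = []
        for s in range(n_subj):
            m = expr.values[s].T  # genes x tissues
            u, _, norms = _row_center_norm(m)
            std_expr.append(u)
            bad = set(np.nonzero(norms == 0)[0].tolist())
            if bad:
                log.warning("subject %s: %d zero-variance genes skipped in "
                            "embedding pretraining", expr.subject_ids[s], len(bad))
            degenerate.append(bad)

        opt = Adam([emb], lr=self.lr)
        trace = []
        for step in range(self.steps):
            s = step % n_subj
            g = rng.integers(0, n_genes, size=self.pairs_per_step)
            h = rng.integers(0, n_genes, size=self.pairs_per_step)
            keep = g != h
            if degenerate[s]:
                bad = degenerate[s]
                keep &= np.array([gi not in bad and hi not in bad
                                  for gi, hi in zip(g, h)])
            g, h = g[keep], h[keep]
            if g.size == 0:
                continue
            target = np.einsum("ij,ij->i", std_expr[s][g], std_expr[s][h])

            u, c, norms = _row_center_norm(emb)
            norms = np.where(norms > 0, norms, 1.0)
            rho = np.einsum("ij,ij->i", u[g], u[h])
            resid = rho - target
            trace.append(float(np.mean(resid ** 2)))
            coef = 2.0 * resid / g.size
            # d rho / d c_g = (u_h - rho * u_g) / |c_g| ; centering projects
            # the gradient onto zero-mean vectors
            dg = coef[:, None] * (u[h] - rho[:, None] * u[g]) / norms[g, None]
            dh = coef[:, None] * (u[g] - rho[:, None] * u[h]) / norms[h, None]
            grad = np.zeros_like(emb)
            np.add.at(grad, g, dg)
            np.add.at(grad, h, dh)
            grad -= grad.mean(axis=1, keepdims=True)
            opt.step([grad])

        self.embedding_ = GeneEmbedding(
            emb, list(expr.gene_ids),
            meta={"dim_g": self.dim_g, "seed": self.seed, "steps": self.steps,
                  "loss_trace": trace},
        )
        self.loss_trace_ = trace
        return self

    def transform(self, gene_ids: list[str]) -> np.ndarray:
        rows = [self.embedding_.gene_ids.index(g) for g in gene_ids]
        return self.embedding_.matrix[rows]


def train_gene_embeddings(expr: ExpressionTensor, dim_g: int = 64,
                          pairs_per_step: int = 4096, steps: int = 200,
                          seed: int = 0, lr: float = 1e-3) -> GeneEmbedding:
    """Functional wrapper over :class:`GeneEmbedder`."""
    return GeneEmbedder(dim_g=dim_g, pairs_per_step=pairs_per_step,
                        steps=steps, lr=lr, seed=seed).fit(expr).embedding_
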