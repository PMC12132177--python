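"""Evaluation statistics for imputed expression.

Three statistics quantify how well imputed expression preserves real
structure: per-gene Spearman correlation of predicted vs held-out values
across subjects; the differential-stability (DS) score — the mean, over
subject pairs, of the Pearson correlation of a gene's across-tissue
profile; and the adjusted Rand index between gene-module partitions with a
label-permutation null.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "per_gene_spearman",
    "ds_score",
    "ari",
    "ari_permutation_p",
    "correlation_modules",
]


def per_gene_spearman(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Spearman correlation per gene (column) across subjects (rows).

    Ties get average ranks.  Genes where either vector is constant get
    NaN and should be excluded from summaries (count them via isnan).
    """
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    if pred.shape[0] < 3:
        raise ValueError("need >= 3 subjects for a rank correlation")
    rp = rankdata(pred, axis=0)
    rt = rankdata(truth, axis=0)
    rp = rp - rp.mean(axis=0)
    rt = rt - rt.mean(axis=0)
    num = (rp * rt).sum(axis=0)
    den = np.sqrt((rp ** 2).sum(axis=0) * (rt ** 2).sum(axis=0))
    out = np.full(pred.shape[1], np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def ds_score(expr_by_subject: list[np.ndarray], return_report: bool = False):
    """Differential-stability score per gene.

    Each element of ``expr_by_subject`` is a tissues x genes matrix for one
    subject.  For every gene the score is the mean, over all unordered
    subject pairs, of the Pearson correlation between the two subjects'
    across-tissue expression vectors; pairs where either vector is constant
    are skipped and counted.
    """
    mats = [np.asarray(m, float) for m in expr_by_subject]
    if len(mats) < 2:
        raise ValueError("need >= 2 subjects")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("all subjects must share the tissue and gene axes")
    n_t, n_g = shape
    # standardize each subject's per-gene tissue vector: genes x tissues
    z = np.empty((len(mats), n_g, n_t))
    valid = np.empty((len(mats), n_g), dtype=bool)
    for i, m in enumerate(mats):
        v = m.T - m.T.mean(axis=1, keepdims=True)
        sd = v.std(axis=1)
        valid[i] = sd > 0
        z[i] = np.divide(v, sd[:, None] * np.sqrt(n_t),
                         out=np.zeros_like(v), where=sd[:, None] > 0)
    scores = np.full(n_g, np.nan)
    skipped = 0
    acc = np.zeros(n_g)
    cnt = np.zeros(n_g)
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            ok = valid[i] & valid[j]
            corr = np.einsum("gt,gt->g", z[i], z[j])
            acc[ok] += corr[ok]
            cnt[ok] += 1
            skipped += int((~ok).sum())
    has = cnt > 0
    scores[has] = acc[has] / cnt[has]
    if return_report:
        return scores, {"skipped_pairs": skipped,
                        "genes_without_valid_pairs": int((~has).sum())}
    return scores


def _check_universe(a: dict, b: dict) -> list:
    if set(a) != set(b):
        raise ValueError("module assignments cover different gene universes")
    return sorted(a)


def ari(a: dict, b: dict) -> float:
    """Adjusted Rand index between two gene-module assignments.

    Identical trivial partitions (everything in one module) score 1.0 by
    the degenerate-denominator convention.
    """
    genes = _check_universe(a, b)
    la = [a[g] for g in genes]
    lb = [b[g] for g in genes]
    return float(adjusted_rand_score(la, lb))


def ari_permutation_p(a: dict, b: dict, n_perm: int = 1000,
                      seed: int = 0) -> tuple[float, float]:
    """Observed ARI and its label-permutation p-value.

    The first partition's labels are shuffled over genes ``n_perm`` times
    (module sizes preserved by construction) and the add-one estimator
    p = (1 + #{perm >= observed}) / (1 + n_perm) is returned, so p is
    never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = _check_universe(a, b)
    la = np.array([a[g] for g in genes])
    lb = [b[g] for g in genes]
    observed = float(adjusted_rand_score(la.tolist(), lb))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(la)
        if adjusted_rand_score(perm.tolist(), lb) >= observed:
            hits += 1
    return observed, (1 + hits) / (1 + n_perm)


def correlation_modules(expr: np.ndarray, gene_ids: list[str],
                        n_modules: int) -> dict:
    """Average-linkage clustering on 1 - |Pearson| into a fixed module count.

    A convenience generator of test partitions only — NOT a weighted
    co-expression network analysis; it performs no soft thresholding,
    topological overlap, or dendrogram cut-height logic.
    """
    expr = np.asarray(expr, float)  # tissues x genes
    c = np.corrcoef(expr.T)
    c = np.nan_to_num(c, nan=0.0)
    dist = 1.0 - np.abs(c)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=n_modules, criterion="maxclust")
    return {g: int(l) for g, l in zip(gene_ids, labels)}
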