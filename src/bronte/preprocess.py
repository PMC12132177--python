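"""Expression containers and harmonization.

Expression is held as a dense subject x tissue x gene array with a
tissue-granular observed mask: a subject either contributed a whole tissue
sample or did not, so all genes of a (subject, tissue) cell share one flag.
Normalization is per-gene quantile normalization against a pooled reference
distribution (the mean of order statistics across genes), so every gene's
observed values end up with an identical sorted profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionTensor",
    "average_probes",
    "quantile_normalize_per_gene",
    "intersect_genes",
    "read_expression_long",
    "write_expression_long",
    "read_expression_wide",
    "write_expression_wide",
]


@dataclass
class ExpressionTensor:
    """Subjects x tissues x genes expression values with an observed mask."""

    values: np.ndarray
    observed: np.ndarray  # bool, same shape; constant along the gene axis
    subject_ids: list[str]
    tissue_ids: list[str]
    gene_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != self.observed.shape:
            raise ValueError("values and observed shapes differ")
        expect = (len(self.subject_ids), len(self.tissue_ids), len(self.gene_ids))
        if self.values.shape != expect:
            raise ValueError(f"shape {self.values.shape} != labels {expect}")
        # tissue-granular missingness
        cellwise = self.observed.all(axis=2) | ~self.observed.any(axis=2)
        if not cellwise.all():
            raise ValueError("observed mask is not tissue-granular")
        if not np.isfinite(self.values[self.observed]).all():
            raise ValueError("non-finite values in observed cells")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def cell_observed(self) -> np.ndarray:
        """Subjects x tissues boolean mask (one flag per tissue sample)."""
        return self.observed[:, :, 0] if self.shape[2] else self.observed.any(axis=2)

    def copy(self) -> "ExpressionTensor":
        return ExpressionTensor(
            self.values.copy(), self.observed.copy(),
            list(self.subject_ids), list(self.tissue_ids), list(self.gene_ids),
            dict(self.meta),
        )

    def subset_subjects(self, keep: list[str]) -> "ExpressionTensor":
        idx = [self.subject_ids.index(s) for s in keep]
        return ExpressionTensor(
            self.values[idx], self.observed[idx], list(keep),
            list(self.tissue_ids), list(self.gene_ids), dict(self.meta),
        )

    def subset_tissues(self, keep: list[str]) -> "ExpressionTensor":
        idx = [self.tissue_ids.index(t) for t in keep]
        return ExpressionTensor(
            self.values[:, idx], self.observed[:, idx], list(self.subject_ids),
            list(keep), list(self.gene_ids), dict(self.meta),
        )


def average_probes(probe_values: np.ndarray, probe_ids: list[str],
                   probe_to_gene: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """Average microarray probe rows that map to the same gene.

    Genes are ordered by first occurrence among the probes.  Every probe
    must map to exactly one gene.
    """
    probe_values = np.asarray(probe_values, dtype=float)
    unmapped = [p for p in probe_ids if p not in probe_to_gene]
    if unmapped:
        raise ValueError(f"probes with no gene mapping: {unmapped}")
    genes: list[str] = []
    rows: dict[str, list[int]] = {}
    for i, p in enumerate(probe_ids):
        g = probe_to_gene[p]
        if g not in rows:
            rows[g] = []
            genes.append(g)
        rows[g].append(i)
    out = np.vstack([probe_values[rows[g]].mean(axis=0) for g in genes])
    return out, genes


def _pooled_reference(tensor: ExpressionTensor) -> np.ndarray:
    """Mean of order statistics across genes with full observation length.

    Genes can have unequal observed counts (whole tissues missing), so the
    reference is built at the maximum observed length and genes with fewer
    observations draw from it by linear interpolation of its quantile
    function.
    """
    obs = tensor.observed
    counts = obs.sum(axis=(0, 1))
    n_ref = int(counts.max())
    grid = np.linspace(0.0, 1.0, n_ref)
    acc = np.zeros(n_ref)
    used = 0
    for g in range(tensor.shape[2]):
        vals = tensor.values[:, :, g][obs[:, :, g]]
        if vals.size < 1:
            continue
        srt = np.sort(vals)
        if srt.size == n_ref:
            acc += srt
        else:
            acc += np.interp(grid, np.linspace(0.0, 1.0, srt.size), srt)
        used += 1
    if used == 0:
        raise ValueError("no observed values in tensor")
    return acc / used


def quantile_normalize_per_gene(tensor: ExpressionTensor) -> ExpressionTensor:
    """Quantile-normalize each gene across all (subject, tissue) cells.

    Each gene's observed values are replaced by rank-assigned values from
    the pooled reference distribution (ties get the mean of the tied
    reference values).  Missing cells are untouched; all-missing genes are
    skipped with a warning.  Idempotent up to floating tolerance.
    """
    out = tensor.copy()
    ref_full = _pooled_reference(tensor)
    grid_full = np.linspace(0.0, 1.0, ref_full.size)
    skipped = []
    for g in range(tensor.shape[2]):
        mask = tensor.observed[:, :, g]
        vals = tensor.values[:, :, g][mask]
        n = vals.size
        if n == 0:
            skipped.append(tensor.gene_ids[g])
            continue
        if n == ref_full.size:
            ref = ref_full
        else:
            ref = np.interp(np.linspace(0.0, 1.0, n), grid_full, ref_full)
        order = np.argsort(vals, kind="stable")
        ranks = np.empty(n)
        ranks[order] = np.arange(n, dtype=float)
        # average reference values over tied observations
        new = ref[ranks.astype(int)]
        uniq, inv = np.unique(vals, return_inverse=True)
        if uniq.size < n:
            sums = np.bincount(inv, weights=new)
            cnts = np.bincount(inv)
            new = (sums / cnts)[inv]
        plane = out.values[:, :, g]
        plane[mask] = new
        out.values[:, :, g] = plane
    if skipped:
        log.warning("quantile normalization skipped %d all-missing genes: %s",
                    len(skipped), skipped[:5])
    out.meta["quantile_normalized"] = True
    return out


def intersect_genes(ids_a: list[str], ids_b: list[str]) -> list[str]:
    """Intersection of two gene lists, ordered by ``ids_a``."""
    in_b = set(ids_b)
    seen: set[str] = set()
    out = []
    for g in ids_a:
        if g in in_b and g not in seen:
            out.append(g)
            seen.add(g)
    return out


# ---------------------------------------------------------------------------
# I/O: long-format and wide GCT-like TSV

def write_expression_long(tensor: ExpressionTensor, path) -> None:
    """Write observed cells as TSV (subject_id, tissue_id, gene_id, value)."""
    subs, tiss, genes = np.nonzero(tensor.observed)
    df = pd.DataFrame({
        "subject_id": [tensor.subject_ids[i] for i in subs],
        "tissue_id": [tensor.tissue_ids[i] for i in tiss],
        "gene_id": [tensor.gene_ids[i] for i in genes],
        "value": tensor.values[subs, tiss, genes],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_expression_long(path) -> ExpressionTensor:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"subject_id": str, "tissue_id": str,
                            "gene_id": str})
    subjects = list(dict.fromkeys(df["subject_id"]))
    tissues = list(dict.fromkeys(df["tissue_id"]))
    genes = list(dict.fromkeys(df["gene_id"]))
    si = {s: i for i, s in enumerate(subjects)}
    ti = {t: i for i, t in enumerate(tissues)}
    gi = {g: i for i, g in enumerate(genes)}
    values = np.zeros((len(subjects), len(tissues), len(genes)))
    observed = np.zeros_like(values, dtype=bool)
    values[df["subject_id"].map(si), df["tissue_id"].map(ti),
           df["gene_id"].map(gi)] = df["value"].to_numpy()
    observed[df["subject_id"].map(si), df["tissue_id"].map(ti),
             df["gene_id"].map(gi)] = True
    return ExpressionTensor(values, observed, subjects, tissues, genes)


def write_expression_wide(tensor: ExpressionTensor, path) -> None:
    """Genes x samples TSV with columns named ``subject|tissue``."""
    cols = {}
    cell_obs = tensor.cell_observed()
    for i, s in enumerate(tensor.subject_ids):
        for j, t in enumerate(tensor.tissue_ids):
            if cell_obs[i, j]:
                cols[f"{s}|{t}"] = tensor.values[i, j, :]
    pd.DataFrame(cols, index=pd.Index(tensor.gene_ids, name="gene_id")).to_csv(
        path, sep="\t", float_format="%.17g")


def read_expression_wide(path) -> ExpressionTensor:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    genes = [str(g) for g in df.index]
    subjects: list[str] = []
    tissues: list[str] = []
    for col in df.columns:
        s, t = col.split("|", 1)
        if s not in subjects:
            subjects.append(s)
        if t not in tissues:
            tissues.append(t)
    values = np.zeros((len(subjects), len(tissues), len(genes)))
    observed = np.zeros_like(values, dtype=bool)
    for col in df.columns:
        s, t = col.split("|", 1)
        values[subjects.index(s), tissues.index(t), :] = df[col].to_numpy()
        observed[subjects.index(s), tissues.index(t), :] = True
    return ExpressionTensor(values, observed, subjects, tissues, genes)
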