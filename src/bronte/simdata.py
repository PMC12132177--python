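"""Synthetic data generators.

These emulate the statistical structure the imputation model assumes, so
every pipeline stage is testable without restricted downloads: tissue
expression is Brownian motion along the ontology tree (so nearby tissues
correlate), each gene carries a stability parameter rho_g in [0, 1] mixing
a shared archetype pattern with per-subject patterns (so differential
stability is planted and recoverable), subjects get per-gene scalar
shifts, genotypes come in LD blocks, and cis effects plus paired GWAS
summary statistics with shared or distinct causal variants are injected on
top.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ontology import BrainOntology
from .preprocess import ExpressionTensor

__all__ = [
    "SimConfig",
    "simulate_ontology",
    "simulate_expression",
    "simulate_genotypes",
    "inject_eqtl_effects",
    "simulate_gwas_summary",
    "mask_tissues",
]


@dataclass
class SimConfig:
    """Desk-scale defaults: a depth-4 binary tree (31 nodes, 16 leaves)
    partitioned into 6 composites; 6 atlas and 40 cohort subjects; 200
    genes; 500 variants."""

    depth: int = 4
    branching: int = 2
    n_composites: int = 6
    n_atlas_subjects: int = 6
    n_cohort_subjects: int = 40
    n_genes: int = 200
    n_variants: int = 500
    archetype_step: float = 0.5   # Brownian step SD per tree edge (shared pattern)
    subject_step: float = 0.5     # Brownian step SD (per-subject pattern)
    subject_signal_fraction: float = 0.5  # weight of the per-(subject, gene) shift
    noise_sd: float = 0.3
    stability: str = "uniform"    # rho_g ~ U[0, 1]
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subject_signal_fraction",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def simulate_ontology(depth: int, branching: int, n_composites: int,
                      seed: int = 0) -> BrainOntology:
    """Balanced tree of the given depth/branching; leaves partitioned into
    ``n_composites`` contiguous composite groups."""
    if depth < 1 or branching < 2:
        raise ValueError("need depth >= 1 and branching >= 2")
    nodes = [{"id": "t0", "name": "root", "level": 0, "parent": None}]
    frontier = ["t0"]
    counter = 1
    for level in range(1, depth + 1):
        new_frontier = []
        for parent in frontier:
            for _ in range(branching):
                nid = f"t{counter}"
                counter += 1
                nodes.append({"id": nid, "name": f"tissue {nid}",
                              "level": level, "parent": parent})
                new_frontier.append(nid)
        frontier = new_frontier
    leaves = frontier
    if n_composites > len(leaves):
        raise ValueError(f"{n_composites} composites > {len(leaves)} leaves")
    bounds = np.linspace(0, len(leaves), n_composites + 1).astype(int)
    composites = {f"c{k}": leaves[bounds[k]:bounds[k + 1]]
                  for k in range(n_composites)}
    return BrainOntology(nodes=nodes, leaf_ids=leaves, composite_map=composites)


def _brownian_on_tree(ont: BrainOntology, step: float,
                      rng: np.random.Generator, size: int) -> np.ndarray:
    """``size`` independent Brownian patterns over all nodes (root at 0);
    returns size x n_leaves restricted to leaves."""
    vals = np.zeros((size, ont.n_nodes))
    order = sorted(range(ont.n_nodes),
                   key=lambda i: ont.nodes[i]["level"])
    for i in order:
        parent = ont.nodes[i]["parent"]
        if parent is None:
            continue
        p = ont.node_index(parent)
        vals[:, i] = vals[:, p] + rng.normal(0.0, step, size=size)
    leaf_cols = [ont.node_index(l) for l in ont.leaf_ids]
    return vals[:, leaf_cols]


def simulate_expression(ont: BrainOntology, config: SimConfig,
                        n_subjects: int | None = None,
                        seed: int | None = None):
    """Leaf-level expression tensor plus the generating truth record.

    Per gene g: archetype a_g is Brownian motion along the tree.  Per
    subject s: x(s, t, g) = rho_g * a_g(t) + (1 - rho_g) * b_{s,g}(t)
    + subject_signal_fraction * u_{s,g} + Normal(0, noise_sd^2), with b an
    independent per-subject Brownian pattern and u a per-(subject, gene)
    standard-normal scalar shift.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_s = config.n_atlas_subjects if n_subjects is None else n_subjects
    n_g, n_l = config.n_genes, ont.n_leaves

    archetypes = _brownian_on_tree(ont, config.archetype_step, rng, n_g)  # g x l
    rho = rng.uniform(0.0, 1.0, size=n_g) if config.stability == "uniform" \
        else np.full(n_g, float(config.stability))
    u = rng.normal(0.0, 1.0, size=(n_s, n_g))
    values = np.empty((n_s, n_l, n_g))
    for s in range(n_s):
        b = _brownian_on_tree(ont, config.subject_step, rng, n_g)  # g x l
        x = (rho[:, None] * archetypes + (1.0 - rho[:, None]) * b).T  # l x g
        x = x + config.subject_signal_fraction * u[s][None, :]
        x = x + rng.normal(0.0, config.noise_sd, size=(n_l, n_g))
        values[s] = x
    gene_ids = [f"g{i}" for i in range(n_g)]
    subject_ids = [f"s{i}" for i in range(n_s)]
    tensor = ExpressionTensor(values, np.ones_like(values, dtype=bool),
                              subject_ids, list(ont.leaf_ids), gene_ids)
    truth = {"archetypes": archetypes, "rho": rho, "u": u,
             "gene_ids": gene_ids, "subject_ids": subject_ids}
    return tensor, truth


def simulate_genotypes(n_subjects: int, n_variants: int,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       ld_blocks: int = 50, flip_prob: float = 0.1,
                       seed: int = 0, chrom: str = "1",
                       spacing_bp: int = 1000):
    """Block-correlated diploid dosages on one synthetic chromosome.

    Within a block every variant copies a latent haplotype pair with
    per-haplotype allele flips at ``flip_prob`` (0 gives within-block
    r^2 = 1); blocks are independent.
    """
    from .genetics import GenotypeMatrix
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    bounds = np.linspace(0, n_variants, ld_blocks + 1).astype(int)
    dosages = np.empty((n_subjects, n_variants), dtype=float)
    for k in range(ld_blocks):
        lo_v, hi_v = bounds[k], bounds[k + 1]
        width = hi_v - lo_v
        if width == 0:
            continue
        maf = rng.uniform(lo, hi)
        h1 = rng.random(n_subjects) < maf
        h2 = rng.random(n_subjects) < maf
        for j in range(lo_v, hi_v):
            f1 = rng.random(n_subjects) < flip_prob
            f2 = rng.random(n_subjects) < flip_prob
            dosages[:, j] = (h1 ^ f1).astype(int) + (h2 ^ f2).astype(int)
    alleles = np.array(["A", "C", "G", "T"])
    ea = rng.integers(0, 4, size=n_variants)
    oa = (ea + rng.integers(1, 4, size=n_variants)) % 4
    variants = pd.DataFrame({
        "id": [f"v{i}" for i in range(n_variants)],
        "chrom": chrom,
        "pos": np.arange(1, n_variants + 1) * spacing_bp,
        "effect_allele": alleles[ea],
        "other_allele": alleles[oa],
    })
    return GenotypeMatrix(dosages, variants, [f"s{i}" for i in range(n_subjects)])


def inject_eqtl_effects(expr: ExpressionTensor, geno, plan: list[dict]):
    """Add planned additive cis effects to an expression tensor.

    Each plan entry: {"variant": id, "gene": id, "tissues": [tissue ids]
    or "all", "beta": float}.  Subjects are matched by position (the
    tensor and genotype matrix must describe the same subjects in order).
    Returns (modified tensor, truth plan).
    """
    out = expr.copy()
    vid_col = {v: i for i, v in enumerate(geno.variants["id"])}
    for entry in plan:
        if entry["variant"] not in vid_col:
            raise KeyError(f"unknown variant {entry['variant']!r}")
        if entry["gene"] not in expr.gene_ids:
            raise KeyError(f"unknown gene {entry['gene']!r}")
        g = expr.gene_ids.index(entry["gene"])
        dosage = geno.dosages[:, vid_col[entry["variant"]]]
        tissues = entry.get("tissues", "all")
        t_idx = (range(len(expr.tissue_ids)) if tissues == "all"
                 else [expr.tissue_ids.index(t) for t in tissues])
        for t in t_idx:
            out.values[:, t, g] += entry["beta"] * dosage
    return out, {"plan": plan}


def simulate_gwas_summary(geno, plan: dict, seed: int = 0):
    """Marginal GWAS summary statistics for one simulated trait.

    ``plan``: {"trait": id, "trait_type": "quantitative"|"binary",
    "causal": {variant_id: effect}}.  Phenotype y = sum theta_v dosage_v
    + N(0, 1); per-variant marginal OLS beta/se/p over all variants.
    """
    from .genetics import GwasStat
    from scipy.stats import t as t_dist
    rng = np.random.default_rng(seed)
    n, m = geno.dosages.shape
    vid_col = {v: i for i, v in enumerate(geno.variants["id"])}
    y = rng.normal(0.0, 1.0, size=n)
    for v, theta in plan.get("causal", {}).items():
        if v not in vid_col:
            raise KeyError(f"unknown causal variant {v!r}")
        y = y + theta * geno.dosages[:, vid_col[v]]
    xc = geno.dosages - geno.dosages.mean(axis=0)
    sxx = (xc ** 2).sum(axis=0)
    yc = y - y.mean()
    syy = float((yc ** 2).sum())
    ok = sxx > 0
    beta = np.zeros(m)
    beta[ok] = (xc[:, ok] * yc[:, None]).sum(axis=0) / sxx[ok]
    sse = np.maximum(syy - beta ** 2 * sxx, 0.0)
    se = np.full(m, np.nan)
    se[ok] = np.sqrt(np.maximum(sse[ok] / (n - 2) / sxx[ok], 1e-300))
    p = np.ones(m)
    p[ok] = np.maximum(2.0 * t_dist.sf(np.abs(beta[ok] / se[ok]), df=n - 2), 1e-300)
    stats = []
    for j in range(m):
        if not ok[j]:
            continue
        stats.append(GwasStat(
            variant_id=str(geno.variants["id"].iloc[j]), beta=float(beta[j]),
            se=float(se[j]), p=float(p[j]), trait_id=plan["trait"],
            trait_type=plan.get("trait_type", "quantitative"), n=n,
            effect_allele=str(geno.variants["effect_allele"].iloc[j]),
            other_allele=str(geno.variants["other_allele"].iloc[j])))
    return stats


def mask_tissues(expr: ExpressionTensor, pattern, seed: int = 0,
                 min_observed: int = 1) -> ExpressionTensor:
    """Mask whole composite tissues per subject.

    ``pattern`` is either ``("random-k", k)`` — mask k uniformly chosen
    tissues per subject — or ``("fixed-list", [tissue ids])``.  Never
    leaves a subject below ``min_observed`` observed tissues.
    """
    out = expr.copy()
    n_s, n_t, _ = expr.shape
    rng = np.random.default_rng(seed)
    kind = pattern[0]
    if kind == "random-k":
        k = int(pattern[1])
        if n_t - k < min_observed:
            raise ValueError(f"masking {k} of {n_t} tissues violates "
                             f"min_observed={min_observed}")
        for s in range(n_s):
            drop = rng.choice(n_t, size=k, replace=False)
            out.observed[s, drop, :] = False
    elif kind == "fixed-list":
        drop = [expr.tissue_ids.index(t) for t in pattern[1]]
        if n_t - len(drop) < min_observed:
            raise ValueError("fixed-list mask violates min_observed")
        out.observed[:, drop, :] = False
    else:
        raise ValueError(f"unknown mask pattern {kind!r}")
    return out

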