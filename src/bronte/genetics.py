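"""Genetic downstream analyses.

The discovery chain runs: additive-model cis-eQTL scan with per-gene
permutation p-values, greedy LD clumping to lead variants, cross-tissue
effect-sharing statistics, single-instrument Wald-ratio Mendelian
randomization with Benjamini-Hochberg FDR over the full variant x tissue x
trait family, and Wakefield approximate-Bayes-factor colocalization under
two prior configurations.  Gene-set overlap uses the exact upper-tail
hypergeometric test; trait-by-region enrichment uses a one-sided Fisher
exact test on the collapsed 2x2 table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import fisher_exact, hypergeom, norm
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "EqtlRecord",
    "GwasStat",
    "MrResult",
    "ColocResult",
    "cis_eqtl_scan",
    "ld_clump",
    "sharing_by_sign",
    "sharing_by_magnitude",
    "pairwise_sharing_matrix",
    "wald_ratio_mr",
    "harmonize",
    "bh_fdr",
    "coloc_abf",
    "hypergeom_overlap_test",
    "trait_region_enrichment",
    "tissue_specific_hits",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class GenotypeMatrix:
    """Subjects x variants dosage matrix with variant metadata."""

    dosages: np.ndarray
    variants: pd.DataFrame  # columns: id, chrom, pos, effect_allele, other_allele
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, float)
        if self.dosages.shape != (len(self.subject_ids), len(self.variants)):
            raise ValueError("dosage shape does not match subjects x variants")
        if not np.isfinite(self.dosages).all():
            raise ValueError("non-finite dosages")
        if (self.dosages < 0).any() or (self.dosages > 2).any():
            raise ValueError("dosages must lie in [0, 2]")
        if self.variants["id"].duplicated().any():
            raise ValueError("duplicate variant ids")
        if (self.variants["pos"] < 0).any():
            raise ValueError("negative positions")

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"unknown variant {variant_id!r}")
        return self.dosages[:, self.variants.index.get_loc(idx[0])]

    @classmethod
    def from_tsv(cls, dosage_path, variants_path) -> "GenotypeMatrix":
        dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
        var = pd.read_csv(variants_path, sep="\t", dtype={"id": str, "chrom": str})
        return cls(dos.to_numpy(), var.reset_index(drop=True),
                   [str(s) for s in dos.index])

    def to_tsv(self, dosage_path, variants_path) -> None:
        pd.DataFrame(self.dosages, index=pd.Index(self.subject_ids, name="subject_id"),
                     columns=self.variants["id"]).to_csv(dosage_path, sep="\t")
        self.variants.to_csv(variants_path, sep="\t", index=False)


@dataclass
class EqtlRecord:
    variant_id: str
    gene_id: str
    tissue_id: str
    beta: float
    se: float
    p_nominal: float
    p_gene: float | None = None
    effect_allele: str | None = None
    other_allele: str | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")


@dataclass
class GwasStat:
    variant_id: str
    beta: float
    se: float
    p: float
    trait_id: str
    trait_type: str = "quantitative"  # or "binary"
    n: int | None = None
    effect_allele: str | None = None
    other_allele: str | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError("trait_type must be quantitative or binary")


@dataclass
class MrResult:
    variant_id: str
    gene_id: str
    tissue_id: str
    trait_id: str
    wald_beta: float
    wald_se: float
    p: float
    q: float | None = None


@dataclass
class ColocResult:
    """Posteriors over the five causal configurations, per prior setting."""

    posteriors: dict[str, dict[str, float]]  # config name -> {PP0..PP4}
    priors: dict[str, tuple[float, float, float]]
    n_variants: int
    colocalized: bool = field(init=False)

    def __post_init__(self) -> None:
        for name, pp in self.posteriors.items():
            total = sum(pp.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"posteriors for {name} sum to {total}")
        self.colocalized = max(pp["PP4"] for pp in self.posteriors.values()) > 0.7


# ---------------------------------------------------------------------------
# cis-eQTL scan

def cis_eqtl_scan(geno: GenotypeMatrix, expr: np.ndarray, gene_ids: list[str],
                  gene_positions: dict[str, tuple[str, int]],
                  tissue_id: str = "tissue", window_bp: int = 1_000_000,
                  n_perm: int = 0, seed: int = 0) -> list[EqtlRecord]:
    """Additive-model cis scan: per (gene, cis variant) OLS of expression on
    dosage with a t-test nominal p, plus an optional per-gene min-p
    permutation p-value (expression shuffled across subjects).

    A deliberately plain reimplementation of the standard cis-eQTL testing
    logic — no adaptive permutations or beta-approximated tails.
    """
    expr = np.asarray(expr, float)
    n = expr.shape[0]
    if n < 10:
        raise ValueError("need >= 10 subjects for the eQTL scan")
    if expr.shape != (n, len(gene_ids)) or len(geno.subject_ids) != n:
        raise ValueError("expression must be subjects x genes matched to genotypes")
    rng = np.random.default_rng(seed)
    var = geno.variants
    positions = var["pos"].to_numpy()
    chroms = var["chrom"].to_numpy()
    dos = geno.dosages
    mono = dos.std(axis=0) == 0
    n_mono = int(mono.sum())
    if n_mono:
        log.info("eQTL scan: %d monomorphic variants skipped", n_mono)

    records: list[EqtlRecord] = []
    perms = [rng.permutation(n) for _ in range(n_perm)]
    for gi, gene in enumerate(gene_ids):
        if gene not in gene_positions:
            continue
        chrom, pos = gene_positions[gene]
        in_cis = (chroms == chrom) & (np.abs(positions - pos) <= window_bp) & ~mono
        cols = np.nonzero(in_cis)[0]
        if cols.size == 0:
            continue
        X = dos[:, cols]
        xc = X - X.mean(axis=0)
        sxx = (xc ** 2).sum(axis=0)

        def stats_for(y: np.ndarray):
            yc = y - y.mean()
            syy = float((yc ** 2).sum())
            beta = (xc * yc[:, None]).sum(axis=0) / sxx
            sse = np.maximum(syy - beta ** 2 * sxx, 0.0)
            sigma2 = sse / (n - 2)
            se = np.sqrt(np.maximum(sigma2 / sxx, 1e-300))
            tstat = beta / se
            p = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
            return beta, se, np.maximum(p, 1e-300)

        beta, se, p = stats_for(expr[:, gi])
        p_gene = None
        if n_perm > 0:
            obs_min = p.min()
            hits = 0
            for perm in perms:
                _, _, pp = stats_for(expr[perm, gi])
                if pp.min() <= obs_min:
                    hits += 1
            p_gene = (1 + hits) / (1 + n_perm)
        ea = var["effect_allele"].to_numpy() if "effect_allele" in var else [None] * len(var)
        oa = var["other_allele"].to_numpy() if "other_allele" in var else [None] * len(var)
        for k, c in enumerate(cols):
            records.append(EqtlRecord(
                variant_id=str(var["id"].iloc[c]), gene_id=gene,
                tissue_id=tissue_id, beta=float(beta[k]), se=float(se[k]),
                p_nominal=float(p[k]), p_gene=p_gene,
                effect_allele=ea[c], other_allele=oa[c]))
    return records


# ---------------------------------------------------------------------------
# LD clumping

def ld_clump(pvals: dict[str, float], geno: GenotypeMatrix,
             window_bp: int = 10_000_000, r2_max: float = 0.001) -> list[str]:
    """Greedy lead-variant selection.

    Repeatedly takes the unclaimed variant with the smallest p (ties by
    variant id), then removes every variant within ``window_bp`` whose
    dosage r-squared with the lead exceeds ``r2_max``.
    """
    var = geno.variants.set_index("id")
    order = sorted(pvals, key=lambda v: (pvals[v], v))
    dos = geno.dosages
    col = {vid: i for i, vid in enumerate(geno.variants["id"])}
    std = dos.std(axis=0)
    zc = dos - dos.mean(axis=0)
    claimed: set[str] = set()
    leads: list[str] = []
    for vid in order:
        if vid in claimed:
            continue
        leads.append(vid)
        claimed.add(vid)
        i = col[vid]
        pos_i, chrom_i = var.at[vid, "pos"], var.at[vid, "chrom"]
        for other in order:
            if other in claimed:
                continue
            j = col[other]
            if var.at[other, "chrom"] != chrom_i:
                continue
            if abs(var.at[other, "pos"] - pos_i) > window_bp:
                continue
            if std[i] == 0 or std[j] == 0:
                continue
            r = float(zc[:, i] @ zc[:, j]) / (len(zc) * std[i] * std[j])
            if r * r > r2_max:
                claimed.add(other)
    return leads


# ---------------------------------------------------------------------------
# cross-tissue sharing

def _reference_index(effects: np.ndarray) -> int:
    finite = np.isfinite(effects)
    if not finite.any():
        raise ValueError("no finite effects")
    masked = np.where(finite, np.abs(effects), -np.inf)
    return int(np.argmax(masked))


def sharing_by_sign(effects) -> int | None:
    """Tissues whose effect shares the sign of the strongest-|beta| tissue.

    Zero effects count as not shared; an all-zero vector is undefined
    (returns None).
    """
    effects = np.asarray(effects, float)
    ref = _reference_index(effects)
    if effects[ref] == 0:
        return None
    sign = np.sign(effects[ref])
    return int(np.sum(np.isfinite(effects) & (np.sign(effects) == sign)))


def sharing_by_magnitude(effects) -> int | None:
    """Tissues sharing the reference sign with |beta| within a factor two."""
    effects = np.asarray(effects, float)
    ref = _reference_index(effects)
    b = effects[ref]
    if b == 0:
        return None
    sign = np.sign(b)
    mag = np.abs(effects)
    ok = (np.isfinite(effects) & (np.sign(effects) == sign)
          & (mag >= np.abs(b) / 2) & (mag <= np.abs(b) * 2))
    return int(ok.sum())


def pairwise_sharing_matrix(effect_table: np.ndarray) -> np.ndarray:
    """Fraction of lead eQTLs shared by magnitude for each tissue pair.

    ``effect_table`` is lead eQTLs x tissues; entry (i, j) is the fraction
    of rows with the same sign in i and j and magnitude ratio within a
    factor two.  The diagonal is 1; pairs without any jointly finite row
    are NaN.
    """
    e = np.asarray(effect_table, float)
    n_t = e.shape[1]
    out = np.full((n_t, n_t), np.nan)
    for i in range(n_t):
        out[i, i] = 1.0
        for j in range(i + 1, n_t):
            a, b = e[:, i], e[:, j]
            ok = np.isfinite(a) & np.isfinite(b)
            if not ok.any():
                continue
            a, b = a[ok], b[ok]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.abs(a) / np.abs(b)
            shared = (np.sign(a) == np.sign(b)) & (a != 0) & (b != 0) \
                & (ratio >= 0.5) & (ratio <= 2.0)
            out[i, j] = out[j, i] = float(shared.mean())
    return out


# ---------------------------------------------------------------------------
# MR

def wald_ratio_mr(exposure: EqtlRecord, outcome: GwasStat) -> MrResult:
    """Single-instrument Wald ratio: outcome effect per unit exposure effect.

    The standard error uses the first-order delta method (exposure
    uncertainty ignored); p from the normal approximation.
    """
    if exposure.beta == 0:
        raise ValueError("exposure effect is zero; Wald ratio undefined")
    wb = outcome.beta / exposure.beta
    ws = abs(outcome.se / exposure.beta)
    p = float(2.0 * norm.sf(abs(wb / ws)))
    return MrResult(exposure.variant_id, exposure.gene_id, exposure.tissue_id,
                    outcome.trait_id, wald_beta=wb, wald_se=ws, p=max(p, 1e-300))


def harmonize(exposure: EqtlRecord, outcome: GwasStat):
    """Align outcome effect alleles to the exposure orientation.

    Forward-strand-only semantics: swapped effect/other alleles negate the
    outcome beta; incompatible allele sets drop the pair (returns None);
    palindromic (A/T or C/G) pairs pass through with a warning.
    """
    ea_e, oa_e = exposure.effect_allele, exposure.other_allele
    ea_o, oa_o = outcome.effect_allele, outcome.other_allele
    if None in (ea_e, oa_e, ea_o, oa_o):
        raise ValueError("both records must carry effect and other alleles")
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    if oa_e == comp.get(ea_e):
        log.warning("palindromic alleles %s/%s at %s passed through unchanged",
                    ea_e, oa_e, exposure.variant_id)
    if (ea_o, oa_o) == (ea_e, oa_e):
        return exposure, outcome
    if (ea_o, oa_o) == (oa_e, ea_e):
        flipped = GwasStat(outcome.variant_id, -outcome.beta, outcome.se,
                           outcome.p, outcome.trait_id, outcome.trait_type,
                           outcome.n, ea_e, oa_e)
        return exposure, flipped
    log.info("dropping %s: allele sets %s/%s vs %s/%s incompatible",
             exposure.variant_id, ea_e, oa_e, ea_o, oa_o)
    return None


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over one joint test family."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# colocalization

def _log_abf(beta: np.ndarray, se: np.ndarray, w: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor per variant."""
    se2 = se ** 2
    r = w ** 2 / (w ** 2 + se2)
    z2 = (beta / se) ** 2
    return 0.5 * (np.log1p(-r) + r * z2)


def coloc_abf(region1: list[GwasStat], region2: list[GwasStat],
              priors: dict[str, tuple[float, float, float]] | None = None,
              prior_sd: dict[str, float] | None = None) -> ColocResult:
    """Approximate-Bayes-factor colocalization of two association regions.

    Evidence for the five hypotheses (no signal / trait-1 only / trait-2
    only / two distinct causal variants / one shared causal variant) is
    accumulated from per-variant Wakefield log-ABFs on the intersection of
    the two regions' variants, then combined with per-hypothesis priors.
    Two prior configurations are evaluated by default: the fixed setting
    (p1 = p2 = 1e-4, p12 = 1e-5) and the region-size setting
    (p1 = p2 = 1/n_variants, p12 = p1/10).  ``colocalized`` is true when
    either configuration gives PP4 > 0.7.

    The prior effect standard deviation is 0.15 for quantitative and 0.2
    for binary traits.
    """
    sd_default = {"quantitative": 0.15, "binary": 0.2}
    sd_map = sd_default | (prior_sd or {})
    d1 = {r.variant_id: r for r in region1}
    d2 = {r.variant_id: r for r in region2}
    common = [v for v in d1 if v in d2]
    if not common:
        raise ValueError("regions share no variants")
    for r in list(d1.values()) + list(d2.values()):
        if r.se <= 0:
            raise ValueError("standard errors must be positive")
    b1 = np.array([d1[v].beta for v in common])
    s1 = np.array([d1[v].se for v in common])
    b2 = np.array([d2[v].beta for v in common])
    s2 = np.array([d2[v].se for v in common])
    w1 = sd_map[region1[0].trait_type]
    w2 = sd_map[region2[0].trait_type]
    l1 = _log_abf(b1, s1, w1)
    l2 = _log_abf(b2, s2, w2)
    n_v = len(common)

    if priors is None:
        p1 = 1.0 / n_v
        priors = {"default": (1e-4, 1e-4, 1e-5),
                  "region_size": (p1, p1, p1 / 10.0)}

    sum1 = logsumexp(l1)
    sum2 = logsumexp(l2)
    sum12 = logsumexp(l1 + l2)
    # H3 over ordered distinct pairs: S1*S2 - sum_i ABF1_i*ABF2_i, in logs
    diff = sum12 - (sum1 + sum2)
    if diff >= 0:
        l_h3_core = -np.inf
    else:
        l_h3_core = sum1 + sum2 + np.log1p(-np.exp(diff))

    posteriors = {}
    for name, (p1, p2, p12) in priors.items():
        lh = np.array([
            0.0,
            np.log(p1) + sum1,
            np.log(p2) + sum2,
            (np.log(p1) + np.log(p2) + l_h3_core) if np.isfinite(l_h3_core) else -np.inf,
            np.log(p12) + sum12,
        ])
        pp = np.exp(lh - logsumexp(lh))
        pp /= pp.sum()
        posteriors[name] = {f"PP{i}": float(pp[i]) for i in range(5)}
    return ColocResult(posteriors=posteriors, priors=dict(priors), n_variants=n_v)


# ---------------------------------------------------------------------------
# overlap and enrichment

def hypergeom_overlap_test(universe: int, set_a: int, set_b: int,
                           overlap: int) -> float:
    """Exact upper-tail hypergeometric overlap p-value, P(X >= overlap).

    Draws ``set_a`` genes from a universe of ``universe`` containing
    ``set_b`` successes.  Computed in log space.
    """
    if not (0 <= overlap <= min(set_a, set_b) <= universe):
        raise ValueError("require 0 <= overlap <= min(set_a, set_b) <= universe")
    if overlap == 0:
        return 1.0
    ks = np.arange(overlap, min(set_a, set_b) + 1)
    logs = hypergeom.logpmf(ks, universe, set_b, set_a)
    return float(min(np.exp(logsumexp(logs)), 1.0))


def trait_region_enrichment(table) -> tuple[float, float]:
    """One-sided (greater) Fisher exact test on a 2x2 count table.

    Returns (odds ratio, p).  The odds ratio is the sample OR; inf when the
    off-diagonal has a zero.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    res = fisher_exact(t, alternative="greater")
    return float(res[0]), float(res[1])


def tissue_specific_hits(results: pd.DataFrame, q_threshold: float = 0.05
                         ) -> pd.DataFrame:
    """Filter (variant, gene) pairs significant in exactly one tissue.

    ``results`` needs columns variant_id, gene_id, tissue_id, q,
    colocalized.  A pair is tissue-specific when (q < threshold AND
    colocalized) holds in exactly one tissue.
    """
    sig = results[(results["q"] < q_threshold) & results["colocalized"]]
    counts = sig.groupby(["variant_id", "gene_id"])["tissue_id"].nunique()
    keep = counts[counts == 1].index
    return sig.set_index(["variant_id", "gene_id"]).loc[keep].reset_index()
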