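"""Synthetic two-trait GWAS generator.

Emulates the standard simulation design for summary-statistic PRS methods:
genotypes drawn under Hardy-Weinberg equilibrium (optionally with local
first-order LD), two overlapping 10%-of-genome annotations, sparse causal
architectures with a tunable fraction of causal variants shared between the
two traits (shared positions, independently drawn effect values), additive
phenotypes at a target heritability, and marginal summary statistics
beta_tilde = X'Y / N computed on standardized data. Every stage of the real
pipeline can therefore be exercised, and written through the same PLINK/TSV
formats the pipeline reads, without any external data.

Causal variants are allocated in thirds: one third from annotation A1, one
third from A2, one third from the complement of their union.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .plink import GenotypePanel
from .sumstats import SummaryStats

_CHUNK = 512  # SNP-column chunk for genotype generation / matmuls


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic two-trait experiment.

    Defaults are desk-scale: 5,000 SNPs with 20,000 training samples per
    trait, heritability 0.3 from 300 causal variants per trait, two
    annotations covering 10% of the genome each, and 20% of causal
    variants shared between the traits.
    """

    m: int = 5000
    n1: int = 20000
    n2: int = 20000
    n_test: int = 2000
    h2_1: float = 0.3
    h2_2: float = 0.3
    m1_causal: int = 300
    m2_causal: int = 300
    shared_prop: float = 0.2
    annot_fraction: float = 0.10
    ld_mode: str = "independent"  # or "autoregressive"
    rho_adj: float = 0.0
    n_chrom: int = 1
    overlap_n: int = 0
    overlap_rho_e: float = 0.0
    binary: bool = False
    prevalence: float = 0.5
    shared_effects_correlated: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.h2_1 < 1 and 0 < self.h2_2 < 1):
            raise ValueError("heritabilities must lie in (0, 1)")
        if not 0 <= self.shared_prop <= 1:
            raise ValueError("shared_prop must lie in [0, 1]")
        if max(self.m1_causal, self.m2_causal) > self.m:
            raise ValueError("causal counts cannot exceed M")
        if self.ld_mode not in ("independent", "autoregressive"):
            raise ValueError("ld_mode must be 'independent' or 'autoregressive'")


@dataclass
class SimulatedTruth:
    beta: np.ndarray = field(repr=False)
    gamma: np.ndarray = field(repr=False)
    causal1: np.ndarray
    causal2: np.ndarray
    shared: np.ndarray


@dataclass
class SimulatedStudy:
    ss1: SummaryStats
    ss2: SummaryStats
    test: GenotypePanel  # doubles as LD reference; carries trait-1 phenotype
    annot: AnnotationSet
    y_test1: np.ndarray = field(repr=False)
    y_test2: np.ndarray = field(repr=False)
    truth: SimulatedTruth = None
    train1: GenotypePanel | None = None
    train2: GenotypePanel | None = None


def _snp_frame(m: int, n_chrom: int) -> pd.DataFrame:
    per = int(np.ceil(m / n_chrom))
    chrom = np.repeat([str(c + 1) for c in range(n_chrom)], per)[:m]
    return pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(m)],
        "chrom": chrom,
        "pos": np.arange(1, m + 1) * 1000,
        "a1": "A",
        "a2": "G",
    })


def _gen_genotypes(n, mafs, chroms, cfg: SimulationConfig, rng) -> np.ndarray:
    """HWE genotypes, int8, independent or first-order autoregressive LD.

    In autoregressive mode each haplotype is a copy chain: allele j+1 equals
    allele j with probability rho_adj, else a fresh Bernoulli(maf) draw, so
    the adjacent-haplotype allelic correlation is rho_adj by construction
    (all SNPs on a chromosome share one MAF to keep the target exact).
    """
    m = mafs.size
    g = np.empty((n, m), dtype=np.int8)
    if cfg.ld_mode == "independent":
        for s in range(0, m, _CHUNK):
            e = min(s + _CHUNK, m)
            g[:, s:e] = rng.binomial(2, mafs[s:e], size=(n, e - s)).astype(np.int8)
        return g
    hap = np.empty((2 * n, m), dtype=np.int8)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        f = mafs[idx[0]]
        mc = idx.size
        # draw the full fresh/copy arrays up front through one reused
        # float64 buffer (row-chunked; identical stream to one full draw)
        buf = np.empty((min(_CHUNK, 2 * n), mc))
        fresh = np.empty((2 * n, mc), dtype=bool)
        for s in range(0, 2 * n, _CHUNK):
            e = min(s + _CHUNK, 2 * n)
            rng.random(out=buf[: e - s])
            np.less(buf[: e - s], f, out=fresh[s:e])
        copy = np.empty((2 * n, mc), dtype=bool)
        for s in range(0, 2 * n, _CHUNK):
            e = min(s + _CHUNK, 2 * n)
            rng.random(out=buf[: e - s])
            np.less(buf[: e - s], cfg.rho_adj, out=copy[s:e])
        # allele j is the fresh draw at the latest non-copy position <= j
        # (position 0 is always fresh; its copy flag is unused)
        copy[:, 0] = False
        cols = np.arange(mc, dtype=np.int32)
        for s in range(0, 2 * n, _CHUNK):
            e = min(s + _CHUNK, 2 * n)
            anc = np.where(copy[s:e], np.int32(0), cols[None, :])
            np.maximum.accumulate(anc, axis=1, out=anc)
            hap[s:e, idx] = np.take_along_axis(fresh[s:e], anc, axis=1)
    return (hap[:n] + hap[n:]).astype(np.int8)


def simulate_genotypes(cfg: SimulationConfig, rng=None) -> dict:
    """Generate train/test genotype panels (train panels disjoint unless
    ``overlap_n`` > 0, in which case the first ``overlap_n`` individuals of
    the two training panels are the same people)."""
    rng = rng or np.random.default_rng(cfg.seed)
    snps = _snp_frame(cfg.m, cfg.n_chrom)
    chroms = snps["chrom"].to_numpy()
    if cfg.ld_mode == "autoregressive":
        mafs = np.empty(cfg.m)
        for c in np.unique(chroms):
            idx = chroms == c
            mafs[idx] = rng.uniform(0.05, 0.5)
    else:
        mafs = rng.uniform(0.05, 0.5, size=cfg.m)

    g1 = _gen_genotypes(cfg.n1, mafs, chroms, cfg, rng)
    g2 = _gen_genotypes(cfg.n2, mafs, chroms, cfg, rng)
    if cfg.overlap_n > 0:
        k = min(cfg.overlap_n, cfg.n1, cfg.n2)
        g2[:k] = g1[:k]
    gt = _gen_genotypes(cfg.n_test, mafs, chroms, cfg, rng)

    def panel(g, tag):
        ids = np.array([f"{tag}{i + 1}" for i in range(g.shape[0])])
        return GenotypePanel(ids, snps.copy(), g)

    return {"train1": panel(g1, "tr1_"), "train2": panel(g2, "tr2_"),
            "test": panel(gt, "te_")}


def simulate_annotations(cfg: SimulationConfig, snp_ids, rng=None) -> AnnotationSet:
    """Two annotations each covering ``annot_fraction`` of SNPs, plus baseline."""
    rng = rng or np.random.default_rng(cfg.seed)
    m = len(snp_ids)
    k_size = int(round(cfg.annot_fraction * m))
    mem = np.zeros((m, 2), dtype=np.int8)
    for k in range(2):
        mem[rng.choice(m, size=k_size, replace=False), k] = 1
    return AnnotationSet(np.asarray(snp_ids), mem, ["A1", "A2"])


def _third_split(total: int) -> list[int]:
    base = total // 3
    rem = total - 3 * base
    return [base + (1 if i < rem else 0) for i in range(3)]


def simulate_effects(cfg: SimulationConfig, annot: AnnotationSet, rng=None
                     ) -> SimulatedTruth:
    """Draw causal positions (thirds over A1 / A2 / complement, a fraction
    shared between traits) and i.i.d. N(0, h2/m_causal) effect values."""
    rng = rng or np.random.default_rng(cfg.seed)
    m = len(annot)
    names = annot.names
    a1 = annot.membership[:, names.index("A1")].astype(bool)
    a2 = annot.membership[:, names.index("A2")].astype(bool)
    # strata are disjoint (A1, A2 \ A1, complement of the union) so causal
    # sets have exactly the nominal sizes and never contain duplicates even
    # when the two random annotations overlap
    strata = [np.flatnonzero(a1), np.flatnonzero(a2 & ~a1),
              np.flatnonzero(~(a1 | a2))]

    per1 = _third_split(cfg.m1_causal)
    per2 = _third_split(cfg.m2_causal)
    causal1, causal2, shared_all = [], [], []
    for pool, k1, k2 in zip(strata, per1, per2):
        k_shared = int(round(cfg.shared_prop * min(k1, k2)))
        need = k1 + k2 - k_shared
        if need > pool.size:
            raise ValueError("annotation stratum too small for causal counts")
        pick = rng.choice(pool, size=need, replace=False)
        shared = pick[:k_shared]
        only1 = pick[k_shared:k_shared + (k1 - k_shared)]
        only2 = pick[k_shared + (k1 - k_shared):]
        causal1.append(np.concatenate([shared, only1]))
        causal2.append(np.concatenate([shared, only2]))
        shared_all.append(shared)
    c1 = np.sort(np.concatenate(causal1))
    c2 = np.sort(np.concatenate(causal2))
    shared = np.sort(np.concatenate(shared_all))

    beta = np.zeros(m)
    gamma = np.zeros(m)
    sd1 = np.sqrt(cfg.h2_1 / cfg.m1_causal)
    sd2 = np.sqrt(cfg.h2_2 / cfg.m2_causal)
    beta[c1] = rng.normal(0.0, sd1, size=c1.size)
    gamma[c2] = rng.normal(0.0, sd2, size=c2.size)
    if cfg.shared_effects_correlated and shared.size:
        # stress-test mode: shared positions get identical standardized draws
        gamma[shared] = beta[shared] * (sd2 / sd1)
    return SimulatedTruth(beta, gamma, c1, c2, shared)


def _phenotype(x_std, effects, h2, rng, extra_eps=None):
    g = x_std @ effects.astype(np.float32)
    eps = rng.normal(0.0, np.sqrt(1.0 - h2), size=g.shape[0])
    if extra_eps is not None:
        eps = eps + extra_eps
    return g.astype(np.float64) + eps


def simulate_sumstats(truth: SimulatedTruth, panels: dict,
                      cfg: SimulationConfig, rng=None):
    """Phenotypes and marginal summary statistics for both traits.

    Y = X beta + eps with Var(eps) = 1 - h2 on standardized genotypes;
    beta_tilde = X'Y / N. When training samples overlap and
    ``overlap_rho_e`` != 0, the overlapping individuals' error terms are
    correlated across the two traits. Binary mode thresholds the liability
    at the configured prevalence; summary statistics are always computed
    from the continuous liability.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    x1 = panels["train1"].standardized(dtype=np.float32)
    x2 = panels["train2"].standardized(dtype=np.float32)

    y1 = _phenotype(x1, truth.beta, cfg.h2_1, rng)
    eps2_extra = None
    if cfg.overlap_n > 0 and cfg.overlap_rho_e != 0.0:
        # rebuild trait-2 errors so the overlapping individuals' eps are
        # correlated rho_e with trait 1's
        k = min(cfg.overlap_n, cfg.n1, cfg.n2)
        g1 = (x1 @ truth.beta.astype(np.float32)).astype(np.float64)
        eps1 = y1 - g1
        s2 = np.sqrt(1.0 - cfg.h2_2)
        rho = cfg.overlap_rho_e / np.sqrt((1 - cfg.h2_1) * (1 - cfg.h2_2))
        rho = np.clip(rho, -0.99, 0.99)
        shared_part = np.zeros(cfg.n2)
        shared_part[:k] = rho * eps1[:k] / np.sqrt(1.0 - cfg.h2_1)
        indep_scale = np.ones(cfg.n2)
        indep_scale[:k] = np.sqrt(1.0 - rho**2)
        g2 = (x2 @ truth.gamma.astype(np.float32)).astype(np.float64)
        y2 = g2 + s2 * (shared_part + indep_scale * rng.standard_normal(cfg.n2))
    else:
        y2 = _phenotype(x2, truth.gamma, cfg.h2_2, rng, eps2_extra)

    def make_ss(x, y, n, snps):
        bh = (x.T @ y.astype(np.float32)).astype(np.float64) / n
        t = snps.copy()
        t["beta_hat"] = bh
        t["n"] = n
        return SummaryStats(t)

    ss1 = make_ss(x1, y1, cfg.n1, panels["train1"].snps)
    ss2 = make_ss(x2, y2, cfg.n2, panels["train2"].snps)

    xt = panels["test"].standardized(dtype=np.float32)
    yt1 = _phenotype(xt, truth.beta, cfg.h2_1, rng)
    yt2 = _phenotype(xt, truth.gamma, cfg.h2_2, rng)
    if cfg.binary:
        thr = np.quantile(yt1, 1.0 - cfg.prevalence)
        yt1 = (yt1 > thr).astype(float)
        thr2 = np.quantile(yt2, 1.0 - cfg.prevalence)
        yt2 = (yt2 > thr2).astype(float)
    return ss1, ss2, yt1, yt2


def simulate_study(cfg: SimulationConfig, keep_training: bool = False
                   ) -> SimulatedStudy:
    """End-to-end generation of one synthetic two-trait study."""
    rng = np.random.default_rng(cfg.seed)
    panels = simulate_genotypes(cfg, rng)
    annot = simulate_annotations(cfg, panels["test"].snp_ids, rng)
    truth = simulate_effects(cfg, annot, rng)
    ss1, ss2, yt1, yt2 = simulate_sumstats(truth, panels, cfg, rng)
    test = panels["test"]
    test.phenotype = yt1
    return SimulatedStudy(
        ss1=ss1, ss2=ss2, test=test, annot=annot,
        y_test1=yt1, y_test2=yt2, truth=truth,
        train1=panels["train1"] if keep_training else None,
        train2=panels["train2"] if keep_training else None,
    )
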