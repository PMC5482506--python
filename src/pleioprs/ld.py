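"""LD blocks and (stratified) LD scores from a reference panel.

The genome is tiled with disjoint windows of consecutive SNPs (never
spanning a chromosome boundary); within each window the sample correlation
matrix D_b of standardized reference genotypes stands in for the GWAS LD
matrix. Stratified LD scores l(i, c) — sums of squared correlations between
SNP i and the members of annotation category c within a window — link the
expected association chi-square to the per-category variance components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationSet
from .plink import GenotypePanel

logger = logging.getLogger(__name__)

RIDGE = 1e-6
MIN_REFERENCE_N = 1000  # recommended reference-panel size


def default_radius(m: int) -> int:
    """Window radius in SNPs: M/3000, the usual summary-statistic PRS scale."""
    return max(1, round(m / 3000))


@dataclass
class LDBlock:
    start: int  # index into harmonized SNP order, inclusive
    end: int  # exclusive
    corr: np.ndarray = field(repr=False)  # (end-start, end-start), unit diagonal

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class LDBlockSet:
    blocks: list[LDBlock]
    m: int

    def __post_init__(self) -> None:
        pos = 0
        for b in self.blocks:
            if b.start != pos:
                raise ValueError("blocks must be contiguous and disjoint")
            pos = b.end
            d = b.corr
            if d.shape != (b.size, b.size) or not np.allclose(np.diag(d), 1.0):
                raise ValueError("block correlation matrix malformed")
        if pos != self.m:
            raise ValueError("blocks must cover all SNPs")

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass
class StratifiedLDScores:
    """l(i, c) per SNP and category, plus the unstratified l(i) and its mean."""

    scores: np.ndarray = field(repr=False)  # (M, K), non-negative
    names: list[str] = field(default_factory=list)
    total: np.ndarray = field(default=None, repr=False)  # (M,) single-category l(i)

    @property
    def mean_score(self) -> float:
        return float(self.total.mean())


def build_blocks(
    panel: GenotypePanel, window_snps: int | None = None
) -> LDBlockSet:
    """Tile SNPs into disjoint LD blocks and estimate each block's D_b.

    ``window_snps`` is the per-side radius; blocks hold up to ``2 *
    window_snps`` consecutive SNPs of one chromosome. D_b is (1/N) X'X on
    standardized genotypes with a ridge term (then the diagonal reset to 1)
    so that N*D_b plus any positive prior precision is invertible.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least 2 reference individuals")
    if panel.n_samples < MIN_REFERENCE_N:
        logger.warning(
            "reference panel has %d individuals; at least %d unrelated "
            "individuals of matching ancestry are recommended",
            panel.n_samples, MIN_REFERENCE_N,
        )
    m = panel.m_snps
    radius = default_radius(m) if window_snps is None else int(window_snps)
    if radius < 1:
        raise ValueError("window_snps must be >= 1")
    block_len = 2 * radius

    x = panel.standardized(dtype=np.float32)
    n = panel.n_samples
    chroms = panel.snps["chrom"].to_numpy()

    blocks: list[LDBlock] = []
    start = 0
    while start < m:
        chrom = chroms[start]
        chrom_end = start
        while chrom_end < m and chroms[chrom_end] == chrom:
            chrom_end += 1
        for s in range(start, chrom_end, block_len):
            e = min(s + block_len, chrom_end)
            xb = x[:, s:e].astype(np.float64)
            d = xb.T @ xb / n
            d[np.diag_indices_from(d)] += RIDGE
            d[np.diag_indices_from(d)] = 1.0
            blocks.append(LDBlock(s, e, d))
        start = chrom_end
    return LDBlockSet(blocks, m)


def stratified_ld_scores(
    panel: GenotypePanel,
    annot: AnnotationSet,
    radius_snps: int | None = None,
    adjust: bool = True,
) -> StratifiedLDScores:
    """Compute l(i, c) within a sliding window of ``radius_snps`` per side.

    With ``adjust`` (default) each squared sample correlation is replaced by
    the small-sample bias-adjusted r2 - (1 - r2)/(N - 2); the self term
    (r2 = 1) is always included when SNP i belongs to the category. The
    unstratified score l(i) uses a single whole-genome category over the
    same window.
    """
    if radius_snps is None:
        radius_snps = default_radius(panel.m_snps)
    if radius_snps < 0:
        raise ValueError("radius_snps must be >= 0")
    if not np.array_equal(annot.snp_ids, panel.snp_ids):
        raise ValueError("annotations not aligned to panel SNPs")

    x = panel.standardized(dtype=np.float32)
    n, m = x.shape
    member = annot.membership.astype(np.float64)
    k = member.shape[1]
    chroms = panel.snps["chrom"].to_numpy()

    scores = member.copy()  # self term: adjusted r2 of 1 is exactly 1
    total = np.ones(m)
    for d in range(1, radius_snps + 1):
        if d >= m:
            break
        r = (x[:, :-d] * x[:, d:]).sum(axis=0) / n
        r2 = r.astype(np.float64) ** 2
        if adjust and n > 2:
            r2 = r2 - (1.0 - r2) / (n - 2)
        same_chrom = chroms[:-d] == chroms[d:]
        r2 = np.where(same_chrom, r2, 0.0)
        scores[:-d] += r2[:, None] * member[d:]
        scores[d:] += r2[:, None] * member[:-d]
        total[:-d] += r2
        total[d:] += r2
    # bias adjustment can push a score for a category a SNP is uncorrelated
    # with slightly below zero; scores are sums of squared correlations
    np.maximum(scores, 0.0, out=scores)
    np.maximum(total, 0.0, out=total)
    return StratifiedLDScores(scores, list(annot.names), total)
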