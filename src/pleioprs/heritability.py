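"""Annotation-stratified variance components and per-SNP heritability.

A two-stage moment estimator: (1) stratified LD-score regression of the
association chi-square on per-category LD scores recovers the variance
contributed per SNP by each annotation category (tau_c); (2) the
annotation-additive per-SNP variances sum(tau_c over categories containing
SNP i) are rescaled by a constant C so their total equals an independent
chip-heritability estimate from the same summary statistics. Rescaling
matters because tau is estimated on whichever SNP set is in hand while the
prediction model uses exactly the harmonized SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationSet
from .ld import StratifiedLDScores
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

H2_MIN, H2_MAX = 0.001, 0.9


@dataclass
class HeritabilityEstimate:
    tau: np.ndarray  # (K,) per-category variance components
    mean_chi2: float
    mean_ld_score: float
    total_h2: float
    rescale_const: float
    per_snp_h2: np.ndarray = field(repr=False)  # (M,)
    floor_applied: int = 0


def estimate_tau(
    ss: SummaryStats,
    scores: StratifiedLDScores,
    free_intercept: bool = False,
) -> np.ndarray:
    """Stratified LD-score regression for the per-category components tau.

    Regresses n_i * beta_hat_i^2 on {n_i * l(i, c)}_c. The intercept is
    fixed at its theoretical value 1 (the null expectation of chi-square)
    unless ``free_intercept``; rows are weighted by 1/max(l(i), 1) to tame
    the heteroskedasticity of high-LD SNPs. The returned tau may contain
    negative entries; these are handled downstream when rescaling.
    """
    chi2 = ss.n * ss.beta_hat**2
    design = ss.n[:, None] * scores.scores
    m, k = design.shape
    if free_intercept:
        design = np.hstack([np.ones((m, 1)), design])
        k += 1
    if k >= m:
        raise ValueError(f"cannot regress {k} categories on {m} SNPs")
    y = chi2 if free_intercept else chi2 - 1.0
    w = 1.0 / np.maximum(scores.total, 1.0)
    sw = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    if rank < k:
        raise ValueError("rank-deficient LD-score design (collinear categories)")
    return coef[1:] if free_intercept else coef


def estimate_total_h2(
    ss: SummaryStats,
    scores: StratifiedLDScores,
    literal: bool = False,
) -> float:
    """Chip heritability from mean chi-square and mean LD score.

    Implements H2 = M * (mean_chi2 - 1) / (mean_n * mean_ld_score), the
    moment inversion of E[chi2_i] = 1 + n * h2 * l(i) / M (a summary-
    statistic analogue of the Haseman-Elston estimator). ``literal`` drops
    the M factor. The result is clipped to [0.001, 0.9] with a warning.
    """
    m = len(ss)
    if m == 0:
        raise ValueError("empty summary statistics")
    lbar = scores.mean_score
    if lbar <= 0:
        raise ValueError("mean LD score must be positive")
    chi2_bar = float(np.mean(ss.n * ss.beta_hat**2))
    nbar = float(np.mean(ss.n))
    h2 = (chi2_bar - 1.0) / (nbar * lbar)
    if not literal:
        h2 *= m
    if not (H2_MIN <= h2 <= H2_MAX):
        logger.warning("total h2 estimate %.4g outside [%g, %g]; clipping",
                       h2, H2_MIN, H2_MAX)
        h2 = float(np.clip(h2, H2_MIN, H2_MAX))
    return h2


def per_snp_heritability(
    tau: np.ndarray,
    annot: AnnotationSet,
    total_h2: float,
) -> tuple[np.ndarray, float, int]:
    """Annotation-additive per-SNP variances rescaled to the chip total.

    raw_i = sum of tau_c over the categories containing SNP i, floored at
    total_h2 / (100 M) so prior precisions stay finite even when negative
    tau estimates dominate a SNP; then multiplied by the constant C that
    makes the per-SNP variances sum exactly to ``total_h2``.

    Returns ``(per_snp_h2, C, n_floored)``.
    """
    if total_h2 <= 0:
        raise ValueError("total_h2 must be positive")
    raw = annot.membership.astype(float) @ np.asarray(tau, dtype=float)
    m = raw.size
    if np.all(raw <= 0):
        logger.warning("all per-SNP raw heritabilities <= 0; "
                       "falling back to the uniform prior")
        return np.full(m, total_h2 / m), 1.0, m
    floor = total_h2 / (100.0 * m)
    n_floored = int((raw < floor).sum())
    raw = np.maximum(raw, floor)
    c = total_h2 / raw.sum()
    return raw * c, float(c), n_floored


def estimate_heritability(
    ss: SummaryStats,
    scores: StratifiedLDScores,
    annot: AnnotationSet,
    free_intercept: bool = False,
) -> HeritabilityEstimate:
    """Run the full two-stage pipeline for one trait."""
    tau = estimate_tau(ss, scores, free_intercept=free_intercept)
    h2 = estimate_total_h2(ss, scores)
    per_snp, c, n_floored = per_snp_heritability(tau, annot, h2)
    return HeritabilityEstimate(
        tau=tau,
        mean_chi2=float(np.mean(ss.n * ss.beta_hat**2)),
        mean_ld_score=scores.mean_score,
        total_h2=h2,
        rescale_const=c,
        per_snp_h2=per_snp,
        floor_applied=n_floored,
    )
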