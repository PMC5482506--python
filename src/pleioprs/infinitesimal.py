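"""Closed-form posterior mean effect sizes under a Gaussian prior.

Under the infinitesimal model every SNP has a nonzero effect drawn from a
normal prior whose variance is its per-SNP heritability; for two traits the
pair of effects at one SNP is bivariate normal with cross-trait correlation
rho_g. Conditioning the marginal GWAS estimators on the LD matrix makes the
posterior mean a ridge-regression-type linear solve per LD block:

    E[effects | data] = (N * D_b + Sigma_prior^-1)^-1 (N * beta_tilde_b)

with the two-trait version stacking both traits into a 2 M_b system.
rho_g is a tuning parameter selected on held-out data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .harmonize import HarmonizedStudy
from .heritability import HeritabilityEstimate
from .ld import LDBlockSet

logger = logging.getLogger(__name__)

_SOLVE_RIDGE = 1e-6


@dataclass
class TwoTraitConfig:
    """Cross-study settings: sample overlap and genetic correlation.

    The overlap term adds the covariance N_s * rho_e / (N1 * N2) * D between
    the two traits' marginal estimators; it is off by default because the
    overlap count is rarely known, the term is an order of magnitude smaller
    than the diagonal, and estimation is robust to ignoring it.
    """

    overlap_n: int = 0
    overlap_rho_e: float = 0.0
    use_overlap_term: bool = False
    rho_g: float | str = "grid"

    def __post_init__(self) -> None:
        if self.overlap_n < 0:
            raise ValueError("overlap_n must be >= 0")
        if not -1 < self.overlap_rho_e < 1:
            raise ValueError("overlap_rho_e must lie in (-1, 1)")
        if isinstance(self.rho_g, (int, float)) and not -1 < self.rho_g < 1:
            raise ValueError("rho_g must lie in (-1, 1)")

    def validate_overlap(self, n1: float, n2: float) -> None:
        if self.use_overlap_term and self.overlap_n > min(n1, n2):
            raise ValueError("overlap_n cannot exceed either study's N")


#: default tuning grid for the cross-trait correlation
RHO_G_GRID = (-0.9, -0.7, -0.5, -0.3, -0.1, 0.0, 0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class InfinitesimalPrior:
    """Per-SNP prior variances and the bivariate-normal coupling."""

    sigma2_1: np.ndarray = field(repr=False)
    sigma2_2: np.ndarray = field(repr=False)
    rho_g: float
    n1: float
    n2: float
    config: TwoTraitConfig = field(default_factory=TwoTraitConfig)

    def __post_init__(self) -> None:
        if not -1 < self.rho_g < 1:
            raise ValueError("|rho_g| must be < 1 (prior singular otherwise)")
        if np.any(self.sigma2_1 <= 0) or np.any(self.sigma2_2 <= 0):
            raise ValueError("prior variances must be positive")
        self.config.validate_overlap(self.n1, self.n2)


def _solve_spd(a: np.ndarray, rhs: np.ndarray, n_scale: float) -> np.ndarray | None:
    """Cholesky solve; one ridge retry; None if still not positive definite."""
    try:
        return sla.cho_solve(sla.cho_factor(a, lower=True), rhs)
    except np.linalg.LinAlgError:
        pass
    try:
        a2 = a + _SOLVE_RIDGE * n_scale * np.eye(a.shape[0])
        return sla.cho_solve(sla.cho_factor(a2, lower=True), rhs)
    except np.linalg.LinAlgError:
        return None


def posterior_single_block(
    beta_tilde_b: np.ndarray,
    d_b: np.ndarray,
    n: float,
    sigma2_b: np.ndarray,
) -> np.ndarray:
    """Posterior mean for one trait in one LD block.

    Solves (n * D_b + diag(1 / sigma2)) m = n * beta_tilde_b symmetrically;
    an unsolvable block (after one ridge retry) falls back to the prior
    mean 0 with a warning.
    """
    beta_tilde_b = np.asarray(beta_tilde_b, dtype=float)
    sigma2_b = np.asarray(sigma2_b, dtype=float)
    if np.any(sigma2_b <= 0):
        raise ValueError("prior variances must be positive")
    a = n * np.asarray(d_b, dtype=float) + np.diag(1.0 / sigma2_b)
    out = _solve_spd(a, n * beta_tilde_b, n)
    if out is None:
        logger.warning("block solve failed; returning prior mean 0")
        return np.zeros_like(beta_tilde_b)
    return out


def _bivariate_precision(s1, s2, rho):
    """Per-SNP 2x2 precision blocks of the bivariate normal prior."""
    f = 1.0 / (1.0 - rho**2)
    p11 = f / s1
    p22 = f / s2
    p12 = -f * rho / np.sqrt(s1 * s2)
    return p11, p12, p22


def posterior_two_trait_block(
    beta_tilde_b: np.ndarray,
    gamma_tilde_b: np.ndarray,
    d_b: np.ndarray,
    prior: InfinitesimalPrior,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint posterior mean of both traits' effects in one LD block.

    Builds the stacked 2 M_b system with the analytic per-SNP 2x2 prior
    precision. When the overlap term is enabled the data covariance becomes
    K (x) D_b with K = [[1/N1, a], [a, 1/N2]], a = N_s rho_e / (N1 N2), and
    the system matrix/right-hand side use K^-1 instead of diag(N1, N2).
    """
    b = np.asarray(beta_tilde_b, dtype=float)
    g = np.asarray(gamma_tilde_b, dtype=float)
    d = np.asarray(d_b, dtype=float)
    mb = b.size
    s1 = np.asarray(prior.sigma2_1, dtype=float)
    s2 = np.asarray(prior.sigma2_2, dtype=float)
    if not (g.size == mb and s1.size == mb and s2.size == mb):
        raise ValueError("block inputs misaligned")
    n1, n2 = prior.n1, prior.n2

    if prior.config.use_overlap_term and prior.config.overlap_n > 0:
        a_off = prior.config.overlap_n * prior.config.overlap_rho_e / (n1 * n2)
        k = np.array([[1.0 / n1, a_off], [a_off, 1.0 / n2]])
        kinv = np.linalg.inv(k)
    else:
        kinv = np.diag([n1, n2])

    amat = np.zeros((2 * mb, 2 * mb))
    amat[:mb, :mb] = kinv[0, 0] * d
    amat[:mb, mb:] = kinv[0, 1] * d
    amat[mb:, :mb] = kinv[1, 0] * d
    amat[mb:, mb:] = kinv[1, 1] * d

    p11, p12, p22 = _bivariate_precision(s1, s2, prior.rho_g)
    idx = np.arange(mb)
    amat[idx, idx] += p11
    amat[mb + idx, mb + idx] += p22
    amat[idx, mb + idx] += p12
    amat[mb + idx, idx] += p12

    rhs = np.concatenate([kinv[0, 0] * b + kinv[0, 1] * g,
                          kinv[1, 0] * b + kinv[1, 1] * g])
    out = _solve_spd(amat, rhs, max(n1, n2))
    if out is None:
        logger.warning("two-trait block solve failed; returning prior mean 0")
        return np.zeros(mb), np.zeros(mb)
    return out[:mb], out[mb:]


def run_infinitesimal_single(
    beta_tilde: np.ndarray,
    blocks: LDBlockSet,
    sigma2: np.ndarray,
    n: float,
) -> np.ndarray:
    """Map the single-trait block solve over the genome."""
    out = np.empty(blocks.m)
    for blk in blocks:
        out[blk.start:blk.end] = posterior_single_block(
            beta_tilde[blk.start:blk.end], blk.corr, n,
            sigma2[blk.start:blk.end],
        )
    return out


def run_infinitesimal(
    study: HarmonizedStudy,
    blocks: LDBlockSet,
    h2: tuple[HeritabilityEstimate, HeritabilityEstimate],
    rho_g: float,
    config: TwoTraitConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-trait posterior mean effects over all LD blocks (deterministic)."""
    n1 = float(np.mean(study.ss1.n))
    n2 = float(np.mean(study.ss2.n))
    prior_cfg = config or TwoTraitConfig()
    b1 = study.ss1.beta_hat
    b2 = study.ss2.beta_hat
    s1 = h2[0].per_snp_h2
    s2 = h2[1].per_snp_h2
    post1 = np.empty(blocks.m)
    post2 = np.empty(blocks.m)
    for blk in blocks:
        sl = slice(blk.start, blk.end)
        prior = InfinitesimalPrior(s1[sl], s2[sl], rho_g, n1, n2, prior_cfg)
        post1[sl], post2[sl] = posterior_two_trait_block(
            b1[sl], b2[sl], blk.corr, prior
        )
    return post1, post2
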