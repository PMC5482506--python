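"""Spike-and-slab Gibbs sampler for one or two traits.

The two-trait prior puts each SNP in one of four components — causal in
both traits (11), in the first only (10), in the second only (01), or in
neither (00) — with mixture probabilities p = (p11, p10, p01, p00) given a
Dirichlet(alpha) hyperprior. A causal margin draws its effect from a normal
slab whose variance is the SNP's per-trait heritability divided by that
trait's total causal probability (sigma2_1i / (p11 + p10) for trait 1), so
the prior's expected per-SNP variance equals sigma2_1i for every p.

Full conditionals per SNP are a four-component mixture of products of
normals and point masses. Writing

    Delta_1 = beta_tilde_i - sum_{j != i} D_ij beta_j        (residual)
    C_1     = N1 / (N1 + (p11 + p10) / sigma2_1i)            (shrinkage)

the causal margin draws from N(C_1 Delta_1, C_1 / N1) and the component
weights are products of Gaussian evidence ratios (see component_weights).
The conditional of p is non-conjugate because p also scales the slab
variances; it is sampled by Metropolis-Hastings with a
Dirichlet(alpha + counts) proposal. To keep the chain from overshooting the
total heritability, the three causal weights are multiplied each sweep by
c = min(1, h2_1 / sum(beta^2), h2_2 / sum(gamma^2)), the deficit going to
the null component.

The SNP sweep is JIT-compiled; all randomness flows through one
numpy Generator so runs are bitwise reproducible given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .ld import LDBlockSet

logger = logging.getLogger(__name__)

# component order used throughout: 11, 10, 01, 00
_COMP_11, _COMP_10, _COMP_01, _COMP_00 = 0, 1, 2, 3


@dataclass
class MixturePrior:
    """Dirichlet hyperprior and current mixture proportions."""

    alpha: np.ndarray = field(default_factory=lambda: np.ones(4))

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (4,) or np.any(self.alpha <= 0):
            raise ValueError("alpha must be a positive 4-vector")

    def initial_p(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()


@dataclass
class GibbsResult:
    post_mean1: np.ndarray
    post_mean2: np.ndarray | None
    p_trace: np.ndarray  # (n_iter, 4) or (n_iter, 2) for single trait
    c_trace: np.ndarray
    h2_trace1: np.ndarray  # sampled sum of squared effects per sweep
    h2_trace2: np.ndarray | None
    accept_rate: float
    n_iter: int
    burn_in: int
    seed: int


# ---------------------------------------------------------------------------
# full-conditional pieces (pure-Python surface, unit-testable)
# ---------------------------------------------------------------------------

def residual_stats(i, beta_tilde, gamma_tilde, d_row, beta, gamma,
                   p, sigma2_1i, sigma2_2i, n1, n2):
    """Residualized estimators and shrinkage factors for SNP i.

    ``d_row`` is SNP i's row of the block LD matrix; ``beta``/``gamma`` are
    the current draws for the same window.
    """
    delta1 = beta_tilde[i] - (d_row @ beta - beta[i])
    delta2 = gamma_tilde[i] - (d_row @ gamma - gamma[i])
    q1 = p[_COMP_11] + p[_COMP_10]
    q2 = p[_COMP_11] + p[_COMP_01]
    c1 = n1 / (n1 + q1 / sigma2_1i)
    c2 = n2 / (n2 + q2 / sigma2_2i)
    return delta1, delta2, c1, c2


def component_weights(delta1, delta2, c1, c2, p, sigma2_1i, sigma2_2i, n1, n2):
    """Normalized posterior probabilities of the four components.

    Computed in log space with max-subtraction. Relative to the null
    component, each causal margin contributes the Gaussian evidence ratio
    (N sigma2_slab + 1)^(-1/2) exp(N C Delta^2 / 2); dividing everything by
    the causal exponentials gives the equivalent form used here, where slab
    margins carry (N sigma2_slab + 1)^(-1/2) and spike margins carry
    exp(-N C Delta^2 / 2).
    """
    q1 = p[_COMP_11] + p[_COMP_10]
    q2 = p[_COMP_11] + p[_COMP_01]
    if q1 <= 0 or q2 <= 0:
        raise ValueError("total causal probability of each trait must be > 0")
    slab1 = sigma2_1i / q1
    slab2 = sigma2_2i / q2
    log_norm1 = -0.5 * np.log(n1 * slab1 + 1.0)
    log_norm2 = -0.5 * np.log(n2 * slab2 + 1.0)
    log_spike1 = -0.5 * n1 * c1 * delta1**2
    log_spike2 = -0.5 * n2 * c2 * delta2**2
    logs = np.array([
        np.log(p[_COMP_11]) + log_norm1 + log_norm2,
        np.log(p[_COMP_10]) + log_norm1 + log_spike2,
        np.log(p[_COMP_01]) + log_spike1 + log_norm2,
        np.log(p[_COMP_00]) + log_spike1 + log_spike2,
    ])
    logs -= logs.max()
    w = np.exp(logs)
    return w / w.sum()


def shrink_weights(weights, c):
    """Multiply the causal weights by c, routing the deficit to the null."""
    w = np.asarray(weights, dtype=float).copy()
    causal = w[:3].sum()
    w[:3] *= c
    w[3] += (1.0 - c) * causal
    return w


def shrink_factor(beta, gamma, h2_1, h2_2):
    """c = min(1, h2_1 / sum(beta^2), h2_2 / sum(gamma^2)); no-shrink on 0."""
    c = 1.0
    s1 = float(np.dot(beta, beta))
    if s1 > 0:
        c = min(c, h2_1 / s1)
    if gamma is not None:
        s2 = float(np.dot(gamma, gamma))
        if s2 > 0:
            c = min(c, h2_2 / s2)
    return c


def sample_effect(weights, delta1, delta2, c1, c2, n1, n2, rng):
    """Draw the component indicator and the effect pair for one SNP."""
    k = int(rng.choice(4, p=weights))
    b = g = 0.0
    if k in (_COMP_11, _COMP_10):
        b = c1 * delta1 + np.sqrt(c1 / n1) * rng.standard_normal()
    if k in (_COMP_11, _COMP_01):
        g = c2 * delta2 + np.sqrt(c2 / n2) * rng.standard_normal()
    return k, b, g


def _log_target(p, counts, alpha, m1c, s1, m2c, s2, p_dependent_slabs):
    """Log posterior density of p given indicators and current effects.

    Dirichlet(alpha) prior x categorical likelihood of the component
    indicators x (when ``p_dependent_slabs``) the normal slab densities of
    the current nonzero effects, whose variances scale with 1/(p11 + p10)
    and 1/(p11 + p01). With p-independent slab variances the conditional is
    conjugate and the Dirichlet(alpha + counts) proposal is exact.
    """
    lp = np.log(p)
    out = float(((alpha - 1.0) + counts) @ lp)
    if p_dependent_slabs:
        q1 = p[_COMP_11] + p[_COMP_10]
        q2 = p[_COMP_11] + p[_COMP_01]
        out += 0.5 * m1c * np.log(q1) - 0.5 * q1 * s1
        out += 0.5 * m2c * np.log(q2) - 0.5 * q2 * s2
    return out


def update_pvec(p, counts, alpha, beta, gamma, sigma2_1, sigma2_2, rng,
                p_dependent_slabs=True):
    """One Metropolis-Hastings update of the mixture proportions.

    Proposes from Dirichlet(alpha + counts) and corrects for the slab
    variances' dependence on p. Returns ``(p_new, accepted, accept_prob)``.
    """
    counts = np.asarray(counts, dtype=float)
    conc = alpha + counts
    prop = rng.dirichlet(conc)
    nz1 = beta != 0
    m1c = int(nz1.sum())
    s1 = float((beta[nz1] ** 2 / sigma2_1[nz1]).sum()) if m1c else 0.0
    nz2 = gamma != 0
    m2c = int(nz2.sum())
    s2 = float((gamma[nz2] ** 2 / sigma2_2[nz2]).sum()) if m2c else 0.0

    def lq(x):  # proposal log density (normalizer cancels)
        return float((conc - 1.0) @ np.log(x))

    log_ratio = (
        _log_target(prop, counts, alpha, m1c, s1, m2c, s2, p_dependent_slabs)
        - _log_target(p, counts, alpha, m1c, s1, m2c, s2, p_dependent_slabs)
        + lq(p) - lq(prop)
    )
    accept_prob = min(1.0, float(np.exp(log_ratio))) if log_ratio < 0 else 1.0
    accepted = np.log(rng.uniform()) < log_ratio
    return (prop if accepted else p), bool(accepted), accept_prob


# ---------------------------------------------------------------------------
# JIT-compiled sweeps
# ---------------------------------------------------------------------------

@njit(cache=False)
def _sweep_two(beta, gamma, comp, beta_tilde, gamma_tilde,
               d_flat, blk_start, blk_size, blk_off,
               sigma2_1, sigma2_2, n1, n2,
               p11, p10, p01, p00, c, u, z1, z2):
    q1 = p11 + p10
    q2 = p11 + p01
    for b in range(blk_start.shape[0]):
        s = blk_start[b]
        mb = blk_size[b]
        off = blk_off[b]
        d = d_flat[off:off + mb * mb].reshape(mb, mb)
        cur1 = np.zeros(mb)
        cur2 = np.zeros(mb)
        for j in range(mb):
            bj = beta[s + j]
            gj = gamma[s + j]
            if bj != 0.0 or gj != 0.0:
                for r in range(mb):
                    cur1[r] += d[r, j] * bj
                    cur2[r] += d[r, j] * gj
        for li in range(mb):
            i = s + li
            slab1 = sigma2_1[i] / q1
            slab2 = sigma2_2[i] / q2
            c1 = n1 / (n1 + 1.0 / slab1)
            c2 = n2 / (n2 + 1.0 / slab2)
            delta1 = beta_tilde[i] - (cur1[li] - beta[i])
            delta2 = gamma_tilde[i] - (cur2[li] - gamma[i])
            ln1 = -0.5 * np.log(n1 * slab1 + 1.0)
            ln2 = -0.5 * np.log(n2 * slab2 + 1.0)
            ls1 = -0.5 * n1 * c1 * delta1 * delta1
            ls2 = -0.5 * n2 * c2 * delta2 * delta2
            a0 = np.log(p11) + ln1 + ln2
            a1 = np.log(p10) + ln1 + ls2
            a2 = np.log(p01) + ls1 + ln2
            a3 = np.log(p00) + ls1 + ls2
            mx = max(max(a0, a1), max(a2, a3))
            w0 = np.exp(a0 - mx)
            w1 = np.exp(a1 - mx)
            w2 = np.exp(a2 - mx)
            w3 = np.exp(a3 - mx)
            tot = w0 + w1 + w2 + w3
            w0 = c * w0 / tot
            w1 = c * w1 / tot
            w2 = c * w2 / tot
            w3 = 1.0 - (w0 + w1 + w2)
            ui = u[i]
            if ui < w0:
                k = 0
            elif ui < w0 + w1:
                k = 1
            elif ui < w0 + w1 + w2:
                k = 2
            else:
                k = 3
            nb = 0.0
            ng = 0.0
            if k == 0 or k == 1:
                nb = c1 * delta1 + np.sqrt(c1 / n1) * z1[i]
            if k == 0 or k == 2:
                ng = c2 * delta2 + np.sqrt(c2 / n2) * z2[i]
            db = nb - beta[i]
            dg = ng - gamma[i]
            if db != 0.0 or dg != 0.0:
                for r in range(mb):
                    cur1[r] += d[r, li] * db
                    cur2[r] += d[r, li] * dg
            beta[i] = nb
            gamma[i] = ng
            comp[i] = k


@njit(cache=False)
def _sweep_single(beta, comp, beta_tilde, d_flat, blk_start, blk_size, blk_off,
                  sigma2, n, p1, p0, c, u, z):
    for b in range(blk_start.shape[0]):
        s = blk_start[b]
        mb = blk_size[b]
        off = blk_off[b]
        d = d_flat[off:off + mb * mb].reshape(mb, mb)
        cur = np.zeros(mb)
        for j in range(mb):
            bj = beta[s + j]
            if bj != 0.0:
                for r in range(mb):
                    cur[r] += d[r, j] * bj
        for li in range(mb):
            i = s + li
            slab = sigma2[i] / p1
            cf = n / (n + 1.0 / slab)
            delta = beta_tilde[i] - (cur[li] - beta[i])
            a1 = np.log(p1) - 0.5 * np.log(n * slab + 1.0)
            a0 = np.log(p0) - 0.5 * n * cf * delta * delta
            mx = a1 if a1 > a0 else a0
            w1 = np.exp(a1 - mx)
            w0 = np.exp(a0 - mx)
            w1 = c * w1 / (w1 + w0)
            nb = 0.0
            k = 0
            if u[i] < w1:
                k = 1
                nb = cf * delta + np.sqrt(cf / n) * z[i]
            db = nb - beta[i]
            if db != 0.0:
                for r in range(mb):
                    cur[r] += d[r, li] * db
            beta[i] = nb
            comp[i] = k


def _flatten_blocks(blocks: LDBlockSet):
    starts = np.array([b.start for b in blocks], dtype=np.int64)
    sizes = np.array([b.size for b in blocks], dtype=np.int64)
    offs = np.concatenate([[0], np.cumsum(sizes**2)[:-1]]).astype(np.int64)
    flat = np.concatenate([b.corr.ravel() for b in blocks]).astype(np.float64)
    return flat, starts, sizes, offs


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def run_gibbs(
    beta_tilde: np.ndarray,
    gamma_tilde: np.ndarray,
    blocks: LDBlockSet,
    sigma2_1: np.ndarray,
    sigma2_2: np.ndarray,
    n1: float,
    n2: float,
    h2_1: float,
    h2_2: float,
    prior: MixturePrior | None = None,
    n_iter: int = 250,
    burn_in: int = 50,
    seed: int = 0,
    update_p: bool = True,
    fixed_p: np.ndarray | None = None,
) -> GibbsResult:
    """Two-trait spike-and-slab Gibbs sampler.

    Effects start at 0 and p at alpha / sum(alpha); SNPs are swept in fixed
    genomic order; after each sweep the mixture proportions are updated by
    Metropolis-Hastings (unless ``update_p`` is False, in which case p stays
    at ``fixed_p`` or its initial value). Posterior means accumulate over
    post-burn-in sweeps. Beyond the Dirichlet concentration and chain
    length there are no tuning parameters.
    """
    if not n_iter > burn_in >= 0:
        raise ValueError("need n_iter > burn_in >= 0")
    prior = prior or MixturePrior()
    m = blocks.m
    beta_tilde = np.ascontiguousarray(beta_tilde, dtype=np.float64)
    gamma_tilde = np.ascontiguousarray(gamma_tilde, dtype=np.float64)
    sigma2_1 = np.ascontiguousarray(sigma2_1, dtype=np.float64)
    sigma2_2 = np.ascontiguousarray(sigma2_2, dtype=np.float64)
    flat, starts, sizes, offs = _flatten_blocks(blocks)
    rng = np.random.default_rng(seed)

    p = np.asarray(fixed_p, dtype=float) if fixed_p is not None else prior.initial_p()
    beta = np.zeros(m)
    gamma = np.zeros(m)
    comp = np.full(m, _COMP_00, dtype=np.int8)
    acc1 = np.zeros(m)
    acc2 = np.zeros(m)
    p_trace = np.empty((n_iter, 4))
    c_trace = np.empty(n_iter)
    h2t1 = np.empty(n_iter)
    h2t2 = np.empty(n_iter)
    n_acc = 0
    n_prop = 0

    for it in range(n_iter):
        c = shrink_factor(beta, gamma, h2_1, h2_2)
        u = rng.uniform(size=m)
        z1 = rng.standard_normal(m)
        z2 = rng.standard_normal(m)
        _sweep_two(beta, gamma, comp, beta_tilde, gamma_tilde,
                   flat, starts, sizes, offs, sigma2_1, sigma2_2,
                   float(n1), float(n2), p[0], p[1], p[2], p[3], c, u, z1, z2)
        if np.isnan(beta).any() or np.isnan(gamma).any():
            raise RuntimeError(
                f"NaN draw at sweep {it}; p={p}, c={c:.3g}, "
                f"sum_b2={np.dot(beta, beta):.3g}"
            )
        counts = np.bincount(comp, minlength=4)
        if update_p:
            p, accepted, _ = update_pvec(
                p, counts, prior.alpha, beta, gamma, sigma2_1, sigma2_2, rng
            )
            n_acc += accepted
            n_prop += 1
        p_trace[it] = p
        c_trace[it] = c
        h2t1[it] = np.dot(beta, beta)
        h2t2[it] = np.dot(gamma, gamma)
        if it >= burn_in:
            acc1 += beta
            acc2 += gamma

    kept = n_iter - burn_in
    return GibbsResult(
        post_mean1=acc1 / kept,
        post_mean2=acc2 / kept,
        p_trace=p_trace,
        c_trace=c_trace,
        h2_trace1=h2t1,
        h2_trace2=h2t2,
        accept_rate=(n_acc / n_prop) if n_prop else float("nan"),
        n_iter=n_iter,
        burn_in=burn_in,
        seed=seed,
    )


def run_gibbs_single(
    beta_tilde: np.ndarray,
    blocks: LDBlockSet,
    sigma2: np.ndarray,
    n: float,
    h2: float,
    alpha: np.ndarray | tuple = (1.0, 1.0),
    n_iter: int = 250,
    burn_in: int = 50,
    seed: int = 0,
    update_p: bool = True,
    fixed_p: np.ndarray | None = None,
) -> GibbsResult:
    """Single-trait two-component (causal / null) degenerate sampler.

    With one whole-genome annotation this is the classic summary-statistic
    spike-and-slab PRS model.
    """
    if not n_iter > burn_in >= 0:
        raise ValueError("need n_iter > burn_in >= 0")
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (2,) or np.any(alpha <= 0):
        raise ValueError("alpha must be a positive 2-vector")
    m = blocks.m
    beta_tilde = np.ascontiguousarray(beta_tilde, dtype=np.float64)
    sigma2 = np.ascontiguousarray(sigma2, dtype=np.float64)
    flat, starts, sizes, offs = _flatten_blocks(blocks)
    rng = np.random.default_rng(seed)

    p = np.asarray(fixed_p, dtype=float) if fixed_p is not None else alpha / alpha.sum()
    beta = np.zeros(m)
    comp = np.zeros(m, dtype=np.int8)
    acc = np.zeros(m)
    p_trace = np.empty((n_iter, 2))
    c_trace = np.empty(n_iter)
    h2t = np.empty(n_iter)
    n_acc = 0
    n_prop = 0
    zero = np.zeros(0)

    for it in range(n_iter):
        c = shrink_factor(beta, None, h2, np.inf)
        u = rng.uniform(size=m)
        z = rng.standard_normal(m)
        _sweep_single(beta, comp, beta_tilde, flat, starts, sizes, offs,
                      sigma2, float(n), p[0], p[1], c, u, z)
        if np.isnan(beta).any():
            raise RuntimeError(f"NaN draw at sweep {it}; p={p}, c={c:.3g}")
        counts = np.bincount(comp, minlength=2)[::-1]  # (causal, null)
        if update_p:
            p, accepted, _ = _update_pvec_single(
                p, counts, alpha, beta, sigma2, rng
            )
            n_acc += accepted
            n_prop += 1
        p_trace[it] = p
        c_trace[it] = c
        h2t[it] = np.dot(beta, beta)
        if it >= burn_in:
            acc += beta

    kept = n_iter - burn_in
    return GibbsResult(
        post_mean1=acc / kept,
        post_mean2=None,
        p_trace=p_trace,
        c_trace=c_trace,
        h2_trace1=h2t,
        h2_trace2=None,
        accept_rate=(n_acc / n_prop) if n_prop else float("nan"),
        n_iter=n_iter,
        burn_in=burn_in,
        seed=seed,
    )


def _update_pvec_single(p, counts, alpha, beta, sigma2, rng,
                        p_dependent_slabs=True):
    """MH update of (p_causal, p_null) in the single-trait sampler."""
    counts = np.asarray(counts, dtype=float)
    conc = alpha + counts
    prop = rng.dirichlet(conc)
    nz = beta != 0
    mc = int(nz.sum())
    s = float((beta[nz] ** 2 / sigma2[nz]).sum()) if mc else 0.0

    def lt(x):
        out = float(((alpha - 1.0) + counts) @ np.log(x))
        if p_dependent_slabs:
            out += 0.5 * mc * np.log(x[0]) - 0.5 * x[0] * s
        return out

    def lq(x):
        return float((conc - 1.0) @ np.log(x))

    log_ratio = lt(prop) - lt(p) + lq(p) - lq(prop)
    accepted = np.log(rng.uniform()) < log_ratio
    accept_prob = min(1.0, float(np.exp(log_ratio))) if log_ratio < 0 else 1.0
    return (prop if accepted else p), bool(accepted), accept_prob
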