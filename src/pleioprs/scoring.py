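"""Polygenic score computation, evaluation statistics and grid tuning.

The polygenic risk score of individual i is the dot product of their
standardized genotype row with the posterior mean effect sizes. Evaluation
reports the Pearson correlation between score and phenotype (COR), the area
under the ROC curve, and the slope of a logistic regression of case status
on the score; nested scores are compared by a likelihood-ratio test on the
logistic deviance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from .plink import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class PRSResult:
    sample_ids: np.ndarray
    prs: np.ndarray
    trait: str = ""
    model: str = ""
    n_skipped_snps: int = 0

    def __post_init__(self) -> None:
        self.prs = np.asarray(self.prs, dtype=float)
        if not np.isfinite(self.prs).all():
            raise ValueError("non-finite PRS values")
        if len(self.prs) != len(self.sample_ids):
            raise ValueError("one PRS value per sample required")

    def write(self, path) -> None:
        pd.DataFrame({"sample_id": self.sample_ids, "prs": self.prs}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class EvalReport:
    cor: float
    auc: float | None = None
    slope: float | None = None
    enrichment: dict | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {"cor": self.cor, "auc": self.auc, "slope": self.slope,
                "enrichment": self.enrichment}


def compute_prs(
    effects: pd.DataFrame | np.ndarray,
    cohort: GenotypePanel,
    trait: str = "",
    model: str = "",
) -> PRSResult:
    """Score a cohort with per-SNP posterior mean effects.

    ``effects`` is either an array aligned to the cohort's SNPs or a
    DataFrame with columns ``snp_id, a1, a2, effect``; in the latter case
    SNPs are matched by id, effects of allele-swapped SNPs are sign-flipped
    and unmatched SNPs are skipped (counted in the result).
    """
    n_skipped = 0
    if isinstance(effects, pd.DataFrame):
        snps = cohort.snps
        merged = snps.merge(effects, on="snp_id", how="left",
                            suffixes=("", "_eff"))
        eff = merged["effect"].to_numpy(dtype=float)
        matched = ~np.isnan(eff)
        same = matched & (merged["a1"] == merged["a1_eff"]) & (
            merged["a2"] == merged["a2_eff"]
        )
        swapped = matched & (merged["a1"] == merged["a2_eff"]) & (
            merged["a2"] == merged["a1_eff"]
        )
        weights = np.zeros(len(snps))
        weights[same] = eff[same]
        weights[swapped] = -eff[swapped]
        n_skipped = int(len(snps) - (same | swapped).sum())
        if n_skipped == len(snps):
            raise ValueError("no effect SNPs overlap the cohort")
        if n_skipped:
            logger.info("compute_prs: skipped %d unmatched SNPs", n_skipped)
    else:
        weights = np.asarray(effects, dtype=float)
        if weights.size != cohort.m_snps:
            raise ValueError("effects not aligned to cohort SNPs")
        if weights.size == 0:
            raise ValueError("no effect SNPs overlap the cohort")
    x = cohort.standardized(dtype=np.float32)
    prs = x @ weights.astype(np.float32)
    return PRSResult(cohort.sample_ids, prs.astype(float), trait, model,
                     n_skipped_snps=n_skipped)


def _is_binary(y: np.ndarray) -> bool:
    return set(np.unique(y)) <= {0.0, 1.0}


def evaluate(prs: PRSResult, phenotype) -> EvalReport:
    """COR, AUC and logistic slope of one score against a phenotype.

    COR is the Pearson correlation on the observed scale (point-biserial
    for a binary phenotype). AUC and the logistic slope are reported for
    binary phenotypes with at least two cases and two controls.
    """
    y = np.asarray(phenotype, dtype=float)
    x = prs.prs
    if y.size != x.size:
        raise ValueError("phenotype not aligned to PRS samples")
    if np.std(x) == 0:
        logger.warning("constant PRS; correlation undefined, reporting 0")
        return EvalReport(cor=0.0)
    cor = float(np.corrcoef(x, y)[0, 1]) if np.std(y) > 0 else 0.0
    auc = slope = None
    if _is_binary(y) and (y == 1).sum() >= 2 and (y == 0).sum() >= 2:
        auc = float(roc_auc_score(y, x))
        slope = float(_logit_fit(y, x[:, None]).params[1])
    return EvalReport(cor=cor, auc=auc, slope=slope)


def _logit_fit(y, x_cols):
    """Logistic fit with an intercept; L2-penalized fallback on separation."""
    design = sm.add_constant(np.asarray(x_cols, dtype=float))
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if np.isfinite(res.params).all() and np.abs(res.params).max() < 1e3:
            return res
    except Exception:  # noqa: BLE001 - perfect separation raises variously
        pass
    logger.warning("logistic fit unstable (separation?); using ridge penalty")
    return sm.Logit(y, design).fit_regularized(
        alpha=1e-3, L1_wt=0.0, disp=0, maxiter=500
    )


def lrt_compare(prs_a: PRSResult, prs_b: PRSResult, phenotype) -> float:
    """Likelihood-ratio p-value: does score b add to score a?

    Fits logistic(y ~ a) and logistic(y ~ a + b); the p-value comes from
    a chi-square(1) on -2 [logL(a) - logL(a + b)].
    """
    y = np.asarray(phenotype, dtype=float)
    if not _is_binary(y):
        raise ValueError("likelihood-ratio comparison needs a binary phenotype")
    xa = prs_a.prs
    xb = prs_b.prs
    if xa.size != y.size or xb.size != y.size:
        raise ValueError("scores and phenotype must share samples")
    ll1 = _logit_fit(y, xa[:, None]).llf
    ll2 = _logit_fit(y, np.column_stack([xa, xb])).llf
    lr = max(0.0, -2.0 * (ll1 - ll2))
    return float(stats.chi2.sf(lr, df=1))


def enrichment_topq(prs: PRSResult, phenotype, q_list=(1, 5, 10, 20, 30)) -> dict:
    """Case proportion among the top q% of samples by score.

    Ties are broken by stable sample order. Returns
    ``{"baseline": overall case rate, q: proportion, ...}``; q values whose
    bucket holds no sample are skipped.
    """
    y = np.asarray(phenotype, dtype=float)
    if not _is_binary(y):
        raise ValueError("enrichment needs a binary phenotype")
    order = np.argsort(-prs.prs, kind="stable")
    n = y.size
    out = {"baseline": float(y.mean())}
    for q in q_list:
        k = int(np.floor(n * q / 100.0))
        if k < 1:
            logger.info("enrichment: top %g%% bucket empty at n=%d; skipped", q, n)
            continue
        out[q] = float(y[order[:k]].mean())
    return out


def tune_split_half(
    param_grid,
    scorer,
    phenotype,
    seed: int = 0,
) -> dict:
    """Select a tuning parameter by the split-half scheme.

    The evaluation cohort is split into two equal halves (stratified by
    case status, seeded). The grid point maximizing COR on half A is
    evaluated on half B and vice versa; the two held-out accuracies are
    averaged. ``scorer(param, sample_index)`` must return the scores of the
    indexed samples. Grid ties break to the lowest index.

    Returns ``{"params": (choice_on_A, choice_on_B), "accuracy": mean,
    "per_half": [...]}.``
    """
    grid = list(param_grid)
    if not grid:
        raise ValueError("empty parameter grid")
    y = np.asarray(phenotype, dtype=float)
    rng = np.random.default_rng(seed)
    idx_a, idx_b = _stratified_halves(y, rng)

    def cor_on(param, idx):
        s = np.asarray(scorer(param, idx), dtype=float)
        if np.std(s) == 0 or np.std(y[idx]) == 0:
            return 0.0
        return float(np.corrcoef(s, y[idx])[0, 1])

    chosen, held_out = [], []
    for tune_idx, eval_idx in ((idx_a, idx_b), (idx_b, idx_a)):
        scores = [cor_on(p, tune_idx) for p in grid]
        best = int(np.argmax(scores))  # argmax takes the first maximum
        chosen.append(grid[best])
        held_out.append(cor_on(grid[best], eval_idx))
    return {
        "params": tuple(chosen),
        "accuracy": float(np.mean(held_out)),
        "per_half": held_out,
    }


def _stratified_halves(y, rng):
    """Random equal split preserving the case/control ratio."""
    idx_a, idx_b = [], []
    for value in np.unique(y):
        members = np.flatnonzero(y == value)
        perm = rng.permutation(members)
        half = len(perm) // 2
        idx_a.append(perm[:half])
        idx_b.append(perm[half:])
    return np.sort(np.concatenate(idx_a)), np.sort(np.concatenate(idx_b))
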