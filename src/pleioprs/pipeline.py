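"""End-to-end orchestration: harmonize -> LD -> heritability -> posterior
effects -> polygenic scores -> evaluation.

Eight model variants are supported, the cross of {single-trait, two-trait}
x {infinitesimal, non-infinitesimal} x {genome-wide, annotated}:

    ldpred-inf          single  infinitesimal      one whole-genome category
    annopred-inf        single  infinitesimal      functional annotations
    pleiopred-inf       two     infinitesimal      one whole-genome category
    pleiopred-anno-inf  two     infinitesimal      functional annotations
    ldpred              single  spike-and-slab     one whole-genome category
    annopred            single  spike-and-slab     functional annotations
    pleiopred           two     spike-and-slab     one whole-genome category
    pleiopred-anno      two     spike-and-slab     functional annotations

The genome-wide variants are exactly the annotated ones run with a single
whole-genome annotation. The infinitesimal two-trait models carry the
cross-trait correlation rho_g as a tuning parameter (selected split-half on
the validation cohort); the spike-and-slab models have no tuning parameter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .harmonize import HarmonizedStudy, harmonize
from .heritability import HeritabilityEstimate, estimate_heritability
from .infinitesimal import (
    RHO_G_GRID,
    TwoTraitConfig,
    run_infinitesimal,
    run_infinitesimal_single,
)
from .ld import LDBlockSet, build_blocks, stratified_ld_scores
from .noninfinitesimal import MixturePrior, run_gibbs, run_gibbs_single
from .plink import GenotypePanel, read_plink
from .scoring import compute_prs, evaluate, tune_split_half
from .sumstats import load_summary_stats

logger = logging.getLogger(__name__)

MODELS = (
    "ldpred-inf", "annopred-inf", "pleiopred-inf", "pleiopred-anno-inf",
    "ldpred", "annopred", "pleiopred", "pleiopred-anno",
)


def _is_two_trait(model: str) -> bool:
    return model.startswith("pleiopred")


def _is_infinitesimal(model: str) -> bool:
    return model.endswith("-inf")


def _uses_annotations(model: str) -> bool:
    return model in ("annopred-inf", "annopred", "pleiopred-anno-inf",
                     "pleiopred-anno")


@dataclass
class RunConfig:
    ssf1: str = ""
    ssf2: str = ""
    ref: str = ""
    annot: str = ""
    valid: str = ""
    out: str = "pleioprs_out"
    model: str = "pleiopred-anno"
    ld_radius: int | None = None
    rho_g: float | str = "grid"
    alpha: tuple = (1.0, 1.0, 1.0, 1.0)
    n_iter: int = 250
    burn_in: int = 50
    seed: int = 0
    use_overlap_term: bool = False
    overlap_n: int = 0
    overlap_rho_e: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")


def fit_model(
    study: HarmonizedStudy,
    blocks: LDBlockSet,
    model: str,
    rho_g: float = 0.0,
    alpha=(1.0, 1.0, 1.0, 1.0),
    n_iter: int = 250,
    burn_in: int = 50,
    seed: int = 0,
    ld_radius: int | None = None,
    two_trait_config: TwoTraitConfig | None = None,
) -> dict:
    """Posterior mean effects for one model variant.

    Returns a dict with ``effects1`` (trait of interest), ``effects2``
    (None for single-trait models), the per-trait ``h2`` estimates, and
    sampler diagnostics where applicable.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    annot = study.annot if _uses_annotations(model) else AnnotationSet.whole_genome(
        study.snp_ids
    )
    scores = stratified_ld_scores(study.panel, annot, radius_snps=ld_radius)
    h2_1 = estimate_heritability(study.ss1, scores, annot)
    n1 = float(np.mean(study.ss1.n))
    out = {"h2_1": h2_1, "h2_2": None, "effects2": None, "diagnostics": None}

    if not _is_two_trait(model):
        if _is_infinitesimal(model):
            out["effects1"] = run_infinitesimal_single(
                study.ss1.beta_hat, blocks, h2_1.per_snp_h2, n1
            )
        else:
            res = run_gibbs_single(
                study.ss1.beta_hat, blocks, h2_1.per_snp_h2, n1,
                h2_1.total_h2, alpha=np.asarray(alpha[:2]),
                n_iter=n_iter, burn_in=burn_in, seed=seed,
            )
            out["effects1"] = res.post_mean1
            out["diagnostics"] = res
        return out

    h2_2 = estimate_heritability(study.ss2, scores, annot)
    out["h2_2"] = h2_2
    n2 = float(np.mean(study.ss2.n))
    if _is_infinitesimal(model):
        eff1, eff2 = run_infinitesimal(
            study, blocks, (h2_1, h2_2), rho_g, config=two_trait_config
        )
    else:
        res = run_gibbs(
            study.ss1.beta_hat, study.ss2.beta_hat, blocks,
            h2_1.per_snp_h2, h2_2.per_snp_h2, n1, n2,
            h2_1.total_h2, h2_2.total_h2,
            prior=MixturePrior(np.asarray(alpha)),
            n_iter=n_iter, burn_in=burn_in, seed=seed,
        )
        eff1, eff2 = res.post_mean1, res.post_mean2
        out["diagnostics"] = res
    out["effects1"] = eff1
    out["effects2"] = eff2
    return out


def _effects_frame(study: HarmonizedStudy, eff1, eff2) -> pd.DataFrame:
    df = study.panel.snps[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    df["posterior_beta_1"] = eff1
    df["posterior_beta_2"] = eff2 if eff2 is not None else np.nan
    return df


def run_pipeline(
    config: RunConfig,
    study: HarmonizedStudy | None = None,
    valid: GenotypePanel | None = None,
    phenotype=None,
) -> dict:
    """Execute the full pipeline and write its artifact bundle.

    Inputs are read from the paths in ``config`` unless pre-built objects
    are passed. Writes ``effects.tsv``, ``prs.tsv``, ``eval.json`` and a
    resolved-config file under ``config.out``, and returns the in-memory
    artifacts.
    """
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)

    if study is None:
        ss1 = load_summary_stats(config.ssf1)
        ss2 = load_summary_stats(config.ssf2) if config.ssf2 else ss1
        panel = read_plink(config.ref).qc()
        annot = (AnnotationSet.read_tsv(config.annot) if config.annot
                 else AnnotationSet.whole_genome(panel.snp_ids))
        study = harmonize(ss1, ss2, panel, annot)
        logger.info("harmonized %d SNPs (%d dropped)", study.m, study.n_dropped)
    if valid is None and config.valid:
        valid = read_plink(config.valid).qc()
    if valid is not None and phenotype is None:
        phenotype = valid.phenotype

    blocks = build_blocks(study.panel, window_snps=config.ld_radius)
    ttc = TwoTraitConfig(
        overlap_n=config.overlap_n, overlap_rho_e=config.overlap_rho_e,
        use_overlap_term=config.use_overlap_term, rho_g=config.rho_g,
    )
    common = dict(alpha=config.alpha, n_iter=config.n_iter,
                  burn_in=config.burn_in, seed=config.seed,
                  ld_radius=config.ld_radius, two_trait_config=ttc)

    tuning = None
    needs_rho = _is_two_trait(config.model) and _is_infinitesimal(config.model)
    if needs_rho and config.rho_g == "grid":
        if valid is None or phenotype is None:
            raise ValueError("rho_g grid tuning requires a validation cohort "
                             "with phenotype")
        grid = list(RHO_G_GRID)
        prs_cache = {}

        def scorer(rho, idx):
            if rho not in prs_cache:
                fit = fit_model(study, blocks, config.model, rho_g=rho, **common)
                prs_cache[rho] = compute_prs(fit["effects1"], valid).prs
            return prs_cache[rho][idx]

        tuning = tune_split_half(grid, scorer, phenotype, seed=config.seed)
        full_cors = [abs(np.corrcoef(scorer(r, np.arange(len(phenotype))),
                                     phenotype)[0, 1]) for r in grid]
        rho_g = grid[int(np.argmax(full_cors))]
    else:
        rho_g = float(config.rho_g) if config.rho_g != "grid" else 0.0

    fit = fit_model(study, blocks, config.model, rho_g=rho_g, **common)
    eff = _effects_frame(study, fit["effects1"], fit["effects2"])
    eff.to_csv(out_dir / "effects.tsv", sep="\t", index=False)

    result = {"effects": eff, "model": config.model, "rho_g": rho_g,
              "tuning": tuning, "h2_1": fit["h2_1"], "h2_2": fit["h2_2"]}
    if valid is not None:
        weights = eff.rename(columns={"posterior_beta_1": "effect"})[
            ["snp_id", "a1", "a2", "effect"]
        ]
        prs = compute_prs(weights, valid, model=config.model)
        prs.write(out_dir / "prs.tsv")
        result["prs"] = prs
        if phenotype is not None:
            report = evaluate(prs, phenotype)
            result["eval"] = report
            payload = report.to_dict()
            payload["tuning"] = tuning
            payload["rho_g"] = rho_g
            payload["total_h2_1"] = fit["h2_1"].total_h2
            (out_dir / "eval.json").write_text(json.dumps(payload, indent=2))

    resolved = asdict(config)
    resolved["rho_g"] = rho_g
    (out_dir / "config.json").write_text(json.dumps(resolved, indent=2))
    return result
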