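"""Cross-dataset SNP harmonization.

Every downstream stage assumes one SNP universe in one canonical order
(chromosome, position) with one effect-allele convention (the reference
panel's A1). Harmonization intersects the SNP sets of both summary-statistic
tables, the LD reference panel and the annotations, flips effect signs where
a source's alleles are swapped, and drops SNPs whose allele pair cannot be
reconciled with the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .plink import GenotypePanel
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class HarmonizedStudy:
    """Two aligned summary-statistic sets, a panel and annotations.

    All members are restricted to the common SNP set in a single canonical
    order; every beta_hat is expressed relative to the canonical a1.
    """

    ss1: SummaryStats
    ss2: SummaryStats
    panel: GenotypePanel
    annot: AnnotationSet
    n_dropped: int = field(default=0)

    def __post_init__(self) -> None:
        ids = self.panel.snp_ids
        for other in (self.ss1.snp_ids, self.ss2.snp_ids, self.annot.snp_ids):
            if len(other) != len(ids) or not np.array_equal(other, ids):
                raise ValueError("harmonized members disagree on SNP sequence")

    @property
    def m(self) -> int:
        return self.panel.m_snps

    @property
    def snp_ids(self) -> np.ndarray:
        return self.panel.snp_ids


def _align_to_panel(ss: SummaryStats, canon: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Reorder ss rows to the canonical frame; return table and a keep mask.

    Effects for sources whose (a1, a2) are swapped relative to the canonical
    pair are sign-flipped; irreconcilable allele pairs are masked out.
    """
    t = ss.table.set_index("snp_id").loc[canon["snp_id"]].reset_index()
    same = (t["a1"].to_numpy() == canon["a1"].to_numpy()) & (
        t["a2"].to_numpy() == canon["a2"].to_numpy()
    )
    swapped = (t["a1"].to_numpy() == canon["a2"].to_numpy()) & (
        t["a2"].to_numpy() == canon["a1"].to_numpy()
    )
    keep = same | swapped
    out = t.copy()
    flip = np.where(swapped, -1.0, 1.0)
    out["beta_hat"] = t["beta_hat"].to_numpy() * flip
    if "z" in out.columns:
        out["z"] = t["z"].to_numpy() * flip
    out["a1"] = canon["a1"].to_numpy()
    out["a2"] = canon["a2"].to_numpy()
    out["chrom"] = canon["chrom"].to_numpy()
    out["pos"] = canon["pos"].to_numpy()
    return out, keep


def harmonize(
    ss1: SummaryStats,
    ss2: SummaryStats,
    panel: GenotypePanel,
    annot: AnnotationSet,
    force: bool = False,
) -> HarmonizedStudy:
    """Intersect and allele-align all inputs onto the panel's convention.

    Raises
    ------
    ValueError
        If the SNP intersection is empty, or if more than half of the
        intersecting SNPs are dropped for irreconcilable alleles (pass
        ``force=True`` to downgrade the latter to a warning).
    """
    common = set(ss1.snp_ids) & set(ss2.snp_ids) & set(panel.snp_ids) & set(
        annot.snp_ids
    )
    if not common:
        raise ValueError("no SNPs shared by all inputs")

    in_common = np.isin(panel.snp_ids, list(common))
    sub = panel.subset_snps(np.flatnonzero(in_common))
    order = np.lexsort(
        (sub.snps["pos"].to_numpy(), sub.snps["chrom"].to_numpy())
    )
    sub = sub.subset_snps(order)
    canon = sub.snps[["snp_id", "chrom", "pos", "a1", "a2"]].reset_index(drop=True)

    t1, keep1 = _align_to_panel(ss1, canon)
    t2, keep2 = _align_to_panel(ss2, canon)
    keep = keep1 & keep2
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("harmonize: dropping %d SNPs with irreconcilable alleles", n_drop)
    if n_drop > 0.5 * len(canon):
        msg = f"harmonize dropped {n_drop}/{len(canon)} SNPs (allele mismatch)"
        if not force:
            raise ValueError(msg + "; pass force=True to proceed")
        logger.warning(msg)

    kept = np.flatnonzero(keep)
    sub = sub.subset_snps(kept)
    t1 = t1.loc[keep].reset_index(drop=True)
    t2 = t2.loc[keep].reset_index(drop=True)

    annot_idx = pd.Series(
        np.arange(len(annot.snp_ids)), index=annot.snp_ids
    ).loc[sub.snp_ids].to_numpy()

    return HarmonizedStudy(
        SummaryStats(t1), SummaryStats(t2), sub, annot.subset(annot_idx),
        n_dropped=n_drop,
    )
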