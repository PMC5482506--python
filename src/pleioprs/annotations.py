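"""Functional annotation memberships per SNP.

An annotation set is an M x K binary membership matrix. A whole-genome
baseline category is always present (prepended if absent), so every SNP
belongs to at least one category and the annotation-additive variance model
is well defined genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASELINE = "base"


@dataclass
class AnnotationSet:
    snp_ids: np.ndarray
    membership: np.ndarray = field(repr=False)  # (M, K) in {0,1}
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        m = np.asarray(self.membership, dtype=np.int8)
        if m.ndim != 2 or m.shape[0] != len(self.snp_ids):
            raise ValueError("membership must be (M, K) aligned to snp_ids")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("membership entries must be 0/1")
        if not self.names:
            self.names = [f"A{k + 1}" for k in range(m.shape[1])]
        if len(self.names) != m.shape[1]:
            raise ValueError("names length must equal K")
        if BASELINE not in self.names:
            m = np.hstack([np.ones((m.shape[0], 1), dtype=np.int8), m])
            self.names = [BASELINE, *self.names]
        self.membership = m

    @property
    def k(self) -> int:
        return self.membership.shape[1]

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, index) -> "AnnotationSet":
        idx = np.asarray(index)
        return AnnotationSet(self.snp_ids[idx], self.membership[idx], list(self.names))

    @classmethod
    def whole_genome(cls, snp_ids) -> "AnnotationSet":
        """Single baseline category covering every SNP (unstratified prior)."""
        snp_ids = np.asarray(snp_ids)
        return cls(snp_ids, np.ones((len(snp_ids), 1), dtype=np.int8), [BASELINE])

    @classmethod
    def read_tsv(cls, path) -> "AnnotationSet":
        """Read a TSV of snp_id followed by K 0/1 membership columns."""
        df = pd.read_csv(path, sep="\t")
        names = [c for c in df.columns if c != "snp_id"]
        return cls(df["snp_id"].to_numpy(), df[names].to_numpy(np.int8), names)

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(self.membership, columns=self.names)
        df.insert(0, "snp_id", self.snp_ids)
        df.to_csv(path, sep="\t", index=False)


def annotations_from_bed(snps: pd.DataFrame, bed_paths: dict) -> AnnotationSet:
    """Intersect SNP positions against BED interval files.

    Parameters
    ----------
    snps
        DataFrame with ``snp_id, chrom, pos`` (pos 1-based).
    bed_paths
        Mapping of category name -> BED file path (0-based half-open
        intervals, columns chrom/start/end, no header).
    """
    m = len(snps)
    cols = {}
    chroms = snps["chrom"].astype(str).to_numpy()
    pos0 = snps["pos"].to_numpy() - 1  # to 0-based
    for name, path in bed_paths.items():
        bed = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                          names=["chrom", "start", "end"], dtype={"chrom": str})
        member = np.zeros(m, dtype=np.int8)
        for chrom, sub in bed.groupby("chrom"):
            on_chrom = np.flatnonzero(chroms == chrom)
            if on_chrom.size == 0:
                continue
            starts = np.sort(sub["start"].to_numpy())
            ends = sub["end"].to_numpy()[np.argsort(sub["start"].to_numpy())]
            # assumes non-overlapping intervals per track (merge upstream)
            idx = np.searchsorted(starts, pos0[on_chrom], side="right") - 1
            ok = idx >= 0
            hit = np.zeros(on_chrom.size, dtype=bool)
            hit[ok] = pos0[on_chrom[ok]] < ends[idx[ok]]
            member[on_chrom[hit]] = 1
        cols[name] = member
    mat = np.column_stack([cols[n] for n in bed_paths]) if cols else np.zeros((m, 0), np.int8)
    return AnnotationSet(snps["snp_id"].to_numpy(), mat, list(bed_paths))
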