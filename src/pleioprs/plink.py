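"""Genotype panels and PLINK bed/bim/fam input/output.

The binary bed format (v1.00, SNP-major) packs four samples per byte with
the 2-bit codes 00 = homozygous A1, 10 = heterozygous, 11 = homozygous A2,
01 = missing. Dosages here count copies of A1, the bim file's first allele,
which is also the effect-allele convention used for summary statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# per-byte decode table: byte -> dosages of 4 samples (A1 copies; -1 missing)
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DECODE = np.zeros((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _DECODE[_b, _k] = _CODE_TO_DOSAGE[(_b >> (2 * _k)) & 0b11]
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, -1: 0b01}


@dataclass
class GenotypePanel:
    """Individuals x SNPs dosage matrix with SNP metadata.

    Attributes
    ----------
    sample_ids : array of str
    snps : DataFrame with columns ``snp_id, chrom, pos, a1, a2``
    genotypes : (n_samples, M) array; {0,1,2} or fractional after
        mean-imputation of missing values
    phenotype : optional per-sample phenotype vector
    """

    sample_ids: np.ndarray
    snps: pd.DataFrame = field(repr=False)
    genotypes: np.ndarray = field(repr=False)
    phenotype: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if n != len(self.sample_ids) or m != len(self.snps):
            raise ValueError("genotype matrix dimensions inconsistent with metadata")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy()

    def standardized(self, dtype=np.float64) -> np.ndarray:
        """Column-standardized dosages (mean 0, variance 1 per SNP).

        Cached per dtype: the same panel is standardized repeatedly within
        a pipeline run (LD scores, posterior solves, scoring) and the
        genotype matrix is never mutated after construction. Callers must
        not write into the returned array.
        """
        cache = self.__dict__.setdefault("_std_cache", {})
        key = np.dtype(dtype).name
        if key in cache:
            return cache[key]
        x = self.genotypes.astype(dtype, copy=True)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant genotype column; run qc() first")
        x -= mu
        x /= sd
        cache[key] = x
        return x

    def qc(self, maf_min: float = 0.01) -> "GenotypePanel":
        """Impute missing dosages by the column mean and drop rare SNPs.

        SNPs with minor allele frequency below ``maf_min`` (or constant
        columns) are removed so every standardized column is well defined.
        """
        g = self.genotypes.astype(np.float64, copy=True)
        miss = g < 0
        if miss.any():
            col_mean = np.where(
                miss, 0.0, g
            ).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1)
            g[miss] = np.broadcast_to(col_mean, g.shape)[miss]
        freq = g.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        keep = (maf >= maf_min) & (g.std(axis=0) > 0)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("qc: dropping %d SNPs with MAF < %g or zero variance",
                        n_drop, maf_min)
        return GenotypePanel(
            self.sample_ids, self.snps.loc[keep], g[:, keep], self.phenotype
        )

    def subset_snps(self, index) -> "GenotypePanel":
        """Restrict (and reorder) to SNPs given by positional index."""
        idx = np.asarray(index)
        return GenotypePanel(
            self.sample_ids, self.snps.iloc[idx], self.genotypes[:, idx],
            self.phenotype,
        )


def read_plink(prefix) -> GenotypePanel:
    """Read a PLINK bed/bim/fam fileset given its path prefix."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed v1.00 file")
    bps = (n + 3) // 4  # bytes per SNP
    body = raw[3:]
    if body.size != m * bps:
        raise ValueError("bed file size inconsistent with bim/fam")
    geno = _DECODE[body.reshape(m, bps)].reshape(m, bps * 4)[:, :n].T
    pheno = fam["pheno"].to_numpy(dtype=float)
    # PLINK missing phenotype conventions: -9 or 0
    phenotype = None if np.all((pheno == -9) | (pheno == 0)) else pheno
    snps = bim[["snp_id", "chrom", "pos", "a1", "a2"]]
    return GenotypePanel(fam["iid"].to_numpy(), snps, geno, phenotype)


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write a panel as bed/bim/fam. Dosages are rounded to {0,1,2}."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    snps = panel.snps
    bim = pd.DataFrame({
        "chrom": snps["chrom"], "snp_id": snps["snp_id"], "cm": 0,
        "pos": snps["pos"], "a1": snps["a1"], "a2": snps["a2"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    pheno = panel.phenotype if panel.phenotype is not None else np.full(
        panel.n_samples, -9.0
    )
    fam = pd.DataFrame({
        "fid": panel.sample_ids, "iid": panel.sample_ids,
        "father": 0, "mother": 0, "sex": 0, "pheno": pheno,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n, m = panel.genotypes.shape
    g = np.rint(panel.genotypes).astype(np.int8)
    g[g < 0] = -1
    g[g > 2] = 2
    bps = (n + 3) // 4
    padded = np.full((m, bps * 4), -1, dtype=np.int8)
    padded[:, :n] = g.T
    codes = np.empty_like(padded, dtype=np.uint8)
    for dos, code in _DOSAGE_TO_CODE.items():
        codes[padded == dos] = code
    # pad samples beyond n encode as hom A2 (0) per PLINK convention
    codes[:, n:] = 0
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (
        (codes.reshape(m, bps, 4) << shifts[None, None, :]).sum(axis=2)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        packed.tofile(fh)
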