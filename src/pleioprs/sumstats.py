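"""GWAS summary statistics: container, loading and basic transforms.

Marginal effects are kept on the standardized scale throughout: genotypes
and phenotype are taken to have mean zero and variance one, so the marginal
estimator for SNP i is beta_hat_i = x_i' y / n with sampling variance
roughly 1/n under the null. Odds ratios are converted via log(OR); when
only a z-score is available the standardized effect is reconstructed as
sign(z) * |z| / sqrt(n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Allele pairs whose strand cannot be resolved without frequencies.
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_REQUIRED = ("snp_id", "chrom", "pos", "a1", "a2", "n")


class ColumnMapError(KeyError):
    """A required summary-statistics column could not be resolved."""


@dataclass
class SummaryStats:
    """Per-SNP marginal association estimates for one trait.

    Attributes
    ----------
    table
        DataFrame with columns ``snp_id, chrom, pos, a1, a2, beta_hat, n``
        and optionally ``z`` and ``p``. ``a1`` is the effect allele;
        ``beta_hat`` is the standardized marginal effect.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in (*_REQUIRED, "beta_hat") if c not in t.columns]
        if missing:
            raise ColumnMapError(f"missing required columns: {missing}")
        if t["snp_id"].duplicated().any():
            dups = t.loc[t["snp_id"].duplicated(), "snp_id"].head().tolist()
            raise ValueError(f"duplicate snp_ids, e.g. {dups}")
        if (t["a1"] == t["a2"]).any():
            raise ValueError("a1 == a2 for some SNPs")
        if (t["n"] < 1).any():
            raise ValueError("per-SNP sample size n must be >= 1")
        if not np.isfinite(t["beta_hat"]).all():
            raise ValueError("non-finite beta_hat")
        if "z" in t.columns:
            z, b = t["z"].to_numpy(), t["beta_hat"].to_numpy()
            if np.any(np.sign(z) * np.sign(b) < 0):
                raise ValueError("sign(z) disagrees with sign(beta_hat)")
        if "p" in t.columns:
            p = t["p"].to_numpy()
            if np.any((p <= 0) | (p > 1)):
                raise ValueError("p-values must lie in (0, 1]")
        self.table = t.reset_index(drop=True)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def beta_hat(self) -> np.ndarray:
        return self.table["beta_hat"].to_numpy(dtype=float)

    @property
    def n(self) -> np.ndarray:
        return self.table["n"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    def write(self, path) -> None:
        """Write as a tab-delimited file (lossless round trip)."""
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SummaryStats":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def load_summary_stats(
    path,
    column_map: dict | None = None,
    drop_ambiguous: bool = True,
) -> SummaryStats:
    """Load GWAS summary statistics from a delimited text file.

    Parameters
    ----------
    path
        Whitespace- or tab-delimited file with a header (gzip accepted).
    column_map
        Maps canonical names (``snp_id, chrom, pos, a1, a2, n`` plus one of
        ``beta`` / ``or`` / ``z`` with ``p``) to the file's column names.
        Identity mapping by default.
    drop_ambiguous
        Drop strand-ambiguous SNPs (A/T, C/G pairs); these cannot be
        aligned to a reference panel without allele frequencies.
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype={"chrom": str})
    cmap = dict(column_map or {})
    rename = {v: k for k, v in cmap.items() if v in raw.columns}
    df = raw.rename(columns=rename)
    df.columns = [c.lower()
                  if c.lower() in (*_REQUIRED, "beta_hat", "beta", "or", "z", "p")
                  else c
                  for c in df.columns]

    for col in _REQUIRED:
        if col not in df.columns:
            raise ColumnMapError(
                f"required column {col!r} not found (have {list(raw.columns)})"
            )
    if (df["n"] <= 0).any():
        raise ValueError("non-positive sample size n")

    if "beta_hat" in df.columns:
        # already on the standardized scale (our own write format)
        df["beta_hat"] = df["beta_hat"].astype(float)
    elif "beta" in df.columns:
        df["beta_hat"] = df["beta"].astype(float)
    elif "or" in df.columns:
        if (df["or"] <= 0).any():
            raise ValueError("odds ratios must be positive")
        df["beta_hat"] = np.log(df["or"].astype(float))
    elif "z" in df.columns:
        df["beta_hat"] = df["z"].astype(float) / np.sqrt(df["n"].astype(float))
    else:
        raise ColumnMapError("need an effect column: one of beta, OR, or z")

    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)

    bad = df["a1"].isna() | df["a2"].isna() | (df["a1"] == "") | (df["a2"] == "")
    if drop_ambiguous:
        amb = [
            (x, y) in AMBIGUOUS_PAIRS for x, y in zip(df["a1"], df["a2"])
        ]
        bad = bad | np.asarray(amb)
    n_drop = int(bad.sum())
    if n_drop:
        logger.info("dropping %d SNPs with missing or strand-ambiguous alleles", n_drop)
        df = df.loc[~bad]

    keep = [*_REQUIRED, "beta_hat"] + [c for c in ("z", "p") if c in df.columns]
    return SummaryStats(df[keep].reset_index(drop=True))


def dichotomize_scores(scores, cutoff: float = 0.5) -> np.ndarray:
    """Turn continuous functional scores in [0, 1] into a 0/1 annotation.

    A SNP is annotated (1) when its score is strictly greater than the
    cutoff; scores equal to the cutoff map to 0.
    """
    s = np.asarray(scores, dtype=float)
    if np.any((s < 0) | (s > 1)) or not np.isfinite(s).all():
        raise ValueError("scores must lie in [0, 1]")
    return (s > cutoff).astype(np.int8)
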