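import numpy as np
import pandas as pd
import pytest

from pleioprs.annotations import AnnotationSet
from pleioprs.plink import GenotypePanel
from pleioprs.sumstats import SummaryStats


def make_snps(m, chrom="1", start_pos=1000):
    return pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(m)],
        "chrom": chrom,
        "pos": start_pos + np.arange(m) * 1000,
        "a1": "A",
        "a2": "G",
    })


def make_sumstats(m, beta=None, n=10000, rng=None, **overrides):
    t = make_snps(m)
    if beta is None:
        rng = rng or np.random.default_rng(0)
        beta = rng.normal(0, 1 / np.sqrt(n), size=m)
    t["beta_hat"] = beta
    t["n"] = n
    for k, v in overrides.items():
        t[k] = v
    return SummaryStats(t)


def make_panel(m, n=200, rng=None, mafs=None, chrom="1"):
    rng = rng or np.random.default_rng(0)
    if mafs is None:
        mafs = rng.uniform(0.1, 0.5, size=m)
    g = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    ids = np.array([f"s{i}" for i in range(n)])
    return GenotypePanel(ids, make_snps(m, chrom=chrom), g)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_panel():
    return make_panel(m=50, n=500)


@pytest.fixture
def whole_genome_annot():
    def _make(snp_ids):
        return AnnotationSet.whole_genome(snp_ids)
    return _make
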