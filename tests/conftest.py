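import numpy as np
import pytest

from sweepscan import VariantTable


def build_table(
    gt,
    pos=None,
    pops=None,
    ref=None,
    alt=None,
    dp=None,
    mq=None,
    phased=True,
    chrom="chr1",
):
    """Construct a VariantTable from a (n_sites, n_samples, 2) genotype array."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples, _ = gt.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if pops is None:
        half = n_samples // 2 or 1
        pops = ["focal"] * half + ["control"] * (n_samples - half)
    samples = [f"s{i + 1:02d}" for i in range(n_samples)]
    return VariantTable(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object) if ref is None else np.asarray(ref, dtype=object),
        alt=np.array(["G"] * n_sites, dtype=object) if alt is None else np.asarray(alt, dtype=object),
        mq=np.full(n_sites, 40.0) if mq is None else np.asarray(mq, dtype=np.float64),
        gt=gt,
        dp=np.full((n_sites, n_samples), 10, dtype=np.int32) if dp is None else np.asarray(dp, dtype=np.int32),
        phased=np.full((n_sites, n_samples), phased, dtype=bool),
        samples=samples,
        populations=np.array(pops, dtype=object),
    )


def random_table(rng, n_sites=50, n_samples=10, miss_frac=0.0, pos_step=50):
    """Random biallelic table with optional missing genotypes."""
    gt = rng.integers(0, 2, size=(n_sites, n_samples, 2)).astype(np.int8)
    if miss_frac > 0:
        missing = rng.random((n_sites, n_samples)) < miss_frac
        gt[missing] = -1
    pos = np.cumsum(rng.integers(1, pos_step, size=n_sites)) + 10
    return build_table(gt, pos=pos)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def table_factory():
    return build_table
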