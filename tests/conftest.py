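import numpy as np
import pytest

from introkit.genio import HaplotypeMatrix


def make_matrix(alleles, pos=None, chrom="chr1", sample_prefix="s"):
    """Build a HaplotypeMatrix from a plain (haplotypes x sites) array."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_hap, n_sites = alleles.shape
    assert n_hap % 2 == 0
    if pos is None:
        pos = 1 + 1000 * np.arange(n_sites)
    return HaplotypeMatrix(
        alleles=alleles,
        sample_ids=[f"{sample_prefix}{i}" for i in range(n_hap // 2)],
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
    )


@pytest.fixture
def random_matrix():
    """20 haplotypes x 200 sites with intermediate frequencies."""
    rng = np.random.default_rng(42)
    freq = rng.uniform(0.1, 0.9, 200)
    alleles = (rng.random((20, 200)) < freq).astype(np.int8)
    return make_matrix(alleles)
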