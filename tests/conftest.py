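import numpy as np
import pytest

from haplopop.io_formats import SiteMatrix
from haplopop.synthetic import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def dataset(default_config):
    """One default synthetic dataset, shared across the suite."""
    return generate_dataset(default_config, seed=1)


def make_site_matrix(alleles, ref=None, chrom_length=None, depth=None, samples=None):
    """SiteMatrix from a dense (n_sites, n_samples) allele-code array."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_sites, n_samples = alleles.shape
    if ref is None:
        ref = np.zeros(n_sites, dtype=np.int8)
    if depth is None:
        depth = np.full(alleles.shape, 10, dtype=np.int32)
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    length = chrom_length or n_sites
    return SiteMatrix(
        chrom_names=["chr1"],
        chrom_lengths=[length],
        chrom_index=np.zeros(n_sites, dtype=np.int32),
        pos=np.arange(n_sites, dtype=np.int64),
        samples=samples,
        ref=np.asarray(ref, dtype=np.int8),
        alleles=alleles,
        depth=np.asarray(depth, dtype=np.int32),
    )
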