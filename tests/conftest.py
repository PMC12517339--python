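import numpy as np
import pytest

from bts.core_model import ModelConfig, RegionData, Variant


def make_region(region_id, z, ld, chrom="chr1", start=1000, spacing=1000):
    z = np.asarray(z, dtype=float)
    variants = [
        Variant(f"{region_id}_v{i}", chrom, start + i * spacing, "A", "G")
        for i in range(len(z))
    ]
    return RegionData(region_id, variants, z, np.asarray(ld, dtype=float))


def random_correlation(n, rng):
    """Random well-conditioned correlation matrix."""
    a = rng.standard_normal((n, n + 5))
    cov = a @ a.T + 0.5 * np.eye(n)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_config():
    return ModelConfig()


@pytest.fixture
def two_indep_region():
    return make_region("indep", [10.0, 10.0], np.eye(2))


@pytest.fixture
def perfect_ld_region():
    return make_region("perfect", [10.0, 10.0], [[1.0, 1.0], [1.0, 1.0]])
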