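import warnings

import numpy as np
import pytest

from calscope.contacts import ContactMap
from calscope.genome import BinnedGenome


def random_raw_map(genome: BinnedGenome, rng, mean_count: float = 20.0,
                   decay: float = 0.0) -> ContactMap:
    """Random symmetric Poisson count map, optional power-law decay."""
    vals, msk = {}, {}
    for c in genome.chrom_names:
        n = genome.n_bins(c)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        lam = mean_count * np.maximum(d, 1.0) ** (-decay)
        up = np.triu(rng.poisson(lam)).astype(float)
        vals[c] = up + np.triu(up, 1).T
        msk[c] = np.zeros(n, dtype=bool)
    return ContactMap(genome, vals, msk, "raw")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def genome50():
    return BinnedGenome(("chr1",), (2_000_000,), 40_000)  # 50 bins


@pytest.fixture(scope="session")
def standard_bundle(tmp_path_factory):
    """The standard planted-structure fixture bundle (small profile)."""
    from calscope.simulate import write_fixture_bundle

    d = tmp_path_factory.mktemp("bundle_std")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        write_fixture_bundle(d, profile="small", seed=11, depth=5e6)
    return d


@pytest.fixture(scope="session")
def standard_run(standard_bundle, tmp_path_factory):
    """Full pipeline results on the standard bundle."""
    from calscope.pipeline import run_bundle

    out = tmp_path_factory.mktemp("run_std")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = run_bundle(standard_bundle, out, seed=3)
    return results, standard_bundle, out
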