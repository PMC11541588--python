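import numpy as np
import pandas as pd
import pytest

from denovokit.simdata import (
    SimConfig,
    build_context_index,
    make_reference_catalogs,
    simulate_genome,
)


@pytest.fixture(scope="session")
def genome50k():
    return simulate_genome(50_000, gc=0.41, cpg_frac=0.02, seed=11)


@pytest.fixture(scope="session")
def ctx_index(genome50k):
    return build_context_index(genome50k)


@pytest.fixture(scope="session")
def fixture_catalogs():
    """Five random sparse reference signatures, 96- and 192-channel."""
    return make_reference_catalogs(5, seed=7)


@pytest.fixture()
def small_config():
    return SimConfig(n_families=4, genome_length=60_000, seed=5)


def random_variant_table(n, seed=0):
    """Random trio-metric candidate table for filter-cascade tests."""
    rng = np.random.default_rng(seed)
    depth = rng.integers(5, 60, size=(n, 3))
    alt = rng.integers(0, 20, size=n)
    alt = np.minimum(alt, depth[:, 0])
    fwd = rng.integers(0, alt + 1)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": rng.integers(100, 10_000, size=n),
            "ref": "C",
            "alt": "T",
            "child_id": rng.choice([f"c{i}" for i in range(8)], size=n),
            "family_id": "F01",
            "callers": "A",
            "child_depth": depth[:, 0],
            "father_depth": depth[:, 1],
            "mother_depth": depth[:, 2],
            "child_alt": alt,
            "father_alt": rng.integers(0, 4, size=n),
            "mother_alt": rng.integers(0, 4, size=n),
            "child_alt_fwd": fwd,
            "child_alt_rev": alt - fwd,
            "child_gq": rng.integers(0, 100, size=n),
            "father_gq": rng.integers(0, 100, size=n),
            "mother_gq": rng.integers(0, 100, size=n),
        }
    )
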