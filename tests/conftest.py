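import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from ligasetrap.io import RunMetadata, SpectralCountTable, load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture
def small_table():
    """3 proteins x 5 runs: 3 bait + 2 control."""
    runs = [
        RunMetadata("b1", "bait", 1),
        RunMetadata("b2", "bait", 2),
        RunMetadata("b3", "bait", 3),
        RunMetadata("c1", "control", 1),
        RunMetadata("c2", "control", 2),
    ]
    counts = np.array(
        [
            [12, 11, 13, 0, 0],  # clean candidate
            [33, 18, 36, 2, 0],  # control-detected
            [0, 0, 0, 0, 0],  # silent
        ]
    )
    return SpectralCountTable(
        proteins=["clean", "sticky", "silent"],
        runs=runs,
        counts=counts,
        lengths={"clean": 100, "sticky": 200, "silent": 300},
    )


def random_table(rng, n_proteins=5, n_bait=3, n_control=2, max_count=20):
    """Small random table for property tests (always valid)."""
    runs = [RunMetadata(f"b{i}", "bait", i + 1) for i in range(n_bait)] + [
        RunMetadata(f"c{i}", "control", i + 1) for i in range(n_control)
    ]
    counts = rng.integers(0, max_count + 1, size=(n_proteins, n_bait + n_control))
    lengths = {f"p{i}": int(L) for i, L in enumerate(rng.integers(50, 2000, n_proteins))}
    return SpectralCountTable(
        proteins=[f"p{i}" for i in range(n_proteins)],
        runs=runs,
        counts=counts,
        lengths=lengths,
    )
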