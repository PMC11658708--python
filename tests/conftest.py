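import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # panels.py helper module

from meiomap.genome import GenomeModel, yeast_genome
from meiomap.simdata import SimParams, generate_marker_map, simulate_meiosis


@pytest.fixture(scope="session")
def genome():
    return yeast_genome()


@pytest.fixture(scope="session")
def toy_genome():
    return GenomeModel(
        names=("chrA", "chrB"),
        lengths=(1_000_000, 400_000),
        centromeres=(500_000, 100_000),
    )


@pytest.fixture(scope="session")
def marker_map(genome):
    """Dense genome-wide marker map shared by the heavier tests."""
    return generate_marker_map(genome, mean_spacing=169.0, seed=1)


@pytest.fixture(scope="session")
def clean_meiosis(marker_map, genome):
    """One simulated meiosis with guarded event separation (unambiguous truth)."""
    params = SimParams(
        seed=3, mean_co=90.0, nco_co_ratio=1 / 3, multi_dsb_rate=0.0,
        min_event_sep=7000.0,
    )
    matrices, truth = simulate_meiosis(marker_map, genome, params)
    return matrices, truth
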