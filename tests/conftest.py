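import numpy as np
import pandas as pd
import pytest

from aldmix.genome_windows import GeneticMap, build_windows
from aldmix.simulator import SyntheticPanelSpec, simulate_panels


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy_map():
    """Two-chromosome map with uneven recombination rates."""
    return GeneticMap(
        pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(6)],
                "chromosome": ["1", "1", "1", "chr2", "chr2", "chr2"],
                "position_bp": [1000, 2000, 4000, 500, 1500, 3000],
                "position_cm": [0.0, 1.0, 2.0, 0.0, 0.5, 2.5],
            }
        )
    )


@pytest.fixture(scope="session")
def small_panels():
    """Two modest diverged panels with LD, plus marker positions."""
    spec = SyntheticPanelSpec(
        n_hap=60, n_markers=300, divergence=0.15, length_cm=15.0, seed=5
    )
    panels, _, freqs = simulate_panels(spec)
    return panels, spec.positions_cm(), freqs


@pytest.fixture(scope="session")
def small_windows(small_panels):
    _, cm, _ = small_panels
    return build_windows(np.repeat("1", cm.size), cm, 0.1)
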