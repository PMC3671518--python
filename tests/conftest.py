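from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from anagen.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_bundle():
    """One shared small synthetic study with planted SSRs and DE contigs."""
    return simulate_study(
        SimulationConfig(
            n_contigs=400,
            seed=7,
            ssr_plants=(("AC", 9, 0), ("AGC", 7, 1), ("AT", 12, 2)),
        )
    )
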