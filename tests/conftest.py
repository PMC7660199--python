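import numpy as np
import pandas as pd
import pytest

from cfish.codebook import Codebook, generate_codebook
from cfish.simulator import SimulationConfig


def alternating_codebook(n_cycles: int = 16) -> Codebook:
    """Two-gene alternating scheme: GAPDH starts on Quasar 570 and swaps
    channel every cycle; Ki67 is the complement."""
    entries = {
        "GAPDH": tuple(c % 2 for c in range(n_cycles)),
        "Ki67": tuple((c + 1) % 2 for c in range(n_cycles)),
    }
    return Codebook.from_entries(entries, n_channels=2, n_cycles=n_cycles)


@pytest.fixture
def fig_codebook() -> Codebook:
    return alternating_codebook(16)


@pytest.fixture
def small_codebook() -> Codebook:
    return generate_codebook(2, 4, ["tA", "tB", "tC"])


def clean_config(**overrides) -> SimulationConfig:
    """Noise-free, drift-free, residual-free, dropout-free conditions."""
    base = dict(
        n_cycles=16,
        n_channels=2,
        image_size=(256, 256),
        shot_noise=False,
        read_noise=0.0,
        bleach_residual=0.0,
        dropout_prob=0.0,
        nonspecific_rate=0.0,
        brightness_cv=0.0,
        drift_per_cycle=(0.0, 0.0),
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def noisy_config(**overrides) -> SimulationConfig:
    """The default noisy, drifting study conditions."""
    base = dict(n_cycles=16, n_channels=2, drift_per_cycle=(0.5, -0.3), seed=0)
    base.update(overrides)
    return SimulationConfig(**base)


def single_spot_truth(row: float, col: float, target: str = "GAPDH") -> pd.DataFrame:
    return pd.DataFrame([dict(cell_id=1, target_id=target, row=row, col=col)])


def spot_grid_truth(
    n: int, target: str = "GAPDH", spacing: float = 12.0, origin: float = 15.0
) -> pd.DataFrame:
    side = int(np.ceil(np.sqrt(n)))
    rows = []
    for i in range(n):
        rows.append(
            dict(
                cell_id=1,
                target_id=target,
                row=origin + (i // side) * spacing,
                col=origin + (i % side) * spacing,
            )
        )
    return pd.DataFrame(rows)
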