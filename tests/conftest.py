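import numpy as np
import pytest

from ftims import DriftCell, IonSpecies, default_calibration_constant


@pytest.fixture
def calib_cell() -> DriftCell:
    """Default calibration-mode cell (C fitted from the TXA benchmark rows)."""
    return DriftCell.from_calibration(default_calibration_constant())


@pytest.fixture
def single_ion() -> list[IonSpecies]:
    """One zero-width ion at 30 ms — the workhorse of resolution tests."""
    return [IonSpecies(name="probe", td=30.0, abundance=1.0, sigma=0.0)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
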