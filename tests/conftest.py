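import numpy as np
import pytest

from ctcsegaudit import CartridgeSpec, SimConfig, generate_cartridge


@pytest.fixture(scope="session")
def small_spec() -> CartridgeSpec:
    """A desk-scale cartridge: 2 frames of 128x160 px."""
    return CartridgeSpec(n_frames=2, frame_height_px=128, frame_width_px=160)


@pytest.fixture(scope="session")
def mixed_archive(small_spec):
    """A small cartridge with all four object classes."""
    cfg = SimConfig(tumor_cells=8, leukocytes=20, tdevs=6, bare_nuclei=4, seed=42)
    return generate_cartridge(small_spec, cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
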