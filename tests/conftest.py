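import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from octbiofilm.core_io import VoxelSpec


@pytest.fixture
def voxel() -> VoxelSpec:
    """Instrument-like geometry: 8 µm lateral, 2.1 µm axial in water."""
    return VoxelSpec(dx=8.0, dy=8.0, dz_air=2.793, refractive_index=1.33)


@pytest.fixture
def coarse_voxel() -> VoxelSpec:
    """Coarse test grid: 20 µm lateral, 15 µm axial in water."""
    return VoxelSpec(dx=20.0, dy=20.0, dz_air=19.95, refractive_index=1.33)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_slab(nz: int, ny: int, nx: int, k: int) -> np.ndarray:
    """Binary volume with a uniform biomass slab occupying z in [0, k)."""
    vol = np.zeros((nz, ny, nx), dtype=np.uint8)
    vol[:k] = 255
    return vol
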