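import numpy as np
import pytest

from canopyreg import (
    BinaryRaster,
    LandUseMap,
    build_queen_weights,
    row_standardize,
    simulate_partition,
)


@pytest.fixture(scope="session")
def lattice_5x5():
    """5x5 regular tract lattice with row-standardized queen weights."""
    part, _ = simulate_partition(5, 5, 4)
    W = row_standardize(build_queen_weights(part))
    return part, W


@pytest.fixture(scope="session")
def lattice_10x10_weights():
    part, _ = simulate_partition(10, 10, 2)
    return row_standardize(build_queen_weights(part))


@pytest.fixture()
def rng():
    return np.random.default_rng(20210327)


@pytest.fixture(scope="session")
def hand_fixture():
    """One 10x10 tract with hand-placed canopy, land use and greenspace.

    Canopy patches (8- and 4-connectivity give the same components):
      A: 2x2 block rows 1-2, cols 1-2          (area 4)
      B: single cell (1, 7)                    (area 1)
      C: L-shape (7,2), (8,2), (8,3)           (area 3)
    Land use: cols 0-4 residential, 5-7 golf, 8-9 park_recreation.
    Green cells: 6 residential, 3 golf, 2 park.
    """
    part, _ = simulate_partition(1, 1, 10)
    canopy = np.zeros((10, 10), dtype=np.uint8)
    canopy[1:3, 1:3] = 1
    canopy[1, 7] = 1
    canopy[7, 2] = canopy[8, 2] = canopy[8, 3] = 1
    labels = np.zeros((10, 10), dtype=np.int16)
    labels[:, 0:5] = LandUseMap.code("residential")
    labels[:, 5:8] = LandUseMap.code("golf")
    labels[:, 8:10] = LandUseMap.code("park_recreation")
    green = np.zeros((10, 10), dtype=np.uint8)
    green[5, 0:3] = 1   # 3 residential cells
    green[6, 1:4] = 1   # 3 more residential cells
    green[3, 5:8] = 1   # 3 golf cells
    green[9, 8:10] = 1  # 2 park cells
    return (part, BinaryRaster(canopy), LandUseMap(labels),
            BinaryRaster(green))
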