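import numpy as np
import pytest

from redsea import (
    CellType,
    SegmentationMask,
    SyntheticSpec,
    generate_scene,
)


@pytest.fixture
def enclosed_mask():
    """A 3x3 cell (label 1) fully enclosed by cell 2, one-pixel zero ring.

    P_1 = b_12 = 16: every boundary pixel of cell 1 also touches cell 2, the
    regime where reinforcement exactly returns the cell's region signal.
    """
    labels = np.full((9, 9), 2, dtype=np.int64)
    labels[2:7, 2:7] = 0
    labels[3:6, 3:6] = 1
    return SegmentationMask(labels)


@pytest.fixture
def single_cell_mask():
    """One 3x3 cell centered in a 7x7 canvas of zeros."""
    labels = np.zeros((7, 7), dtype=np.int64)
    labels[2:5, 2:5] = 1
    return SegmentationMask(labels)


@pytest.fixture
def two_cell_mask():
    """Two 2x2 cells separated by one zero column, 7x6 canvas."""
    labels = np.zeros((7, 6), dtype=np.int64)
    labels[2:4, 1:3] = 1
    labels[2:4, 4:6] = 2
    return SegmentationMask(labels)


@pytest.fixture(scope="session")
def small_scene():
    """A deterministic 48x48 scene with 12 cells and moderate spillover."""
    spec = SyntheticSpec(height=48, width=48, n_cells=12, spillover=0.25, seed=11)
    return generate_scene(spec)


def two_type_cell_types(intensity: float = 10.0):
    """Two cell types with one mutually exclusive marker pair + nuclear channel."""
    v = float(intensity)
    return (
        CellType("T", {"dsDNA": v, "CD3": v, "CD20": 0.0}),
        CellType("B", {"dsDNA": v, "CD3": 0.0, "CD20": v}),
    )


def random_small_masks(n_masks: int, seed: int, max_side: int = 32, max_cells: int
= 12):
    """Yield (index, mask) for a family of random packed masks."""
    rng = np.random.default_rng(seed)
    for i in range(n_masks):
        h = int(rng.integers(16, max_side + 1))
        w = int(rng.integers(16, max_side + 1))
        n = int(rng.integers(2, min(max_cells, (h * w) // 25) + 1))
        spec = SyntheticSpec(height=h, width=w, n_cells=n, seed=int(rng.integers(2**31)))
        from redsea import generate_mask

        yield i, generate_mask(spec, np.random.default_rng(spec.seed))
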