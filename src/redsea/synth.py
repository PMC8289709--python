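"""Synthetic packed-tissue scenes with known cell types and spillover.

The generator emulates the regime the compensation method targets: a canvas
densely tiled with cells separated by a one-pixel zero boundary, each cell
expressing membrane-localized markers deposited uniformly on its border
pixels, with mutually exclusive marker pairs across cell types (the CD3/CD20
and CD4/CD8 situation) plus one nuclear channel shared by every cell.

Spillover is modeled as explicit mass transfer between adjacent cells: a
fraction ``spillover * b_AK / P_A`` of donor A's membrane signal moves onto
neighbor K's border pixels, uniformly. This isolates exactly the
lateral-adjacency mechanism the compensation equations model — signal is
moved, never created, so total signal is conserved at every spillover level
(before optional Poisson resampling) — and keeps the oracle math of small
scenes hand-computable. What it does not emulate: realistic cell morphology,
nucleus/cytoplasm compartments, segmentation errors, or smooth point-spread
blur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .borders import find_border_pixels, make_structuring_element
from .imgio import ChannelManifest, ChannelStack, SegmentationMask
from .topology import compute_adjacency

#: Element defining where membrane signal is deposited.
_MEMBRANE_ELEMENT = ("star", 2)

_MIN_PIXELS_PER_CELL = 25


@dataclass(frozen=True)
class CellType:
    """A named cell type with expected membrane intensity per channel."""

    name: str
    profile: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.profile.values()):
            raise ValueError(f"marker profile for {self.name!r} must be non-negative")


def default_cell_types(intensity: float = 10.0) -> tuple[CellType, ...]:
    """Two mutually exclusive marker pairs plus a shared nuclear channel.

    T cells carry CD3 and exactly one of CD4/CD8; B cells carry CD20;
    every type carries dsDNA. ``intensity`` is the expected per-border-pixel
    count of an expressed marker.
    """
    v = float(intensity)
    return (
        CellType("T_helper", {"dsDNA": v, "CD3": v, "CD4": v, "CD8": 0.0, "CD20": 0.0}),
        CellType("T_cytotoxic", {"dsDNA": v, "CD3": v, "CD4": 0.0, "CD8": v, "CD20": 0.0}),
        CellType("B", {"dsDNA": v, "CD3": 0.0, "CD4": 0.0, "CD8": 0.0, "CD20": v}),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for a scene; the scene is a pure function of this spec."""

    height: int = 128
    width: int = 128
    n_cells: int = 50
    cell_types: tuple[CellType, ...] = field(default_factory=default_cell_types)
    spillover: float = 0.3
    noise: str = "none"
    seed: int = 0
    nuclear_channels: tuple[str, ...] = ("dsDNA",)

    def __post_init__(self):
        if not 0 <= self.spillover < 1:
            raise ValueError("spillover fraction must be in [0, 1)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"noise must be 'none' or 'poisson', got {self.noise!r}")
        if not self.cell_types:
            raise ValueError("at least one cell type required")

    @property
    def channel_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for ct in self.cell_types:
            for ch in ct.profile:
                if ch not in names:
                    names.append(ch)
        return tuple(names)


@dataclass(frozen=True)
class SyntheticScene:
    mask: SegmentationMask
    stack: ChannelStack
    truth: pd.DataFrame  # index: cell label; columns: cell_type + per-channel totals
    spec: SyntheticSpec

    def manifest(self) -> ChannelManifest:
        """Default manifest: compensate every non-nuclear channel."""
        names = self.stack.channel_names
        return ChannelManifest(
            names, tuple(ch not in self.spec.nuclear_channels for ch in names)
        )


def _sample_seeds(
    h: int, w: int, n: int, rng: np.random.Generator, min_sep: int
) -> np.ndarray:
    """Rejection-sample n seed pixels with pairwise Chebyshev distance >= min_sep."""
    seeds: list[tuple[int, int]] = []
    attempts = 0
    while len(seeds) < n:
        attempts += 1
        if attempts > 500 * n:
            raise ValueError(
                f"could not place {n} seeds with separation {min_sep} on a {h}x{w} canvas"
            )
        r = int(rng.integers(1, h - 1))
        c = int(rng.integers(1, w - 1))
        if all(max(abs(r - sr), abs(c - sc)) >= min_sep for sr, sc in seeds):
            seeds.append((r, c))
    return np.array(seeds)


def _carve_boundary(labels: np.ndarray) -> np.ndarray:
    """Zero every pixel with an 8-neighbor of strictly greater positive label.

    One-sided carving yields a one-pixel boundary: after it, no two
    8-connected pixels carry different positive labels.
    """
    h, w = labels.shape
    padded = np.zeros((h + 2, w + 2), dtype=labels.dtype)
    padded[1:-1, 1:-1] = labels
    carve = np.zeros((h, w), dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if (dr, dc) == (0, 0):
                continue
            nb = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
            carve |= (labels > 0) & (nb > labels)
    out = labels.copy()
    out[carve] = 0
    return out


def generate_mask(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> SegmentationMask:
    """Tile the canvas with ``n_cells`` Voronoi regions and carve a zero boundary.

    Deterministic given the spec seed. Raises if the canvas is too small
    (< 25 pixels per cell) or seeds cannot be placed.
    """
    h, w, n = spec.height, spec.width, spec.n_cells
    if h * w < _MIN_PIXELS_PER_CELL * n:
        raise ValueError(
            f"canvas {h}x{w} too small for {n} cells (need >= {_MIN_PIXELS_PER_CELL} px/cell)"
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    for _ in range(10):
        seeds = _sample_seeds(h, w, n, rng, min_sep=4)
        seed_ids = np.zeros((h, w), dtype=np.int64)
        seed_ids[seeds[:, 0], seeds[:, 1]] = np.arange(1, n + 1)
        _, (ir, ic) = ndimage.distance_transform_edt(seed_ids == 0, return_indices=True)
        labels = _carve_boundary(seed_ids[ir, ic])
        present = np.unique(labels)
        if len(present[present > 0]) == n:
            return SegmentationMask(labels)
    raise ValueError("failed to generate a mask with all cells surviving boundary carving")


def render_channels(
    mask: SegmentationMask, spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[ChannelStack, pd.DataFrame]:
    """Deposit membrane signal, apply lateral spillover, optionally add noise.

    Each cell's expressed markers are placed uniformly on its border pixels
    (star element, size 2). For each neighbor K of donor A, the amount
    ``spillover * T_A * b_AK / P_A`` (T_A = A's noise-free total) moves from
    A's border pixels onto K's, uniformly. ``truth`` records each cell's type
    and pre-spillover, noise-free totals.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    adj = compute_adjacency(mask)
    element = make_structuring_element(*_MEMBRANE_ELEMENT)
    border = find_border_pixels(mask, element)
    cells = [int(c) for c in mask.cell_labels]
    type_idx = rng.integers(0, len(spec.cell_types), size=len(cells))
    cell_type = {c: spec.cell_types[i] for c, i in zip(cells, type_idx)}

    channels = spec.channel_names
    images = {ch: np.zeros(mask.shape) for ch in channels}
    truth = pd.DataFrame(
        {"cell_type": [cell_type[c].name for c in cells]},
        index=pd.Index(cells, name="cell"),
    )

    n_border = {c: len(border[c]) for c in cells}
    out_frac = {}
    for c in cells:
        p = adj.perimeter.get(c, 0)
        shared = sum(adj.b(c, k) for k in adj.neighbors(c)) if p else 0
        out_frac[c] = spec.spillover * shared / p if p else 0.0

    for ch in channels:
        totals = {c: cell_type[c].profile.get(ch, 0.0) * n_border[c] for c in cells}
        truth[ch] = [totals[c] for c in cells]
        img = images[ch]
        for c in cells:
            if n_border[c] == 0:
                continue
            incoming = sum(
                spec.spillover * totals[k] * adj.b(c, k) / adj.perimeter[k]
                for k in adj.neighbors(c)
            )
            per_pixel = (totals[c] * (1.0 - out_frac[c]) + incoming) / n_border[c]
            if per_pixel == 0.0:
                continue
            coords = np.array(sorted(border[c]))
            img[coords[:, 0], coords[:, 1]] += per_pixel

    pixels = np.stack([images[ch] for ch in channels])
    if spec.noise == "poisson":
        pixels = rng.poisson(pixels).astype(np.float64)
    return ChannelStack(pixels, channels), truth


def generate_scene(spec: SyntheticSpec) -> SyntheticScene:
    """Generate mask, channels and ground truth from one seeded stream."""
    rng = np.random.default_rng(spec.seed)
    mask = generate_mask(spec, rng)
    stack, truth = render_channels(mask, spec, rng)
    return SyntheticScene(mask, stack, truth, spec)
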