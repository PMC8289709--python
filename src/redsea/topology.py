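"""Cell adjacency from the zero-valued boundary pixels of a segmentation mask.

Every zero pixel is scanned with a 3x3 window; the distinct positive labels
among its 8 neighbors define which cells that boundary pixel serves. From
these per-pixel label sets come the two quantities the compensation
equations need:

* the perimeter ``P_A`` of cell A — the number of boundary pixels 8-adjacent
  to A;
* the shared boundary ``b_AK`` between cells A and K — the number of boundary
  pixels 8-adjacent to both.

A boundary pixel adjacent to m >= 3 cells contributes to every one of its
C(m, 2) unordered pairs: each pairwise spillover path is physical. Windows
are cropped at the image edge (no wrap-around). Perimeters are pixel counts,
not geometric lengths, because the compensation coefficients are the pixel
ratios b_AK / P.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .imgio import SegmentationMask

_NEIGHBOR_OFFSETS = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


@dataclass(frozen=True)
class AdjacencyModel:
    """Perimeters and pairwise shared-boundary counts of a mask.

    ``shared`` stores each unordered pair once under the key
    ``(min(A, K), max(A, K))``; pairs with no shared boundary are absent.
    """

    perimeter: dict[int, int]
    shared: dict[tuple[int, int], int]
    cells: frozenset[int]
    _neighbors: dict[int, tuple[int, ...]] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        nbrs: dict[int, list[int]] = {c: [] for c in self.cells}
        for a, k in self.shared:
            nbrs[a].append(k)
            nbrs[k].append(a)
        object.__setattr__(
            self, "_neighbors", {c: tuple(sorted(v)) for c, v in nbrs.items()}
        )

    def b(self, a: int, k: int) -> int:
        """Shared boundary pixel count; 0 when the cells do not touch."""
        return self.shared.get((min(a, k), max(a, k)), 0)

    def neighbors(self, a: int) -> tuple[int, ...]:
        """Labels sharing boundary with cell ``a``, ascending."""
        if a not in self.cells:
            raise KeyError(f"unknown cell label {a}")
        return self._neighbors[a]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Debug dump: (perimeter table, shared-boundary table)."""
        per = pd.DataFrame(
            {"cell": sorted(self.perimeter), "perimeter": [self.perimeter[c] for c in sorted(self.perimeter)]}
        )
        pairs = sorted(self.shared)
        sh = pd.DataFrame(
            {"cell_a": [p[0] for p in pairs], "cell_k": [p[1] for p in pairs],
             "shared_boundary": [self.shared[p] for p in pairs]}
        )
        return per, sh


def compute_adjacency(mask: SegmentationMask) -> AdjacencyModel:
    """Scan every boundary (zero) pixel's 3x3 neighborhood for cell labels.

    Returns an :class:`AdjacencyModel` whose ``cells`` are all positive labels
    in the mask, including cells with no neighbors. An all-zero mask yields an
    empty model.
    """
    labels = mask.labels
    h, w = labels.shape
    cells = frozenset(int(c) for c in mask.cell_labels)
    if not cells:
        return AdjacencyModel({}, {}, frozenset())

    padded = np.zeros((h + 2, w + 2), dtype=labels.dtype)
    padded[1:-1, 1:-1] = labels
    zero = labels == 0
    # (n_zero, 8) array of neighbor labels for every boundary/background pixel
    neigh = np.stack(
        [padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w][zero] for dr, dc in _NEIGHBOR_OFFSETS],
        axis=1,
    )
    neigh.sort(axis=1)
    positive = neigh > 0
    first = np.ones_like(positive)
    first[:, 1:] = neigh[:, 1:] != neigh[:, :-1]
    keep = positive & first

    perimeter_counts = np.bincount(neigh[keep], minlength=int(labels.max()) + 1)
    perimeter = {int(c): int(perimeter_counts[c]) for c in sorted(cells)}

    shared: dict[tuple[int, int], int] = {}
    multi = keep.sum(axis=1) >= 2
    for row_labels, row_keep in zip(neigh[multi], keep[multi]):
        distinct = row_labels[row_keep]
        for a, k in combinations(distinct.tolist(), 2):  # sorted ⇒ a < k
            key = (a, k)
            shared[key] = shared.get(key, 0) + 1

    return AdjacencyModel(perimeter, shared, cells)


def boundary_fraction(adj: AdjacencyModel, a: int, k: int, denominator: str = "K") -> float:
    """The compensation coefficient ``b_AK / P`` for a cell pair.

    ``denominator`` selects whose perimeter divides the shared boundary:
    ``"K"`` gives the subtraction coefficient ``b_AK / P_K`` and ``"A"`` the
    reinforcement coefficient ``b_AK / P_A``. Returns 0 for non-touching
    pairs; raises ``KeyError`` for labels absent from the model.
    """
    if a not in adj.cells:
        raise KeyError(f"unknown cell label {a}")
    if k not in adj.cells:
        raise KeyError(f"unknown cell label {k}")
    if denominator not in ("A", "K"):
        raise ValueError("denominator must be 'A' or 'K'")
    b = adj.b(a, k)
    if b == 0:
        return 0.0
    denom_cell = a if denominator == "A" else k
    return b / adj.perimeter[denom_cell]
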