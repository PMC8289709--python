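"""The compensation core: remove neighbor spillover and reinforce own signal.

For a cell A with neighbors K (sharing b_AK boundary pixels; perimeters P),
the corrected total for one channel is

    subtraction:   X_Acomp = X_A0 - sum_K Y_K * b_AK / P_K
    full (redsea): X_Acomp = X_A0 + sum_K Y_A * b_AK / P_A
                                  - sum_K Y_K * b_AK / P_K

where Y is the *region* signal: the cell's border-pixel total when
``region="border"``, or its whole-cell total when ``region="whole"``. The
subtraction term removes the share of each neighbor's signal attributable to
the shared boundary; the reinforcement term returns the cell's own spilled
signal in the same proportion. Negative results clip to zero after both
terms are combined.

The explicit neighbor-sum form is used with the actual b_AK and P values, not
the simplification that assumes every cell is fully enclosed
(sum_K b_AK = P_A): cells touching the image edge or background simply
receive partial reinforcement, which degrades gracefully.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .borders import BorderSignals, StructuringElement
from .imgio import COMPENSATED_SUFFIX, CellFeatureTable, ChannelStack, SegmentationMask
from .topology import AdjacencyModel

METHODS = ("subtraction", "redsea")
REGIONS = ("whole", "border")


@dataclass(frozen=True)
class CompensationConfig:
    """Which correction to run, on which signal region, for which channels."""

    method: str = "redsea"
    region: str = "border"
    element: StructuringElement | None = None
    channels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if not self.channels:
            raise ValueError("at least one channel must be selected for compensation")
        object.__setattr__(self, "channels", tuple(self.channels))


def extract_original(mask: SegmentationMask, stack: ChannelStack) -> CellFeatureTable:
    """Per-cell size, centroid and whole-cell channel totals (X_A0)."""
    if stack.pixels.shape[1:] != mask.shape:
        raise ValueError(
            f"stack shape {stack.pixels.shape[1:]} does not match mask shape {mask.shape}"
        )
    labels = mask.labels
    cells = [int(c) for c in mask.cell_labels]
    index = pd.Index(cells, name="cell")
    if not cells:
        cols = ["size", "centroid_row", "centroid_col", *stack.channel_names]
        return CellFeatureTable(pd.DataFrame(columns=cols, index=index), stack.channel_names)
    n = int(labels.max()) + 1
    flat = labels.ravel()
    sizes = np.bincount(flat, minlength=n)
    rows, cols_ = np.indices(labels.shape)
    sum_r = np.bincount(flat, weights=rows.ravel(), minlength=n)
    sum_c = np.bincount(flat, weights=cols_.ravel(), minlength=n)
    data = {
        "size": sizes[cells],
        "centroid_row": sum_r[cells] / sizes[cells],
        "centroid_col": sum_c[cells] / sizes[cells],
    }
    for name in stack.channel_names:
        data[name] = np.bincount(flat, weights=stack.channel(name).ravel(), minlength=n)[cells]
    return CellFeatureTable(pd.DataFrame(data, index=index), stack.channel_names)


def region_signals(
    table: CellFeatureTable, border: BorderSignals, region: str
) -> pd.DataFrame:
    """The Y terms of the correction: border totals or whole-cell totals."""
    if region == "border":
        return border.totals
    if region == "whole":
        return table.frame[list(table.channel_names)]
    raise ValueError(f"region must be one of {REGIONS}, got {region!r}")


def subtracted_signal(
    adj: AdjacencyModel, signals: pd.DataFrame, a: int, channel: str
) -> float:
    """Spillover received by cell ``a``: sum_K Y_K * b_AK / P_K.

    Accumulates in ascending neighbor-label order for determinism.
    """
    total = 0.0
    for k in adj.neighbors(a):
        total += float(signals.at[k, channel]) * adj.b(a, k) / adj.perimeter[k]
    return total


def reinforced_signal(
    adj: AdjacencyModel, signals: pd.DataFrame, a: int, channel: str
) -> float:
    """Cell ``a``'s own signal returned from neighbors: sum_K Y_A * b_AK / P_A."""
    neighbors = adj.neighbors(a)
    if not neighbors:
        return 0.0
    shared_total = sum(adj.b(a, k) for k in neighbors)
    return float(signals.at[a, channel]) * shared_total / adj.perimeter[a]


def compensate(
    table: CellFeatureTable,
    adj: AdjacencyModel,
    border: BorderSignals,
    config: CompensationConfig,
    clip: bool = True,
) -> CellFeatureTable:
    """Fill the compensated columns of a feature table.

    Channels not selected in ``config.channels`` are copied through
    unchanged (nuclear markers like dsDNA violate the membrane-localization
    assumptions and must not be corrected). ``clip=False`` skips the final
    negative-to-zero clip and exists for conservation diagnostics only.

    Returns a new table; metadata records the configuration and the number
    of clipped cells per channel.
    """
    unknown = set(config.channels) - set(table.channel_names)
    if unknown:
        raise ValueError(f"channels not present in table: {sorted(unknown)}")
    frame = table.frame.copy()
    cells = [int(c) for c in frame.index]
    signals = region_signals(table, border, config.region)

    # directed neighbor pair arrays, sorted by (A, K) for fixed accumulation order
    pairs = sorted(
        [(a, k) for (x, y) in adj.shared for a, k in ((x, y), (y, x))]
    )
    pos = {c: i for i, c in enumerate(cells)}
    a_idx = np.array([pos[a] for a, _ in pairs], dtype=np.intp)
    k_idx = np.array([pos[k] for _, k in pairs], dtype=np.intp)
    b_arr = np.array([adj.b(a, k) for a, k in pairs], dtype=np.float64)
    perim = np.array([adj.perimeter.get(c, 0) for c in cells], dtype=np.float64)
    shared_sum = np.zeros(len(cells))
    np.add.at(shared_sum, a_idx, b_arr)

    clipped: dict[str, int] = {}
    for ch in table.channel_names:
        comp_col = ch + COMPENSATED_SUFFIX
        original = frame[ch].to_numpy(dtype=np.float64)
        if ch not in config.channels:
            frame[comp_col] = original
            continue
        y = signals[ch].reindex(frame.index).to_numpy(dtype=np.float64)
        sub = np.zeros(len(cells))
        if len(pairs):
            np.add.at(sub, a_idx, y[k_idx] * b_arr / perim[k_idx])
        result = original - sub
        if config.method == "redsea":
            with np.errstate(invalid="ignore", divide="ignore"):
                reinf = np.where(perim > 0, y * shared_sum / perim, 0.0)
            result = result + reinf
        n_neg = int((result < 0).sum())
        if clip:
            result = np.maximum(result, 0.0)
        clipped[ch] = n_neg
        frame[comp_col] = result

    metadata = dict(table.metadata)
    metadata.update(
        {
            "method": config.method,
            "region": config.region,
            "element": None
            if config.element is None
            else {"shape": config.element.shape, "size": config.element.size},
            "compensated_channels": list(config.channels),
            "clipped_cells": clipped,
            "n_neighbor_pairs": len(adj.shared),
            "clip": clip,
        }
    )
    return CellFeatureTable(frame, table.channel_names, metadata)
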