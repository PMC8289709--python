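"""Post-extraction normalizations and display transforms.

Two distinct normalizations are used downstream of feature extraction:

* a per-cell display transform for comparing marker distributions —
  size-normalize, arcsinh with a cofactor, then a square root, the chain
  standard in mass-cytometry visualization;
* a clustering normalization — divide each marker by the per-field-of-view
  median of a reference nuclear channel (e.g. dsDNA), then min-max rescale
  each marker to [0, 1] over all cells pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TransformSpec:
    """Display-transform chain: x -> sqrt(asinh((x / size) / cofactor))."""

    size_normalize: bool = True
    cofactor: float = 1.0
    final_sqrt: bool = True

    def __post_init__(self):
        if self.cofactor <= 0:
            raise ValueError(f"cofactor must be > 0, got {self.cofactor}")


def transform_counts(x, size, spec: TransformSpec = TransformSpec()):
    """Apply the display transform to counts ``x`` from a cell of ``size`` pixels.

    Accepts scalars or arrays; strictly increasing in ``x`` and maps 0 to 0.
    """
    x = np.asarray(x, dtype=np.float64)
    size = np.asarray(size, dtype=np.float64)
    if (x < 0).any():
        raise ValueError("counts must be >= 0")
    if (size < 1).any():
        raise ValueError("cell size must be >= 1 pixel")
    y = x / size if spec.size_normalize else x
    y = np.arcsinh(y / spec.cofactor)
    if spec.final_sqrt:
        y = np.sqrt(y)
    return y if y.ndim else float(y)


def normalize_for_clustering(
    frame: pd.DataFrame,
    marker_channels: list[str],
    reference_channel: str,
    group: str | None = None,
) -> pd.DataFrame:
    """Reference-channel normalization followed by pooled min-max rescaling.

    Each marker value is divided by its group's median of
    ``reference_channel`` (one group = one field of view; ``group`` names the
    grouping column, or ``None`` treats the table as a single field), then
    each marker column is rescaled to [0, 1] over all cells. A constant
    column maps to all zeros. The output is invariant to uniform positive
    scaling of the input.
    """
    if reference_channel not in frame.columns:
        raise KeyError(f"reference channel {reference_channel!r} not in table")
    missing = [c for c in marker_channels if c not in frame.columns]
    if missing:
        raise KeyError(f"marker channels not in table: {missing}")
    out = frame.copy()
    if group is None:
        groups = pd.Series(0, index=frame.index)
    else:
        groups = frame[group]
    for gval, idx in out.groupby(groups).groups.items():
        med = float(out.loc[idx, reference_channel].median())
        if not med > 0:
            raise ValueError(f"median of {reference_channel!r} is not positive in group {gval!r}")
        out.loc[idx, marker_channels] = out.loc[idx, marker_channels] / med
    for ch in marker_channels:
        col = out[ch].to_numpy(dtype=np.float64)
        lo, hi = col.min(), col.max()
        out[ch] = np.zeros_like(col) if hi == lo else (col - lo) / (hi - lo)
    return out
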