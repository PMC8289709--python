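"""Image, mask and manifest input; single-cell feature-table output (FCS/CSV).

All images are single-channel grayscale TIFF. The segmentation mask is an
integer image in which each cell's pixels carry one unique positive label and
cells are separated by a one-pixel-wide band of zeros; zero also marks plain
background — the compensation algorithm needs no distinction between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import _fcs

#: Suffix appended to a channel name to form its compensated feature column.
COMPENSATED_SUFFIX = "_comp"

# forward (row-major) half of the 8-neighborhood; the backward half is
# covered by symmetry when checking pairwise adjacency
_FORWARD_SHIFTS = ((0, 1), (1, -1), (1, 0), (1, 1))


@dataclass(frozen=True)
class ChannelStack:
    """An ordered set of same-shape single-channel images.

    ``pixels`` has shape (n_channels, height, width); values are
    non-negative finite counts or intensities in arbitrary units.
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self):
        pixels = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if pixels.ndim != 3:
            raise ValueError("pixels must be (n_channels, height, width)")
        if pixels.shape[0] != len(self.channel_names):
            raise ValueError("one name per channel required")
        if len(set(self.channel_names)) != len(self.channel_names) or any(
            not n for n in self.channel_names
        ):
            raise ValueError("channel names must be unique and non-empty")
        if not np.isfinite(pixels).all() or (pixels < 0).any():
            raise ValueError("pixel values must be finite and >= 0")

    @property
    def height(self) -> int:
        return self.pixels.shape[1]

    @property
    def width(self) -> int:
        return self.pixels.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """2-D view of one channel by name."""
        return self.pixels[self.channel_names.index(name)]


@dataclass(frozen=True)
class SegmentationMask:
    """Labeled cell image: 0 = boundary/background, k >= 1 = pixels of cell k.

    Construction validates the one-pixel-boundary topology: no two 8-connected
    pixels may carry two different positive labels.
    """

    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("mask must be a 2-D image")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("mask labels must be integers (floating-point masks are ambiguous)")
        if (labels < 0).any():
            raise ValueError("mask labels must be >= 0")
        labels = labels.astype(np.int64, copy=False)
        bad = _adjacent_label_pairs(labels)
        if bad:
            raise ValueError(
                "mask violates the one-pixel-boundary rule: labels "
                f"{sorted(bad)[:5]} are 8-adjacent without a zero pixel between them"
            )
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def cell_labels(self) -> np.ndarray:
        """Sorted array of positive labels present."""
        u = np.unique(self.labels)
        return u[u > 0]


def _adjacent_label_pairs(labels: np.ndarray) -> set[tuple[int, int]]:
    """Pairs of distinct positive labels that touch under 8-connectivity."""
    bad: set[tuple[int, int]] = set()
    h, w = labels.shape
    padded = np.zeros((h + 2, w + 2), dtype=labels.dtype)
    padded[1:-1, 1:-1] = labels
    for dr, dc in _FORWARD_SHIFTS:
        b = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        viol = (labels > 0) & (b > 0) & (labels != b)
        if viol.any():
            for x, y in zip(labels[viol].ravel(), b[viol].ravel()):
                bad.add((int(min(x, y)), int(max(x, y))))
    return bad


@dataclass(frozen=True)
class ChannelManifest:
    """Per-channel compensation flags, read from a `channel,compensate` CSV."""

    channels: tuple[str, ...]
    compensate: tuple[bool, ...]

    @property
    def compensated_channels(self) -> tuple[str, ...]:
        return tuple(c for c, f in zip(self.channels, self.compensate) if f)

    def validate_against(self, stack: ChannelStack) -> None:
        if set(self.channels) != set(stack.channel_names):
            missing = set(self.channels) ^ set(stack.channel_names)
            raise ValueError(f"manifest/stack channel mismatch: {sorted(missing)}")


@dataclass
class CellFeatureTable:
    """Per-cell features: size, centroid, original and compensated totals.

    ``frame`` is indexed by cell label with columns ``size``, ``centroid_row``,
    ``centroid_col``, one column per channel (original totals) and, once
    compensation has run, one ``<channel>_comp`` column per channel.
    """

    frame: pd.DataFrame
    channel_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    @property
    def cell_labels(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @property
    def has_compensated(self) -> bool:
        return all(c + COMPENSATED_SUFFIX in self.frame.columns for c in self.channel_names)

    def original(self, channel: str) -> pd.Series:
        return self.frame[channel]

    def compensated(self, channel: str) -> pd.Series:
        return self.frame[channel + COMPENSATED_SUFFIX]


# ---------------------------------------------------------------------------
# readers


def read_channel_stack(paths: Sequence, names: Sequence[str]) -> ChannelStack:
    """Read one single-channel TIFF per name into a :class:`ChannelStack`."""
    if len(paths) != len(names):
        raise ValueError("need exactly one path per channel name")
    arrays = []
    shape = None
    for path, name in zip(paths, names):
        try:
            arr = tifffile.imread(path)
        except (OSError, ValueError) as exc:
            raise OSError(f"cannot read channel image {path}: {exc}") from exc
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {arr.shape}")
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(
                f"{path}: shape {arr.shape} does not match first channel shape {shape}"
            )
        arrays.append(np.asarray(arr, dtype=np.float64))
    return ChannelStack(np.stack(arrays, axis=0), tuple(names))


def read_mask(path) -> SegmentationMask:
    """Read and validate a labeled segmentation mask TIFF."""
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be a 2-D image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: mask must be an integer image, got dtype {arr.dtype}")
    return SegmentationMask(arr)


def write_mask(mask: SegmentationMask, path) -> None:
    labels = mask.labels
    dtype = np.uint16 if labels.max(initial=0) < 2**16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))


def write_channel(image: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_manifest(path) -> ChannelManifest:
    """Read a CSV channel manifest with header ``channel,compensate``."""
    df = pd.read_csv(path)
    expected = {"channel", "compensate"}
    if not expected.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(expected)}, got {list(df.columns)}")
    channels = tuple(str(c) for c in df["channel"])
    if len(set(channels)) != len(channels):
        raise ValueError("manifest channel names must be unique")
    flags = tuple(_parse_bool(v) for v in df["compensate"])
    return ChannelManifest(channels, flags)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean compensate flag")


def write_manifest(manifest: ChannelManifest, path) -> None:
    pd.DataFrame(
        {"channel": manifest.channels, "compensate": manifest.compensate}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feature-table output


def _table_columns(table: CellFeatureTable) -> list[str]:
    cols = ["cell_id", "size", "centroid_row", "centroid_col"]
    cols += list(table.channel_names)
    cols += [c + COMPENSATED_SUFFIX for c in table.channel_names]
    return cols


def write_feature_table(table: CellFeatureTable, path, format: str = "csv") -> None:
    """Write the feature table as CSV (full precision) or FCS 3.1.

    The FCS file carries one event per cell and one parameter per column:
    cell id, size, centroid, each channel's original total and its
    compensated total (``<name>_comp``). If compensation has not been run,
    compensated parameters equal the originals.
    """
    if len(table.frame) == 0:
        raise ValueError("refusing to write an empty feature table")
    df = table.frame.copy()
    for ch in table.channel_names:
        comp = ch + COMPENSATED_SUFFIX
        if comp not in df.columns:
            df[comp] = df[ch]
    df = df.reset_index(names="cell_id")[_table_columns(table)]
    if format == "csv":
        df.to_csv(path, index=False)  # default float repr is shortest round-trip
    elif format == "fcs":
        _fcs.write_fcs(path, list(df.columns), df.to_numpy(dtype=np.float64))
    else:
        raise ValueError(f"unknown format {format!r}; expected 'fcs' or 'csv'")


def read_feature_table_csv(path) -> CellFeatureTable:
    """Re-read a CSV written by :func:`write_feature_table`."""
    df = (
        pd.read_csv(path, float_precision="round_trip")
        .set_index("cell_id")
        .rename_axis("cell")
    )
    reserved = {"size", "centroid_row", "centroid_col"}
    channels = tuple(
        c for c in df.columns if c not in reserved and not c.endswith(COMPENSATED_SUFFIX)
    )
    return CellFeatureTable(df, channels)
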