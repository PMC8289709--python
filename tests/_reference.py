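"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain per-pixel Python loops, deliberately
sharing no code path with the package, so agreement between the two is
meaningful. Also contains a minimal byte-level FCS parser independent of the
package's reader.
"""

from __future__ import annotations

import struct
from itertools import combinations

import numpy as np


def ref_adjacency(labels: np.ndarray):
    """Perimeters and shared boundaries by scanning every zero pixel's 3x3 window."""
    h, w = labels.shape
    perimeter: dict[int, int] = {}
    shared: dict[tuple[int, int], int] = {}
    for r in range(h):
        for c in range(w):
            if labels[r, c] != 0:
                continue
            found = set()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] > 0:
                        found.add(int(labels[rr, cc]))
            for a in found:
                perimeter[a] = perimeter.get(a, 0) + 1
            for a, k in combinations(sorted(found), 2):
                shared[(a, k)] = shared.get((a, k), 0) + 1
    for lab in np.unique(labels):
        if lab > 0:
            perimeter.setdefault(int(lab), 0)
    return perimeter, shared


def ref_border_pixels(labels: np.ndarray, offsets) -> dict[int, set]:
    """Per-cell border pixel sets by exhaustive per-pixel offset scan."""
    h, w = labels.shape
    out: dict[int, set] = {int(lab): set() for lab in np.unique(labels) if lab > 0}
    for r in range(h):
        for c in range(w):
            lab = int(labels[r, c])
            if lab == 0:
                continue
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] == 0:
                    out[lab].add((r, c))
                    break
    return out


def ref_border_signals(labels, channel_images: dict, offsets):
    """Per-cell, per-channel sums over brute-force border pixels."""
    border = ref_border_pixels(labels, offsets)
    return {
        (cell, ch): float(sum(img[r, c] for r, c in pixels))
        for cell, pixels in border.items()
        for ch, img in channel_images.items()
    }


def ref_whole_signals(labels, channel_images: dict):
    out = {}
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        mask = labels == lab
        for ch, img in channel_images.items():
            out[(int(lab), ch)] = float(img[mask].sum())
    return out


def ref_compensate(labels, channel_images: dict, offsets, method: str, region: str,
                   clip: bool = True):
    """Direct per-cell evaluation of the correction equations.

    Returns {(cell, channel): compensated total}.
    """
    perimeter, shared = ref_adjacency(labels)
    whole = ref_whole_signals(labels, channel_images)
    border = ref_border_signals(labels, channel_images, offsets)
    signals = border if region == "border" else whole

    def b(a, k):
        return shared.get((min(a, k), max(a, k)), 0)

    out = {}
    cells = sorted(perimeter)
    for a in cells:
        neighbors = sorted(k for k in cells if k != a and b(a, k) > 0)
        for ch in channel_images:
            sub = sum(signals[(k, ch)] * b(a, k) / perimeter[k] for k in neighbors)
            value = whole[(a, ch)] - sub
            if method == "redsea":
                reinf = sum(signals[(a, ch)] * b(a, k) / perimeter[a] for k in neighbors)
                value += reinf
            out[(a, ch)] = max(0.0, value) if clip else value
    return out


def ref_read_fcs(path):
    """Independent FCS reader: header offsets, TEXT key/values, per-event struct."""
    raw = open(path, "rb").read()
    assert raw[:6] == b"FCS3.1", raw[:10]
    text = raw[int(raw[10:18]) : int(raw[18:26]) + 1].decode("ascii")
    delim, body = text[0], text[1:]
    items = body.split(delim)
    kw = dict(zip(items[0::2], items[1::2]))
    n_par, n_tot = int(kw["$PAR"]), int(kw["$TOT"])
    assert kw["$DATATYPE"] == "F" and kw["$BYTEORD"] == "1,2,3,4" and kw["$MODE"] == "L"
    assert all(kw[f"$P{i}B"] == "32" for i in range(1, n_par + 1))
    begin = int(kw["$BEGINDATA"])
    events = []
    fmt = "<" + "f" * n_par
    step = 4 * n_par
    for i in range(n_tot):
        events.append(struct.unpack(fmt, raw[begin + i * step : begin + (i + 1) * step]))
    names = [kw[f"$P{i}N"] for i in range(1, n_par + 1)]
    return names, np.array(events, dtype=np.float64)
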