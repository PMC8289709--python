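"""Minimal FCS 3.1 writer and reader.

Single dataset, list mode, 32-bit little-endian floats ($DATATYPE F,
$BYTEORD 1,2,3,4) — the most widely readable dialect. Only what the
feature-table export needs; not a general-purpose FCS library.
"""

from __future__ import annotations

import numpy as np

_DELIM = "/"
_HEADER_LEN = 58


def _text_segment(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in keywords.items():
        if _DELIM in key or _DELIM in value:
            raise ValueError(f"delimiter {_DELIM!r} not allowed in keyword {key!r}={value!r}")
        parts.append(f"{key}{_DELIM}{value}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(path, names: list[str], data: np.ndarray) -> None:
    """Write `data` (n_events x n_params) as an FCS 3.1 file."""
    data = np.asarray(data, dtype="<f4")
    if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] != len(names):
        raise ValueError("data must be 2-D with one column per parameter name")
    n_events, n_params = data.shape
    payload = data.tobytes()

    def build(begin_data: int, end_data: int) -> bytes:
        kw: dict[str, str] = {
            "$BEGINANALYSIS": "0",
            "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0",
            "$ENDSTEXT": "0",
            # zero-padded so the TEXT length is independent of the values
            "$BEGINDATA": f"{begin_data:010d}",
            "$ENDDATA": f"{end_data:010d}",
            "$BYTEORD": "1,2,3,4",
            "$DATATYPE": "F",
            "$MODE": "L",
            "$NEXTDATA": "0",
            "$PAR": str(n_params),
            "$TOT": str(n_events),
        }
        for i, name in enumerate(names, start=1):
            col = data[:, i - 1]
            rng = max(1.0, float(np.ceil(col.max()))) if col.size else 1.0
            kw[f"$P{i}N"] = name
            kw[f"$P{i}B"] = "32"
            kw[f"$P{i}E"] = "0,0"
            kw[f"$P{i}R"] = f"{rng:.0f}"
        return _text_segment(kw)

    text = build(0, 0)
    begin_data = _HEADER_LEN + len(text)
    end_data = begin_data + len(payload) - 1
    text = build(begin_data, end_data)
    assert _HEADER_LEN + len(text) == begin_data

    begin_text = _HEADER_LEN
    end_text = begin_text + len(text) - 1
    header = (
        "FCS3.1    "
        f"{begin_text:>8d}{end_text:>8d}"
        f"{begin_data:>8d}{end_data:>8d}"
        f"{0:>8d}{0:>8d}"
    ).encode("ascii")
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)


def read_fcs(path) -> tuple[list[str], np.ndarray]:
    """Read an FCS file written by :func:`write_fcs` (float data only).

    Returns (parameter names, n_events x n_params float64 array).
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if not raw.startswith(b"FCS3"):
        raise ValueError("not an FCS 3.x file")
    begin_text = int(raw[10:18])
    end_text = int(raw[18:26])
    text = raw[begin_text : end_text + 1].decode("ascii")
    delim = text[0]
    fields = text[1:].split(delim)
    kw = {fields[i]: fields[i + 1] for i in range(0, len(fields) - 1, 2)}

    if kw["$DATATYPE"] != "F":
        raise ValueError(f"unsupported $DATATYPE {kw['$DATATYPE']!r}")
    order = kw["$BYTEORD"]
    dtype = {"1,2,3,4": "<f4", "4,3,2,1": ">f4"}.get(order)
    if dtype is None:
        raise ValueError(f"unsupported $BYTEORD {order!r}")
    n_params = int(kw["$PAR"])
    n_events = int(kw["$TOT"])
    begin_data = int(kw["$BEGINDATA"])
    end_data = int(kw["$ENDDATA"])
    payload = raw[begin_data : end_data + 1]
    data = np.frombuffer(payload, dtype=dtype, count=n_events * n_params)
    names = [kw[f"$P{i}N"] for i in range(1, n_params + 1)]
    return names, data.reshape(n_events, n_params).astype(np.float64)
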