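"""Minimal FCS 3.0/3.1 list-mode reader (and writer, used for round-trips).

Supports floating-point data ($DATATYPE F or D), list mode ($MODE L) and
both byte orders. Channel names are taken from $PnS where present, falling
back to $PnN. This intentionally covers only what the pipeline needs —
no compensation, gating or integer/bit-packed data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_fcs", "write_fcs"]

_DTYPE = {"F": "f4", "D": "f8"}
_ORDER = {"1,2,3,4": "<", "4,3,2,1": ">"}


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an FCS file; returns (events x channels matrix, channel names)."""
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise ValueError(f"{path}: too short to be an FCS file")
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"{path}: unsupported FCS version {version!r}")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FCS header offsets (bytes 10-42)") from exc
    text = raw[text_start : text_end + 1].decode("latin-1")
    if not text:
        raise ValueError(f"{path}: empty TEXT segment")
    delim = text[0]
    parts = text[1:].split(delim)
    keywords = {
        parts[i].strip().upper(): parts[i + 1]
        for i in range(0, len(parts) - 1, 2)
        if parts[i].strip()
    }
    # FCS3.x allows zero header offsets with the true ones in TEXT
    if data_start == 0:
        data_start = int(keywords["$BEGINDATA"])
    if data_end == 0:
        data_end = int(keywords["$ENDDATA"])
    mode = keywords.get("$MODE", "L").upper()
    if mode != "L":
        raise ValueError(f"{path}: only list mode ($MODE L) is supported, got {mode!r}")
    datatype = keywords.get("$DATATYPE", "").upper()
    if datatype not in _DTYPE:
        raise ValueError(f"{path}: only $DATATYPE F/D supported, got {datatype!r}")
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    if byteord not in _ORDER:
        raise ValueError(f"{path}: unsupported $BYTEORD {byteord!r}")
    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    names = []
    for p in range(1, n_par + 1):
        name = keywords.get(f"$P{p}S") or keywords.get(f"$P{p}N") or f"channel_{p}"
        names.append(name)
        bits = int(keywords.get(f"$P{p}B", 32))
        if bits != int(_DTYPE[datatype][1]) * 8:
            raise ValueError(f"{path}: $P{p}B={bits} inconsistent with $DATATYPE {datatype}")
    dtype = np.dtype(_ORDER[byteord] + _DTYPE[datatype])
    data = np.frombuffer(raw[data_start : data_end + 1], dtype=dtype)
    if len(data) != n_par * n_tot:
        raise ValueError(
            f"{path}: DATA segment holds {len(data)} values, expected {n_par * n_tot}"
        )
    return data.reshape(n_tot, n_par).astype(float), names


def write_fcs(path: str | Path, values: np.ndarray, names: list[str]) -> None:
    """Write a minimal FCS 3.1 file (float32, little-endian, list mode)."""
    values = np.asarray(values, dtype="<f4")
    n_tot, n_par = values.shape
    if len(names) != n_par:
        raise ValueError("one name per channel required")
    delim = "/"
    kv = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for p, name in enumerate(names, start=1):
        kv[f"$P{p}N"] = name
        kv[f"$P{p}B"] = "32"
        kv[f"$P{p}E"] = "0,0"
        kv[f"$P{p}R"] = "262144"
    # iterate: offsets depend on TEXT length which depends on offsets
    header_len = 58
    data_len = values.nbytes
    text = ""
    for _ in range(3):
        data_start = header_len + len(text.encode("latin-1"))
        data_end = data_start + data_len - 1
        kv["$BEGINDATA"] = str(data_start)
        kv["$ENDDATA"] = str(data_end)
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in kv.items()) + delim
        new_start = header_len + len(text.encode("latin-1"))
        if new_start == data_start:
            break
    text_bytes = text.encode("latin-1")
    data_start = header_len + len(text_bytes)
    data_end = data_start + data_len - 1
    header = (
        b"FCS3.1    "
        + f"{header_len:>8d}".encode()
        + f"{header_len + len(text_bytes) - 1:>8d}".encode()
        + f"{data_start:>8d}".encode()
        + f"{data_end:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    Path(path).write_bytes(header + text_bytes + values.tobytes())
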