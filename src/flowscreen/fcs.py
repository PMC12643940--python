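"""Minimal FCS 3.0/3.1 reader and writer.

Supports the common case produced by modern cytometers: list-mode data
(``$MODE L``) stored as float32/float64 or fixed-width integers, little- or
big-endian. Spillover matrices, analysis segments and non-list modes are out
of scope; events are read as stored (assumed compensated upstream).

The writer emits a small, standard-conformant FCS 3.1 file (float32,
little-endian) and exists mainly so that round-trip tests and users can
materialize synthetic tables without binary fixtures.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .events import EventTable

__all__ = ["read_fcs", "write_fcs"]

_DELIM = "/"


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1")
    # First and (per spec) last character are the delimiter.
    parts = body.strip(delim).split(delim)
    if len(parts) % 2 == 1:
        parts = parts[:-1]
    return {k.strip().upper(): v for k, v in zip(parts[::2], parts[1::2])}


def read_fcs(path: str | Path, sample_id: str = "") -> EventTable:
    """Read a list-mode FCS 3.0/3.1 file into an :class:`EventTable`."""
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FormatError(f"{path}: too short to be an FCS file")
    version = blob[:6].decode("latin-1", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        field = blob[lo:hi].decode("latin-1").strip() or "0"
        try:
            return int(field)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed header offset {field!r}") from exc

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    text = _parse_text_segment(blob[text_start : text_end + 1])

    if text.get("$MODE", "L").upper() != "L":
        raise FormatError(f"{path}: only list-mode ($MODE L) data is supported")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    # FCS 3.x allows data offsets beyond the 8-char header to live in TEXT.
    if data_start == 0:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    if data_start <= 0 and n_tot > 0:
        raise FormatError(f"{path}: no DATA segment offsets")

    datatype = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32, 64):
            raise FormatError(f"{path}: unsupported mixed/odd integer widths {bits}")
        dtype = np.dtype(f"{endian}u{bits[0] // 8}")
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    n_values = n_par * n_tot
    raw = blob[data_start : data_start + n_values * dtype.itemsize]
    if len(raw) < n_values * dtype.itemsize:
        raise FormatError(f"{path}: DATA segment truncated")
    arr = np.frombuffer(raw, dtype=dtype, count=n_values).reshape(n_tot, n_par)

    channels = []
    for i in range(1, n_par + 1):
        name = text.get(f"$P{i}N") or f"P{i}"
        channels.append(name)
    meta = {k: v for k, v in text.items() if not k.startswith("$P")}
    return EventTable(
        pd.DataFrame(arr.astype(float), columns=channels),
        sample_id=sample_id or path.stem,
        metadata={"fcs_keywords": meta},
    )


def write_fcs(table: EventTable, path: str | Path) -> None:
    """Write an event table as a little-endian float32 FCS 3.1 file."""
    path = Path(path)
    data = np.ascontiguousarray(table.data.to_numpy(dtype="<f4"))
    n_tot, n_par = data.shape

    keywords: dict[str, str] = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, ch in enumerate(table.channels, start=1):
        if _DELIM in ch:
            raise FormatError(f"channel name {ch!r} contains the TEXT delimiter")
        keywords[f"$P{i}N"] = ch
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(1.0, float(data[:, i - 1].max(initial=0.0)))) + 1)

    # Two-pass layout: TEXT length depends on the data offsets it records.
    header_len = 58
    data_len = data.nbytes
    begin_data = 0
    for _ in range(3):
        text = _DELIM + _DELIM.join(
            f"{k}{_DELIM}{v}"
            for k, v in {**keywords, "$BEGINDATA": str(begin_data), "$ENDDATA": str(begin_data + max(data_len - 1, 0))}.items()
        ) + _DELIM
        new_begin = header_len + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    text_bytes = text.encode("latin-1")
    text_start = header_len
    text_end = text_start + len(text_bytes) - 1
    data_start = begin_data if n_tot else 0
    data_end = begin_data + data_len - 1 if n_tot else 0

    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + (f"{data_start:>8d}".encode() if data_end < 10**8 else b"       0")
        + (f"{data_end:>8d}".encode() if data_end < 10**8 else b"       0")
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == 58
    path.write_bytes(header + text_bytes + data.tobytes())
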