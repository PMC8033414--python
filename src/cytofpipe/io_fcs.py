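"""Minimal FCS 3.0/3.1 list-mode reader and FCS 3.1 writer.

Covers what a post-normalization CyTOF workflow needs: single-dataset
files, list mode, float (``$DATATYPE F``/``D``) or unsigned integer data,
little- or big-endian byte order, channel names from ``$PnN`` and stain
names from ``$PnS``. Written files use FCS 3.1, float32, little-endian,
with ``$BEGINDATA``/``$ENDDATA`` offsets mirrored in the header when they
fit its 8-character fields.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from cytofpipe.core import EventTable
from cytofpipe.panel import EMBED_MARKERS, Channel, PanelSpec

DELIM = "/"

_GAUSSIAN = {"Event_length", "Center", "Offset", "Width", "Residual"}


class FCSParseError(ValueError):
    """Malformed FCS content; message carries the byte offset when known."""


def _infer_channel(name: str) -> Channel:
    """Best-effort role assignment for a channel read without a panel."""
    if name == "Time":
        return Channel("Time", role="time")
    if name in _GAUSSIAN:
        return Channel(name, role="gaussian")
    if name.startswith("c_"):  # batch-corrected duplicate channel
        base = _infer_channel(name[2:])
        return Channel("c_" + base.metal, base.marker, base.role, base.embed)
    metal, _, marker = name.partition("_")
    if not marker:
        return Channel(metal, role="excluded")
    if marker == "Bead":
        return Channel(metal, marker, "bead")
    if metal.endswith("Pd"):
        return Channel(metal, marker, "barcode")
    if metal.endswith("Ir"):
        return Channel(metal, marker, "dna")
    if marker == "Cisplatin":
        return Channel(metal, marker, "viability")
    if marker in {"CD45", "c-Cas3"}:
        return Channel(metal, marker, "gating")
    return Channel(metal, marker, "phenotyping", embed=marker in EMBED_MARKERS)


def _parse_text(raw: bytes, offset: int) -> dict[str, str]:
    try:
        text = raw.decode("utf-8", errors="replace")
    except Exception as exc:  # pragma: no cover - decode with replace cannot raise
        raise FCSParseError(f"TEXT segment undecodable at offset {offset}") from exc
    if not text:
        raise FCSParseError(f"empty TEXT segment at offset {offset}")
    delim = text[0]
    body = text[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise FCSParseError(
            f"TEXT segment at offset {offset} has an odd number of fields "
            f"(unbalanced delimiter {delim!r})"
        )
    return {parts[i].strip(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path: str | os.PathLike, panel: PanelSpec | None = None) -> EventTable:
    """Read an FCS file into an :class:`EventTable`.

    If ``panel`` is given its channel names must match the file's ``$PnN``
    names exactly (order included); otherwise a panel is inferred from the
    channel names.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise FCSParseError("file shorter than FCS header (58 bytes)")
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise FCSParseError(f"unsupported FCS version {version!r}")

    def _hdr(a: int, b: int) -> int:
        s = raw[a:b].decode("ascii", errors="replace").strip()
        try:
            return int(s) if s else 0
        except ValueError as exc:
            raise FCSParseError(f"non-numeric header offset at byte {a}") from exc

    t0, t1 = _hdr(10, 18), _hdr(18, 26)
    d0, d1 = _hdr(26, 34), _hdr(34, 42)
    if not (0 < t0 < t1 < len(raw)):
        raise FCSParseError(f"invalid TEXT offsets {t0}..{t1}")
    kw = _parse_text(raw[t0 : t1 + 1], t0)

    if d0 == 0 or d1 == 0:
        d0 = int(kw.get("$BEGINDATA", 0))
        d1 = int(kw.get("$ENDDATA", 0))
    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        dtype_code = kw["$DATATYPE"].strip().upper()
        byteord = kw["$BYTEORD"].strip()
        mode = kw.get("$MODE", "L").strip().upper()
    except KeyError as exc:
        raise FCSParseError(f"missing required keyword {exc}") from exc
    if mode != "L":
        raise FCSParseError(f"only list mode supported, got $MODE={mode}")

    names = []
    for i in range(1, n_par + 1):
        if f"$P{i}N" not in kw:
            raise FCSParseError(f"missing $P{i}N")
        names.append(kw[f"$P{i}N"].strip())
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise FCSParseError(f"duplicate channel names: {dupes}")

    endian = "<" if byteord.startswith("1") else ">"
    if dtype_code == "F":
        np_dtype = np.dtype(endian + "f4")
    elif dtype_code == "D":
        np_dtype = np.dtype(endian + "f8")
    elif dtype_code == "I":
        bits = {int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1 or next(iter(bits)) not in (16, 32):
            raise FCSParseError(f"unsupported integer widths {sorted(bits)}")
        np_dtype = np.dtype(endian + ("u2" if next(iter(bits)) == 16 else "u4"))
    else:
        raise FCSParseError(f"unsupported $DATATYPE {dtype_code}")

    n_vals = n_par * n_tot
    if n_tot > 0:
        expected = n_vals * np_dtype.itemsize
        seg = raw[d0 : d1 + 1]
        if len(seg) < expected:
            raise FCSParseError(
                f"DATA segment at offset {d0} holds {len(seg)} bytes, "
                f"expected {expected}"
            )
        arr = np.frombuffer(seg[:expected], dtype=np_dtype).reshape(n_tot, n_par)
        arr = arr.astype(np.float64)
    else:
        arr = np.empty((0, n_par), dtype=np.float64)

    if panel is not None:
        if panel.names != names:
            raise FCSParseError(
                "file channels do not match the supplied panel: "
                f"{names} vs {panel.names}"
            )
    else:
        panel = PanelSpec([_infer_channel(n) for n in names])
    df = pd.DataFrame(arr, columns=names)
    return EventTable(df, panel)


def write_fcs(table: EventTable, path: str | os.PathLike, extra_keywords: dict | None = None) -> Path:
    """Write an :class:`EventTable` as FCS 3.1 (float32, little-endian).

    Round trip through :func:`read_fcs` reproduces the matrix to float32
    precision. An empty table is an error.
    """
    if table.n_events == 0:
        raise ValueError("refusing to write an FCS file with zero events")
    path = Path(path)
    data = table.data.to_numpy(dtype="<f4")
    n_tot, n_par = data.shape

    kw: dict[str, str] = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$TOT": str(n_tot),
        "$PAR": str(n_par),
    }
    for i, ch in enumerate(table.panel.channels, start=1):
        kw[f"$P{i}N"] = ch.name
        if ch.marker:
            kw[f"$P{i}S"] = ch.marker
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        rng = float(np.nanmax(data[:, i - 1])) if n_tot else 0.0
        kw[f"$P{i}R"] = str(int(max(rng, 1)) + 1)
    if extra_keywords:
        kw.update({str(k): str(v) for k, v in extra_keywords.items()})

    # fixed-width data offsets so TEXT length is independent of their value
    kw["$BEGINDATA"] = "0" * 12
    kw["$ENDDATA"] = "0" * 12

    def render(d: dict[str, str]) -> bytes:
        parts = [DELIM]
        for k, v in d.items():
            v = v if v != "" else " "
            parts.append(f"{k}{DELIM}{v}{DELIM}")
        return "".join(parts).encode("utf-8")

    text = render(kw)
    text_start = 58
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1
    kw["$BEGINDATA"] = str(data_start).rjust(12, "0")
    kw["$ENDDATA"] = str(data_end).rjust(12, "0")
    text = render(kw)

    def hdr_num(x: int) -> bytes:
        return (str(x) if x <= 99_999_999 else "0").rjust(8).encode("ascii")

    header = b"FCS3.1    " + hdr_num(text_start) + hdr_num(text_end)
    header += hdr_num(data_start if data_end <= 99_999_999 else 0)
    header += hdr_num(data_end if data_end <= 99_999_999 else 0)
    header += hdr_num(0) + hdr_num(0)
    assert len(header) == 58

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())
    return path
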