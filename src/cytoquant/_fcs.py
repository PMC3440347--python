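"""Minimal read-only FCS 3.0/3.1 ingestion.

Supports the common acquisition layout: list-mode data, float (``$DATATYPE F``/``D``)
or fixed-width integer (``$DATATYPE I``) events, little- or big-endian.
Parameter short names (``$PnN``) are matched case-insensitively against
the canonical channel names; the first four parameters are used as
FSC/SSC/FL1/FL2 when no names match.
"""

from __future__ import annotations

import re
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

_CANONICAL = {"fsc": ("fsc", "fsc-a", "fsc-h"), "ssc": ("ssc", "ssc-a", "ssc-h"),
              "fl1": ("fl1", "fl1-a", "fl1-h", "fitc", "fitc-a"),
              "fl2": ("fl2", "fl2-a", "fl2-h", "pe", "pe-a")}


def _read_text_segment(raw: bytes) -> dict:
    if not raw:
        raise FormatError("empty FCS TEXT segment")
    delim = raw[:1]
    parts = raw[1:].split(delim)
    kv = {}
    # keys and values alternate; empty trailing element from final delimiter
    it = iter(parts)
    for key in it:
        val = next(it, None)
        if val is None:
            break
        k = key.decode("latin-1").strip()
        if k:
            kv[k.upper()] = val.decode("latin-1")
    return kv


def read_fcs(path) -> pd.DataFrame:
    """Parse an FCS 3.0/3.1 file into a DataFrame with canonical columns."""
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise FormatError("file too short to be FCS")
    version = raw[:6].decode("latin-1", "replace")
    if not version.startswith("FCS3"):
        raise FormatError(f"unsupported FCS version: {version!r}")

    def seg(lo, hi):
        return int(raw[lo:hi].decode("latin-1").strip() or 0)

    text_start, text_end = seg(10, 18), seg(18, 26)
    data_start, data_end = seg(26, 34), seg(34, 42)
    text = _read_text_segment(raw[text_start:text_end + 1])
    if not data_start:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    dtype_code = text.get("$DATATYPE", "F").upper()
    order = text.get("$BYTEORD", "1,2,3,4")
    little = order.startswith("1")
    endian = "<" if little else ">"
    if text.get("$MODE", "L").upper() != "L":
        raise FormatError("only list-mode FCS data is supported")

    bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if dtype_code == "F":
        np_dtype, width = np.dtype(endian + "f4"), 4
    elif dtype_code == "D":
        np_dtype, width = np.dtype(endian + "f8"), 8
    elif dtype_code == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32):
            raise FormatError("only uniform 8/16/32-bit integer FCS data supported")
        np_dtype, width = np.dtype(endian + f"u{bits[0] // 8}"), bits[0] // 8
    else:
        raise FormatError(f"unsupported $DATATYPE: {dtype_code}")

    need = n_par * n_tot * width
    buf = raw[data_start:data_start + need]
    if len(buf) < need:
        raise FormatError("FCS DATA segment truncated")
    mat = np.frombuffer(buf, dtype=np_dtype).reshape(n_tot, n_par).astype(float)

    names = [text.get(f"$P{i}N", f"P{i}").strip().lower() for i in range(1, n_par + 1)]
    cols = {}
    for canon, aliases in _CANONICAL.items():
        for j, name in enumerate(names):
            if name in aliases:
                cols[canon] = j
                break
    if len(cols) < 4:
        if n_par < 4:
            raise FormatError("FCS file has fewer than 4 parameters")
        cols = {c: j for j, c in enumerate(("fsc", "ssc", "fl1", "fl2"))}
    out = pd.DataFrame({c: mat[:, j] for c, j in cols.items()})
    return out[["fsc", "ssc", "fl1", "fl2"]]
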