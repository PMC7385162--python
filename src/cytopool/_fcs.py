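"""Minimal reader for FCS 3.0 / 3.1 list-mode files.

Covers the subset of the standard produced by modern mass and flow
cytometers after acquisition-software export: a single dataset per file,
``$MODE L`` (list mode), ``$DATATYPE`` F, D, or I with uniform bit width,
and either byte order. Log amplifier scaling (``$PnE``) and detector gain
(``$PnG``) are applied so returned values are on the linear scale.

Only reading is supported; writing FCS is out of scope (the package's CSV
path is the round-trip format).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["FcsReadError", "read_fcs"]


class FcsReadError(ValueError):
    """Raised when a file is not parseable as FCS 3.0/3.1 list-mode data."""


def _parse_header(raw: bytes) -> dict[str, int]:
    version = raw[0:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsReadError(f"unsupported FCS version {version!r}; need FCS3.0 or FCS3.1")
    offsets = {}
    fields = ("text_begin", "text_end", "data_begin", "data_end")
    for i, name in enumerate(fields):
        lo, hi = 10 + 8 * i, 18 + 8 * i
        chunk = raw[lo:hi].strip() or b"0"
        try:
            offsets[name] = int(chunk)
        except ValueError as exc:
            raise FcsReadError(f"malformed header offset {name!r}: {chunk!r}") from exc
    return offsets


def _parse_text(segment: bytes) -> dict[str, str]:
    if not segment:
        raise FcsReadError("empty TEXT segment")
    delim = segment[0:1]
    # Delimiters inside values are escaped by doubling; split on single
    # occurrences by first replacing escaped pairs with a sentinel.
    sentinel = b"\x00\x01\x00"
    body = segment[1:].rstrip(delim + b" ")
    parts = body.replace(delim + delim, sentinel).split(delim)
    parts = [p.replace(sentinel, delim) for p in parts]
    if len(parts) % 2 == 1:
        parts = parts[:-1]
    keywords = {}
    for key, value in zip(parts[::2], parts[1::2]):
        keywords[key.decode("utf-8", "replace").strip().upper()] = value.decode(
            "utf-8", "replace"
        ).strip()
    return keywords


def _dtype_for(keywords: dict[str, str], n_par: int) -> np.dtype:
    datatype = keywords.get("$DATATYPE", "").upper()
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"
    if datatype == "F":
        return np.dtype(f"{order}f4")
    if datatype == "D":
        return np.dtype(f"{order}f8")
    if datatype == "I":
        widths = {int(keywords.get(f"$P{i}B", "0")) for i in range(1, n_par + 1)}
        if len(widths) != 1:
            raise FcsReadError(f"mixed integer bit widths {sorted(widths)} not supported")
        bits = widths.pop()
        if bits not in (8, 16, 32, 64):
            raise FcsReadError(f"unsupported integer width {bits}")
        return np.dtype(f"{order}u{bits // 8}")
    raise FcsReadError(f"unsupported $DATATYPE {datatype!r}")


def _linearize(values: np.ndarray, keywords: dict[str, str], n_par: int) -> np.ndarray:
    """Undo log amplification ($PnE) and gain ($PnG), per the standard."""
    out = values.astype(np.float64, copy=True)
    for i in range(1, n_par + 1):
        col = i - 1
        pne = keywords.get(f"$P{i}E", "0,0")
        try:
            decades, f2 = (float(x) for x in pne.split(","))
        except ValueError as exc:
            raise FcsReadError(f"malformed $P{i}E={pne!r}") from exc
        if decades > 0:
            f2 = f2 if f2 > 0 else 1.0  # f2=0 is a common writer bug; treat as 1
            rng = float(keywords.get(f"$P{i}R", "1024"))
            out[:, col] = f2 * 10.0 ** (decades * out[:, col] / rng)
        else:
            gain = float(keywords.get(f"$P{i}G", "1") or "1")
            if gain not in (0.0, 1.0):
                out[:, col] = out[:, col] / gain
    return out


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an FCS file's primary data segment.

    Returns ``(values, channel_names)`` where *values* is an
    ``events x parameters`` float64 array on the linear scale and channel
    names come from ``$PnN``.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise FcsReadError("file too short to contain an FCS header")
    offsets = _parse_header(raw)
    keywords = _parse_text(raw[offsets["text_begin"] : offsets["text_end"] + 1])

    if keywords.get("$MODE", "L").upper() != "L":
        raise FcsReadError("only list-mode ($MODE L) files are supported")
    try:
        n_par = int(keywords["$PAR"])
        n_tot = int(keywords["$TOT"])
    except KeyError as exc:
        raise FcsReadError(f"missing required keyword {exc}") from exc

    data_begin = offsets["data_begin"] or int(keywords.get("$BEGINDATA", "0"))
    data_end = offsets["data_end"] or int(keywords.get("$ENDDATA", "0"))
    if data_begin <= 0 or data_end <= 0:
        raise FcsReadError("data segment offsets missing from header and TEXT")

    dtype = _dtype_for(keywords, n_par)
    expected = n_par * n_tot * dtype.itemsize
    segment = raw[data_begin : data_begin + expected]
    if len(segment) < expected:
        raise FcsReadError(
            f"data segment truncated: need {expected} bytes, have {len(segment)}"
        )
    values = np.frombuffer(segment, dtype=dtype).reshape(n_tot, n_par)
    values = _linearize(values, keywords, n_par)

    names = [keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return values, names


def write_fcs_minimal(path: str | Path, values: np.ndarray, names: list[str]) -> None:
    """Write a minimal little-endian float32 FCS 3.1 file (testing aid)."""
    values = np.asarray(values, dtype="<f4")
    n_tot, n_par = values.shape
    pairs = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
        # zero-padded to fixed width so the TEXT length is offset-independent
        "$BEGINDATA": "00000000",
        "$ENDDATA": "00000000",
    }
    for i, name in enumerate(names, start=1):
        pairs[f"$P{i}N"] = name
        pairs[f"$P{i}B"] = "32"
        pairs[f"$P{i}E"] = "0,0"
        pairs[f"$P{i}R"] = "262144"

    def render(p: dict[str, str]) -> str:
        return "|" + "|".join(f"{k}|{v}" for k, v in p.items()) + "|"

    text_begin = 58
    text_end = text_begin + len(render(pairs)) - 1
    data_begin = text_end + 1
    data_end = data_begin + values.nbytes - 1
    pairs["$BEGINDATA"] = f"{data_begin:08d}"
    pairs["$ENDDATA"] = f"{data_end:08d}"
    text = render(pairs)
    header = (
        b"FCS3.1    "
        + f"{text_begin:8d}{text_end:8d}{data_begin:8d}{data_end:8d}{0:8d}{0:8d}".encode()
    )
    Path(path).write_bytes(header + text.encode() + values.tobytes())
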