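"""Minimal NRRD (Nearly Raw Raster Data) reader/writer.

Supports the subset of NRRD0004 this package produces and consumes:
3-D single-block arrays, ``raw`` or ``gzip`` encodings, little- or
big-endian scalar types, with voxel spacing carried either in ``spacings``
or as a diagonal ``space directions`` matrix.  Data are stored in the NRRD
convention (first listed axis fastest), i.e. Fortran index order relative
to ``sizes``.

Anything outside this subset (detached headers, block types, non-diagonal
space directions) raises a clear error rather than guessing.
"""

from __future__ import annotations

import gzip
import zlib
from pathlib import Path

import numpy as np

__all__ = ["read", "write", "NrrdError"]


class NrrdError(ValueError):
    """Malformed or unsupported NRRD file."""


_TYPE_MAP = {
    "signed char": "i1", "int8": "i1", "int8_t": "i1",
    "uchar": "u1", "unsigned char": "u1", "uint8": "u1", "uint8_t": "u1",
    "short": "i2", "signed short": "i2", "int16": "i2", "int16_t": "i2",
    "ushort": "u2", "unsigned short": "u2", "uint16": "u2", "uint16_t": "u2",
    "int": "i4", "signed int": "i4", "int32": "i4", "int32_t": "i4",
    "uint": "u4", "unsigned int": "u4", "uint32": "u4", "uint32_t": "u4",
    "longlong": "i8", "int64": "i8", "int64_t": "i8",
    "ulonglong": "u8", "uint64": "u8", "uint64_t": "u8",
    "float": "f4", "double": "f8",
}

_DTYPE_TO_NRRD = {
    "int8": "int8", "uint8": "uint8", "int16": "int16", "uint16": "uint16",
    "int32": "int32", "uint32": "uint32", "int64": "int64", "uint64": "uint64",
    "float32": "float", "float64": "double",
}


def _parse_header(raw: bytes) -> tuple[dict[str, str], int]:
    """Parse header lines; return (fields, byte offset of data)."""
    end = raw.find(b"\n\n")
    # header ends at the first blank line (possibly \r\n\r\n)
    end_crlf = raw.find(b"\r\n\r\n")
    if end_crlf != -1 and (end == -1 or end_crlf < end):
        end, sep = end_crlf, 4
    elif end != -1:
        sep = 2
    else:
        raise NrrdError("no blank line terminating the NRRD header")
    header_text = raw[:end].decode("ascii", errors="replace")
    lines = header_text.splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise NrrdError("missing NRRD magic")
    fields: dict[str, str] = {}
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        if ":=" in line:  # key-value pairs: keep verbatim
            k, v = line.split(":=", 1)
            fields[k.strip().lower()] = v.strip()
            continue
        if ":" not in line:
            raise NrrdError(f"malformed header line: {line!r}")
        k, v = line.split(":", 1)
        fields[k.strip().lower()] = v.strip()
    return fields, end + sep


def read(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an NRRD file.

    Returns ``(array, header)`` where the array has shape = ``sizes`` and
    the header dict carries ``spacings`` (list of floats or None) plus the
    raw parsed fields.
    """
    raw = Path(path).read_bytes()
    fields, offset = _parse_header(raw)

    if "data file" in fields or "datafile" in fields:
        raise NrrdError("detached data files are not supported")
    typ = fields.get("type")
    if typ not in _TYPE_MAP:
        raise NrrdError(f"unsupported type {typ!r}")
    code = _TYPE_MAP[typ]
    endian = fields.get("endian", "little")
    dtype = np.dtype(("<" if endian == "little" else ">") + code)

    try:
        sizes = [int(s) for s in fields["sizes"].split()]
        dim = int(fields["dimension"])
    except KeyError as e:
        raise NrrdError(f"missing required field {e}") from None
    if len(sizes) != dim:
        raise NrrdError("sizes/dimension mismatch")

    encoding = fields.get("encoding", "raw")
    payload = raw[offset:]
    if encoding == "raw":
        data = payload
    elif encoding in ("gzip", "gz"):
        data = gzip.decompress(payload)
    elif encoding in ("zlib",):
        data = zlib.decompress(payload)
    else:
        raise NrrdError(f"unsupported encoding {encoding!r}")

    count = int(np.prod(sizes))
    arr = np.frombuffer(data, dtype=dtype, count=count)
    if arr.size != count:
        raise NrrdError("data block shorter than sizes imply")
    arr = arr.reshape(sizes, order="F")

    spacings = None
    if "spacings" in fields:
        spacings = [float(s) for s in fields["spacings"].split()]
    elif "space directions" in fields:
        spacings = _diag_spacings(fields["space directions"])
    header = dict(fields)
    header["spacings"] = spacings
    return arr, header


def _diag_spacings(text: str) -> list[float]:
    vecs = []
    for token in text.split(") ("):
        token = token.strip().strip("()")
        if token == "none":
            continue
        vecs.append([float(x) for x in token.split(",")])
    spacings = []
    for i, v in enumerate(vecs):
        for j, x in enumerate(v):
            if i != j and x != 0.0:
                raise NrrdError("non-axis-aligned space directions are not supported")
        spacings.append(abs(v[i]))
    return spacings


def write(
    path: str | Path,
    array: np.ndarray,
    spacings: list[float] | tuple[float, ...] | None = None,
    encoding: str = "raw",
) -> None:
    """Write an array as NRRD (first axis fastest, native little-endian)."""
    array = np.ascontiguousarray(array)
    name = str(array.dtype.newbyteorder("=").name)
    if name not in _DTYPE_TO_NRRD:
        raise NrrdError(f"unsupported dtype {array.dtype}")
    lines = [
        "NRRD0004",
        "# generated by flydyad",
        f"type: {_DTYPE_TO_NRRD[name]}",
        f"dimension: {array.ndim}",
        f"sizes: {' '.join(str(s) for s in array.shape)}",
        f"encoding: {encoding}",
        "endian: little",
    ]
    if spacings is not None:
        if len(spacings) != array.ndim:
            raise NrrdError("spacings length must equal array dimension")
        lines.append("spacings: " + " ".join(repr(float(s)) for s in spacings))
    header = "\n".join(lines) + "\n\n"
    payload = array.astype(array.dtype.newbyteorder("<")).tobytes(order="F")
    if encoding == "gzip":
        payload = gzip.compress(payload)
    elif encoding != "raw":
        raise NrrdError(f"unsupported encoding {encoding!r}")
    Path(path).write_bytes(header.encode("ascii") + payload)
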