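"""Minimal ASPRS LAS reader/writer.

Supports the subset of the LAS specification needed for height-normalised
airborne-LiDAR tiles: versions 1.1-1.4, point record formats 0-3 and 6-8 on
read, and LAS 1.2 / point format 0 on write.  Only the dimensions the
pipeline consumes are decoded: X, Y, Z, return number, number of returns and
classification.  LAZ (compressed) input is detected and rejected with an
explicit error, as no decompression codec is bundled.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = ["LASFormatError", "read_las", "write_las"]

_SIGNATURE = b"LASF"

# point record layouts we can decode: format id -> (record dtype, flag byte offset)
_POINT_DTYPES: dict[int, np.dtype] = {}


def _legacy_dtype(extra: int) -> np.dtype:
    fields = [
        ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
        ("intensity", "<u2"), ("flags", "u1"), ("classification", "u1"),
        ("scan_angle", "i1"), ("user_data", "u1"), ("point_source", "<u2"),
    ]
    if extra:
        fields.append(("extra", f"V{extra}"))
    return np.dtype(fields)


def _modern_dtype(extra: int) -> np.dtype:
    # formats 6+: 14-bit return counts packed in two bytes
    fields = [
        ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
        ("intensity", "<u2"), ("returns", "u1"), ("flags", "u1"),
        ("classification", "u1"), ("user_data", "u1"),
        ("scan_angle", "<i2"), ("point_source", "<u2"), ("gps_time", "<f8"),
    ]
    if extra:
        fields.append(("extra", f"V{extra}"))
    return np.dtype(fields)


class LASFormatError(ValueError):
    """Raised for unreadable, truncated, compressed or unsupported LAS input."""


@dataclass
class _Header:
    version: tuple[int, int]
    point_format: int
    record_length: int
    n_points: int
    offset_to_points: int
    scales: tuple[float, float, float]
    offsets: tuple[float, float, float]


def _parse_header(buf: bytes) -> _Header:
    if len(buf) < 227:
        raise LASFormatError("file too short to contain a LAS header")
    if buf[:4] != _SIGNATURE:
        raise LASFormatError("missing LASF signature; not a LAS file")
    major, minor = buf[24], buf[25]
    header_size = struct.unpack_from("<H", buf, 94)[0]
    offset_to_points = struct.unpack_from("<I", buf, 96)[0]
    point_format = buf[104]
    record_length = struct.unpack_from("<H", buf, 105)[0]
    n_points = struct.unpack_from("<I", buf, 107)[0]
    scales = struct.unpack_from("<3d", buf, 131)
    offsets = struct.unpack_from("<3d", buf, 155)
    if point_format & 0x80:
        raise LASFormatError("LAZ (laszip-compressed) input is not supported; "
                             "decompress to .las first")
    if (major, minor) == (1, 4) and n_points == 0:
        if len(buf) < header_size or header_size < 375:
            raise LASFormatError("truncated LAS 1.4 header")
        n_points = struct.unpack_from("<Q", buf, 247)[0]
        if n_points > 2**63:
            raise LASFormatError("implausible point count")
    if header_size < 227 or offset_to_points < header_size:
        raise LASFormatError("inconsistent LAS header sizes")
    return _Header((major, minor), point_format, record_length, int(n_points),
                   offset_to_points, scales, offsets)


def read_las(path) -> dict:
    """Read a .las file into plain numpy arrays.

    Returns a dict with keys ``x``, ``y``, ``z`` (float64, metres),
    ``return_number``, ``number_of_returns`` (int16) and
    ``classification`` (uint8).
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    hdr = _parse_header(buf)
    fmt = hdr.point_format
    base = {0: 20, 1: 28, 2: 26, 3: 34, 6: 30, 7: 36, 8: 38}.get(fmt)
    if base is None:
        raise LASFormatError(f"unsupported point record format {fmt}")
    if hdr.record_length < base:
        raise LASFormatError("point record length shorter than format minimum")
    if fmt < 6:
        # formats 1-3 append gps time / rgb after the 20-byte core
        dtype = _legacy_dtype(hdr.record_length - 20)
    else:
        dtype = _modern_dtype(hdr.record_length - 30)
    end = hdr.offset_to_points + hdr.n_points * hdr.record_length
    if len(buf) < end:
        raise LASFormatError("truncated point data block")
    raw = np.frombuffer(buf, dtype=dtype, count=hdr.n_points,
                        offset=hdr.offset_to_points)
    sx, sy, sz = hdr.scales
    ox, oy, oz = hdr.offsets
    out = {
        "x": raw["X"] * sx + ox,
        "y": raw["Y"] * sy + oy,
        "z": raw["Z"] * sz + oz,
    }
    if fmt < 6:
        flags = raw["flags"]
        out["return_number"] = (flags & 0x07).astype(np.int16)
        out["number_of_returns"] = ((flags >> 3) & 0x07).astype(np.int16)
        out["classification"] = (raw["classification"] & 0x1F).astype(np.uint8)
    else:
        ret = raw["returns"]
        out["return_number"] = (ret & 0x0F).astype(np.int16)
        out["number_of_returns"] = ((ret >> 4) & 0x0F).astype(np.int16)
        out["classification"] = raw["classification"].astype(np.uint8)
    if hdr.n_points and not out["number_of_returns"].any():
        raise LASFormatError(
            "NumberOfReturns is zero for every point; the metafield required "
            "by the return-count filter is missing from this file")
    return out


def write_las(path, x, y, z, number_of_returns, return_number=None,
              classification=None, scale: float = 0.001) -> None:
    """Write a LAS 1.2 / point-format-0 file.

    Coordinates are stored as int32 counts of ``scale`` metres relative to the
    per-axis minimum, the standard LAS quantisation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    n = x.size
    nor = np.asarray(number_of_returns, dtype=np.int64)
    if nor.size != n:
        raise ValueError("number_of_returns length mismatch")
    if n and (nor < 1).any():
        raise ValueError("number_of_returns must be >= 1 for every point")
    rn = (np.ones(n, dtype=np.int64) if return_number is None
          else np.asarray(return_number, dtype=np.int64))
    cls = (np.zeros(n, dtype=np.uint8) if classification is None
           else np.asarray(classification, dtype=np.uint8))
    mins = [float(v.min()) if n else 0.0 for v in (x, y, z)]
    maxs = [float(v.max()) if n else 0.0 for v in (x, y, z)]

    rec = np.zeros(n, dtype=_legacy_dtype(0))
    rec["X"] = np.round((x - mins[0]) / scale).astype(np.int32)
    rec["Y"] = np.round((y - mins[1]) / scale).astype(np.int32)
    rec["Z"] = np.round((z - mins[2]) / scale).astype(np.int32)
    rec["flags"] = ((np.clip(rn, 1, 7) & 0x07)
                    | ((np.clip(nor, 1, 7) & 0x07) << 3)).astype(np.uint8)
    rec["classification"] = cls

    hdr = bytearray(227)
    hdr[0:4] = _SIGNATURE
    hdr[24] = 1
    hdr[25] = 2
    hdr[26:26 + 11] = b"urbancanopy"
    hdr[58:58 + 11] = b"urbancanopy"
    struct.pack_into("<H", hdr, 94, 227)        # header size
    struct.pack_into("<I", hdr, 96, 227)        # offset to point data
    struct.pack_into("<I", hdr, 100, 0)         # number of VLRs
    hdr[104] = 0                                # point data format
    struct.pack_into("<H", hdr, 105, 20)        # point record length
    struct.pack_into("<I", hdr, 107, n)
    by_return = np.zeros(5, dtype=np.int64)
    for i in range(5):
        by_return[i] = int(np.count_nonzero(np.clip(rn, 1, 7) == i + 1))
    struct.pack_into("<5I", hdr, 111, *by_return)
    struct.pack_into("<3d", hdr, 131, scale, scale, scale)
    struct.pack_into("<3d", hdr, 155, *mins)
    struct.pack_into("<6d", hdr, 179, maxs[0], mins[0], maxs[1], mins[1],
                     maxs[2], mins[2])
    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        fh.write(rec.tobytes())
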