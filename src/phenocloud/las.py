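"""Minimal LAS reader/writer for x,y,z point clouds.

Reads uncompressed LAS 1.1-1.4 (any point record format: only the leading
x, y, z int32 triplet is decoded; intensity, RGB, classification and the
rest of the record are ignored by the algorithm).  Writes LAS 1.2, point
format 0, or point format 1 when normalized heights are persisted (the
8-byte GPS-time field is reused to carry height above terrain -- a
documented convention of this package, flagged in the generating-software
header string).

LAZ (compressed) files are detected and rejected with a clear error; only
uncompressed LAS is supported.

CRS metadata is carried through the GeoKeyDirectory VLR (record 34735):
a ProjectedCSTypeGeoKey (3072) maps to ``"EPSG:<code>"``; a file carrying
only a GeographicTypeGeoKey (2048) is rejected, because the pipeline's
metric thresholds are meaningless in degrees.

A CSV fallback (columns x,y,z) is provided for toy fixtures.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Optional

import numpy as np

from .pointcloud import PointCloud

__all__ = ["read_point_cloud", "write_point_cloud", "read_csv_points", "write_csv_points"]

_HEADER_FMT = "<4sHH16sBB32s32sHHHIIBHI5I12d"
_HEADER_SIZE = struct.calcsize(_HEADER_FMT)  # 227 bytes, the LAS 1.2 header
_VLR_HEADER_FMT = "<H16sHH32s"
_SOFTWARE = b"phenocloud (hag-in-gpstime)"

# GeoTIFF key ids used in the GeoKeyDirectory VLR
_KEY_GEOGRAPHIC_TYPE = 2048
_KEY_PROJECTED_CS_TYPE = 3072


class LasFormatError(ValueError):
    """Raised for unreadable, corrupt or compressed files."""


def _parse_geokeys(payload: bytes) -> tuple[Optional[int], Optional[int]]:
    """Return (projected_epsg, geographic_epsg) from a GeoKeyDirectory."""
    shorts = np.frombuffer(payload, dtype="<u2")
    if shorts.size < 4:
        return None, None
    n_keys = int(shorts[3])
    projected = geographic = None
    for k in range(n_keys):
        entry = shorts[4 + 4 * k : 8 + 4 * k]
        if entry.size < 4:
            break
        key_id, tag_location, _count, value = (int(v) for v in entry)
        if tag_location != 0:
            continue  # value stored in another tag; out of scope
        if key_id == _KEY_PROJECTED_CS_TYPE:
            projected = value
        elif key_id == _KEY_GEOGRAPHIC_TYPE:
            geographic = value
    return projected, geographic


def read_point_cloud(path, heights_in_gps_time: bool = False) -> PointCloud:
    """Read an uncompressed LAS file.

    Parameters
    ----------
    path
        LAS file path.  ``.csv`` files are routed to :func:`read_csv_points`.
    heights_in_gps_time
        If True and the file has a GPS-time field (point formats 1 and 3),
        interpret it as height above terrain written by
        :func:`write_point_cloud` with ``keep_heights=True``.

    Raises
    ------
    LasFormatError
        For corrupt or LAZ-compressed input.
    ValueError
        If the file declares a geographic (lat/lon) CRS.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_csv_points(path)
    data = path.read_bytes()
    if len(data) < _HEADER_SIZE or data[:4] != b"LASF":
        raise LasFormatError(f"{path}: not a LAS file (bad signature)")
    fields = struct.unpack_from(_HEADER_FMT, data, 0)
    (_sig, _src, _enc, _guid, ver_major, ver_minor, _sysid, _software, _day,
     _year, header_size, point_offset, n_vlrs, point_format, record_len,
     n_points_legacy) = fields[:16]
    scales_offsets = fields[21:33]
    if ver_major != 1:
        raise LasFormatError(f"{path}: unsupported LAS version {ver_major}.{ver_minor}")
    if point_format & 0x80:
        raise LasFormatError(
            f"{path}: LAZ-compressed point data is not supported; "
            "decompress to .las first"
        )
    n_points = n_points_legacy
    if ver_minor >= 4 and n_points == 0 and len(data) >= 247 + 8:
        (n_points_64,) = struct.unpack_from("<Q", data, 247)
        n_points = int(n_points_64)
    sx, sy, sz, ox, oy, oz = scales_offsets[:6]

    crs = None
    pos = header_size
    for _ in range(n_vlrs):
        if pos + 54 > len(data):
            raise LasFormatError(f"{path}: truncated VLR block")
        _res, user_id, record_id, rec_len, _desc = struct.unpack_from(
            _VLR_HEADER_FMT, data, pos
        )
        payload = data[pos + 54 : pos + 54 + rec_len]
        pos += 54 + rec_len
        if user_id.rstrip(b"\x00") == b"LASF_Projection" and record_id == 34735:
            projected, geographic = _parse_geokeys(payload)
            if projected is not None:
                crs = f"EPSG:{projected}"
            elif geographic is not None:
                raise ValueError(
                    f"{path}: geographic CRS EPSG:{geographic} -- coordinates "
                    "must be in a projected, metric system"
                )

    if record_len < 12:
        raise LasFormatError(f"{path}: point record length {record_len} < 12")
    end = point_offset + n_points * record_len
    if end > len(data):
        raise LasFormatError(
            f"{path}: header declares {n_points} points but file is truncated"
        )
    raw = np.frombuffer(data[point_offset:end], dtype=np.uint8)
    raw = raw.reshape(n_points, record_len) if n_points else raw.reshape(0, record_len)
    xyz_int = raw[:, :12].copy().view("<i4").reshape(-1, 3).astype(np.float64)
    xyz = xyz_int * np.array([sx, sy, sz]) + np.array([ox, oy, oz])

    hat = None
    if heights_in_gps_time:
        gps_offset = {1: 20, 3: 20}.get(point_format)
        if gps_offset is None or record_len < gps_offset + 8:
            raise LasFormatError(
                f"{path}: point format {point_format} has no GPS-time field "
                "to read heights from"
            )
        hat = raw[:, gps_offset : gps_offset + 8].copy().view("<f8").ravel()
    return PointCloud(xyz.reshape(-1, 3), crs=crs, height_above_terrain=hat)


def _geokey_vlr(epsg: int) -> bytes:
    # GeoKeyDirectory: version 1.1.0, one key: ProjectedCSTypeGeoKey
    payload = struct.pack("<8H", 1, 1, 0, 1, _KEY_PROJECTED_CS_TYPE, 0, 1, epsg)
    header = struct.pack(
        _VLR_HEADER_FMT, 0, b"LASF_Projection", 34735, len(payload), b"GeoKeyDirectory"
    )
    return header + payload


def write_point_cloud(pc: PointCloud, path, scale: float = 0.001,
                      keep_heights: bool = False) -> None:
    """Write a LAS 1.2 file.

    Coordinates are stored as scaled integers; the declared ``scale``
    (default 1 mm) bounds the round-trip error at ``scale / 2``.

    ``keep_heights`` controls what happens to ``height_above_terrain``:
    by default it is dropped (LAS has no standard slot for it); with
    ``keep_heights=True`` point format 1 is written and the normalized
    height is stored in the GPS-time field, recoverable via
    ``read_point_cloud(path, heights_in_gps_time=True)``.
    """
    path = Path(path)
    n = len(pc)
    persist = keep_heights and pc.height_above_terrain is not None
    point_format = 1 if persist else 0
    record_len = 28 if persist else 20
    if n:
        mins = pc.xyz.min(axis=0)
        maxs = pc.xyz.max(axis=0)
    else:
        mins = maxs = np.zeros(3)
    offsets = np.floor(mins)
    xyz_int = np.round((pc.xyz - offsets) / scale).astype("<i4")

    vlrs = b""
    epsg = None
    if pc.crs:
        from .pointcloud import _epsg_code

        epsg = _epsg_code(pc.crs)
    if epsg is not None:
        vlrs = _geokey_vlr(epsg)
    point_offset = _HEADER_SIZE + len(vlrs)

    header = struct.pack(
        _HEADER_FMT,
        b"LASF", 0, 0, b"\x00" * 16, 1, 2,
        b"phenocloud".ljust(32, b"\x00"), _SOFTWARE.ljust(32, b"\x00"),
        1, 2019, _HEADER_SIZE, point_offset, 1 if vlrs else 0,
        point_format, record_len, n, n, 0, 0, 0, 0,
        scale, scale, scale, *offsets, maxs[0], mins[0], maxs[1], mins[1],
        maxs[2], mins[2],
    )

    records = np.zeros((n, record_len), dtype=np.uint8)
    if n:
        records[:, :12] = xyz_int.astype("<i4").view(np.uint8).reshape(n, 12)
        records[:, 14] = 1  # return number 1 of 1 (bits 0-2 and 3-5)
        records[:, 14] |= 1 << 3
        if persist:
            hat = np.asarray(pc.height_above_terrain, dtype="<f8")
            records[:, 20:28] = hat.view(np.uint8).reshape(n, 8)
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(vlrs)
            fh.write(records.tobytes())
    except OSError as exc:
        raise OSError(f"cannot write LAS file {path}: {exc}") from exc


def read_csv_points(path) -> PointCloud:
    """CSV fallback for toy fixtures: columns x,y,z (header optional)."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if set("xyz") <= set(cols):
        df.columns = cols
        xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    else:  # headerless: first three columns
        df = pd.read_csv(path, header=None)
        xyz = df.iloc[:, :3].to_numpy(dtype=float)
    return PointCloud(xyz)


def write_csv_points(pc: PointCloud, path) -> None:
    import pandas as pd

    df = pd.DataFrame(pc.xyz, columns=["x", "y", "z"])
    if pc.height_above_terrain is not None:
        df["height_above_terrain"] = pc.height_above_terrain
    df.to_csv(path, index=False)
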