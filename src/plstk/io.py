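"""Reading and writing point clouds and ancillary inputs.

Point clouds travel as ASPRS LAS files (LAS 1.4 / point format 6 on write;
LAS 1.2 / format 1 also accepted on read).  The pipeline's derived per-point
attributes — Reflectance (dB), Deviation, the scan angles Theta and Phi, the
range from the scanner and the tree label — are stored as named extra-byte
records (RIEGL naming convention, matched case-insensitively on read).
Coordinates are quantized at 0.001 m with per-file offsets at the floor of the
coordinate minima, so centimetre-level science survives a round trip.

Only uncompressed ``.las`` is supported: LAZ decompression needs an external
codec and is out of scope here; a ``.laz`` path raises a clear error.

LAS makes intensity and the return counters mandatory per-point fields, so
they always materialize on read (0 and 1/1 when the written cloud lacked
them); truly optional columns are only present when an extra-byte record
exists — they are never zero-filled.
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cloud import ControlPointPair, PointCloud, TerrainModel

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "read_dtm",
    "read_control_points",
]

COORD_SCALE = 1e-3  # metres per integer step

# canonical attribute -> extra-byte record name written to file
_EXTRA_NAMES = {
    "reflectance": "Reflectance",
    "deviation": "Deviation",
    "theta": "Theta",
    "phi_az": "Phi",
    "range": "Range",
    "label": "label",
}
# file name (lowercased) -> canonical attribute
_NAME_TO_ATTR = {v.lower(): k for k, v in _EXTRA_NAMES.items()}
_NAME_TO_ATTR["phi_az"] = "phi_az"

_EB_DTYPES = {
    1: np.dtype("u1"), 2: np.dtype("i1"), 3: np.dtype("<u2"), 4: np.dtype("<i2"),
    5: np.dtype("<u4"), 6: np.dtype("<i4"), 7: np.dtype("<u8"), 8: np.dtype("<i8"),
    9: np.dtype("<f4"), 10: np.dtype("<f8"),
}

_FMT6 = np.dtype([
    ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"), ("intensity", "<u2"),
    ("returns", "u1"), ("flags", "u1"), ("classification", "u1"),
    ("user_data", "u1"), ("scan_angle", "<i2"), ("point_source", "<u2"),
    ("gps_time", "<f8"),
])
_FMT1 = np.dtype([
    ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"), ("intensity", "<u2"),
    ("flag", "u1"), ("classification", "u1"), ("scan_angle", "i1"),
    ("user_data", "u1"), ("point_source", "<u2"), ("gps_time", "<f8"),
])


def _check_las_path(path: Path) -> None:
    if path.suffix.lower() == ".laz":
        raise ValueError(
            f"{path}: LAZ decompression is not supported; supply an uncompressed .las file"
        )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _extra_bytes_vlr(attrs: list[str]) -> bytes:
    recs = b""
    for a in attrs:
        dtype_code = 10 if a != "label" else 8  # doubles; label as int64
        name = _EXTRA_NAMES[a].encode("ascii")
        rec = struct.pack("<2B", 0, 0)
        rec += struct.pack("<B", dtype_code)
        rec += struct.pack("<B", 0)          # options: raw values, no scaling
        rec += name.ljust(32, b"\x00")
        rec += b"\x00" * 4                   # unused
        rec += b"\x00" * 24 * 3              # no_data / min / max (unused)
        rec += struct.pack("<3d", 1.0, 1.0, 1.0)   # scale (unused)
        rec += struct.pack("<3d", 0.0, 0.0, 0.0)   # offset (unused)
        rec += b"\x00" * 32                  # description
        recs += rec
    header = struct.pack("<H", 0)
    header += b"LASF_Spec".ljust(16, b"\x00")
    header += struct.pack("<H", 4)
    header += struct.pack("<H", len(recs))
    header += b"extra bytes".ljust(32, b"\x00")
    return header + recs


def write_point_cloud(cloud: PointCloud, path) -> None:
    """Write ``cloud`` to an uncompressed LAS 1.4 / point-format-6 file."""
    path = Path(path)
    _check_las_path(path)
    cloud.validate()
    n = len(cloud)

    extras = [a for a in _EXTRA_NAMES if cloud.has(a)]
    extra_len = sum(8 for _ in extras)
    rec_len = _FMT6.itemsize + extra_len

    if n:
        offs = np.floor(np.array([cloud.x.min(), cloud.y.min(), cloud.z.min()]))
        mins = np.array([cloud.x.min(), cloud.y.min(), cloud.z.min()])
        maxs = np.array([cloud.x.max(), cloud.y.max(), cloud.z.max()])
    else:
        offs = np.zeros(3)
        mins = maxs = np.zeros(3)

    fields = list(_FMT6.descr) + [(_EXTRA_NAMES[a], "<f8" if a != "label" else "<i8")
                                  for a in extras]
    rec = np.zeros(n, dtype=np.dtype(fields))
    for axis, name in zip("xyz", ("X", "Y", "Z")):
        q = np.round((cloud[axis] - offs["xyz".index(axis)]) / COORD_SCALE)
        if n and (q.min() < -2**31 or q.max() >= 2**31):
            raise ValueError("coordinates exceed LAS int32 range at 1 mm scale")
        rec[name] = q.astype(np.int64)
    if cloud.has("intensity"):
        rec["intensity"] = np.clip(np.round(cloud["intensity"]), 0, 65535).astype(np.uint16)
    rn = cloud["return_number"] if cloud.has("return_number") else np.ones(n, dtype=np.int64)
    nr = (cloud["number_of_returns"] if cloud.has("number_of_returns")
          else np.maximum(rn, 1))
    rec["returns"] = ((nr.astype(np.uint8) & 0x0F) << 4) | (rn.astype(np.uint8) & 0x0F)
    for a in extras:
        rec[_EXTRA_NAMES[a]] = cloud[a]

    vlr = _extra_bytes_vlr(extras) if extras else b""
    n_vlr = 1 if extras else 0
    header_size = 375
    offset_to_points = header_size + len(vlr)

    hdr = bytearray(header_size)
    hdr[0:4] = b"LASF"
    struct.pack_into("<H", hdr, 4, 0)
    struct.pack_into("<H", hdr, 6, 0)
    hdr[24] = 1
    hdr[25] = 4
    hdr[26:26 + 5] = b"plstk"
    hdr[58:58 + 5] = b"plstk"
    struct.pack_into("<H", hdr, 94, header_size)
    struct.pack_into("<I", hdr, 96, offset_to_points)
    struct.pack_into("<I", hdr, 100, n_vlr)
    hdr[104] = 6
    struct.pack_into("<H", hdr, 105, rec_len)
    # legacy counts stay 0 for format 6
    struct.pack_into("<3d", hdr, 131, COORD_SCALE, COORD_SCALE, COORD_SCALE)
    struct.pack_into("<3d", hdr, 155, *offs)
    struct.pack_into("<6d", hdr, 179, maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2])
    struct.pack_into("<Q", hdr, 247, n)
    by_return = np.zeros(15, dtype=np.uint64)
    if n:
        vals, counts = np.unique(np.clip(rn, 1, 15), return_counts=True)
        by_return[vals.astype(int) - 1] = counts
    struct.pack_into("<15Q", hdr, 255, *by_return.tolist())

    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        fh.write(vlr)
        fh.write(rec.tobytes())


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_extra_vlr(payload: bytes):
    out = []
    for off in range(0, len(payload), 192):
        chunk = payload[off:off + 192]
        if len(chunk) < 192:
            break
        dtype_code = chunk[2]
        options = chunk[3]
        name = chunk[4:36].split(b"\x00", 1)[0].decode("ascii", "replace")
        scale = struct.unpack_from("<d", chunk, 112)[0] if options & 0x08 else 1.0
        offset = struct.unpack_from("<d", chunk, 136)[0] if options & 0x10 else 0.0
        out.append((name, dtype_code, scale, offset))
    return out


def read_point_cloud(path, required_attrs=()) -> PointCloud:
    """Read a LAS file, mapping extra-byte records to named attribute columns.

    ``required_attrs`` lists canonical attribute names (e.g. ``deviation``)
    that must be present; a missing one is an error naming the attribute.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_las_path(path)
    data = path.read_bytes()
    if data[:4] != b"LASF":
        raise ValueError(f"{path}: not a LAS file")
    major, minor = data[24], data[25]
    if (major, minor) < (1, 2) or (major, minor) > (1, 4):
        raise ValueError(f"{path}: unsupported LAS version {major}.{minor}")
    offset_to_points = struct.unpack_from("<I", data, 96)[0]
    n_vlr = struct.unpack_from("<I", data, 100)[0]
    header_size = struct.unpack_from("<H", data, 94)[0]
    fmt = data[104]
    if fmt & 0xC0:
        raise ValueError(f"{path}: compressed (LAZ) point records are not supported")
    rec_len = struct.unpack_from("<H", data, 105)[0]
    n_points = struct.unpack_from("<I", data, 107)[0]
    if minor >= 4:
        n64 = struct.unpack_from("<Q", data, 247)[0]
        n_points = n64 or n_points
    scales = struct.unpack_from("<3d", data, 131)
    offs = struct.unpack_from("<3d", data, 155)

    # walk VLRs for the extra-bytes descriptor
    extra_desc = []
    pos = header_size
    for _ in range(n_vlr):
        user_id = data[pos + 2:pos + 18].split(b"\x00", 1)[0]
        record_id = struct.unpack_from("<H", data, pos + 18)[0]
        length = struct.unpack_from("<H", data, pos + 20)[0]
        payload = data[pos + 54:pos + 54 + length]
        if user_id == b"LASF_Spec" and record_id == 4:
            extra_desc = _parse_extra_vlr(payload)
        pos += 54 + length

    if fmt == 6:
        base = _FMT6
    elif fmt == 1:
        base = _FMT1
    else:
        raise ValueError(f"{path}: unsupported point data format {fmt}")
    extra_len = rec_len - base.itemsize
    if extra_len < 0:
        raise ValueError(f"{path}: record length {rec_len} below format minimum")
    fields = list(base.descr)
    declared = sum(_EB_DTYPES[c].itemsize for _, c, _, _ in extra_desc) if extra_desc else 0
    if extra_desc and declared == extra_len:
        for name, code, _, _ in extra_desc:
            fields.append((f"__eb_{name}", _EB_DTYPES[code].str))
    elif extra_len:
        fields.append(("__pad", f"V{extra_len}"))
    dtype = np.dtype(fields)

    raw = np.frombuffer(data, dtype=dtype, count=n_points, offset=offset_to_points)
    if n_points == 0:
        warnings.warn(f"{path}: zero points", stacklevel=2)

    x = raw["X"] * scales[0] + offs[0]
    y = raw["Y"] * scales[1] + offs[1]
    z = raw["Z"] * scales[2] + offs[2]
    attrs: dict[str, np.ndarray] = {"intensity": raw["intensity"].astype(np.float64)}
    if fmt == 6:
        attrs["return_number"] = (raw["returns"] & 0x0F).astype(np.int64)
        attrs["number_of_returns"] = (raw["returns"] >> 4).astype(np.int64)
    else:
        attrs["return_number"] = (raw["flag"] & 0x07).astype(np.int64)
        attrs["number_of_returns"] = ((raw["flag"] >> 3) & 0x07).astype(np.int64)
    for name, code, scale, offset in extra_desc:
        attr = _NAME_TO_ATTR.get(name.lower())
        key = f"__eb_{name}"
        if attr is None or key not in raw.dtype.names:
            continue
        vals = raw[key].astype(np.float64) * scale + offset
        attrs[attr] = vals.astype(np.int64) if attr == "label" else vals

    for req in required_attrs:
        if req not in ("x", "y", "z") and req not in attrs:
            raise ValueError(f"{path}: required attribute {req!r} absent from file")

    return PointCloud(x, y, z, **attrs)


# ---------------------------------------------------------------------------
# ancillary inputs
# ---------------------------------------------------------------------------

def read_dtm(path, resolution: float | None = None) -> TerrainModel:
    """Read a DTM from LAS points or a CSV/XYZ text table.

    When ``resolution`` is omitted it is inferred as the median planimetric
    nearest-neighbour spacing of the support points.
    """
    path = Path(path)
    if path.suffix.lower() in (".las", ".laz"):
        cloud = read_point_cloud(path)
        support = cloud.xyz
    else:
        df = pd.read_csv(path)
        cols = [c.lower() for c in df.columns]
        if {"x", "y", "z"}.issubset(cols):
            support = df[[df.columns[cols.index(a)] for a in "xyz"]].to_numpy(float)
        else:
            support = df.iloc[:, :3].to_numpy(float)
    if support.shape[0] == 0:
        raise ValueError(f"{path}: empty DTM")
    if resolution is None:
        if support.shape[0] > 1:
            sub = support[:: max(1, support.shape[0] // 5000)]
            d, _ = cKDTree(support[:, :2]).query(sub[:, :2], k=2)
            resolution = float(np.median(d[:, 1]))
        else:
            resolution = 0.20
    return TerrainModel(support, resolution=resolution)


def read_control_points(path) -> list[ControlPointPair]:
    """Read control-point pairs from a CSV with header sx,sy,sz,tx,ty,tz."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    needed = ["sx", "sy", "sz", "tx", "ty", "tz"]
    missing = [c for c in needed if c not in cols]
    if missing:
        raise ValueError(f"{path}: control point CSV lacks columns {missing}")
    if len(df) < 3:
        raise ValueError(
            f"{path}: need >= 3 control point pairs for a 7-parameter fit, got {len(df)}"
        )
    return [
        ControlPointPair(row[[cols[c] for c in needed[:3]]].to_numpy(float),
                         row[[cols[c] for c in needed[3:]]].to_numpy(float))
        for _, row in df.iterrows()
    ]
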