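"""Minimal C3D reader/writer for marker trajectories.

C3D is the standard binary container for optical motion-capture data.
This module implements the subset needed for gait trials: the 512-byte
header, the POINT parameter group (USED, FRAMES, LABELS, RATE, UNITS,
SCALE, DATA_START) and the 3D point data section.  Intel (PC) byte
order is supported; both floating-point and scaled-integer point data
are read, while files are always written as floats.  Occluded samples
are flagged through the point residual word (negative residual =
invalid), the convention used by all mainstream C3D producers.

Analog channels, force-platform and EMG data are ignored on read and
never written.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

_BLOCK = 512
_PROC_INTEL = 84


class C3DError(IOError):
    """Raised on malformed or unsupported C3D content."""


@dataclass
class C3DPointData:
    labels: list[str]
    rate: float
    units: str
    points: np.ndarray      # (n_frames, n_points, 3)
    residuals: np.ndarray   # (n_frames, n_points); negative = invalid
    first_frame: int


# ----------------------------------------------------------------------
# reading
# ----------------------------------------------------------------------

def _read_param_section(buf: bytes, start: int) -> dict[str, dict[str, object]]:
    """Walk the parameter section, returning {GROUP: {PARAM: value}}."""
    proc = buf[start + 3]
    if proc != _PROC_INTEL:
        raise C3DError(f"unsupported processor type {proc} (only Intel/PC supported)")
    groups_by_id: dict[int, str] = {}
    params: list[tuple[int, str, object]] = []
    pos = start + 4
    while pos < len(buf) - 1:
        n_chars = struct.unpack_from("b", buf, pos)[0]
        if n_chars == 0:
            break
        group_id = struct.unpack_from("b", buf, pos + 1)[0]
        name = buf[pos + 2 : pos + 2 + abs(n_chars)].decode("ascii", "replace").strip().upper()
        p = pos + 2 + abs(n_chars)
        offset = struct.unpack_from("<h", buf, p)[0]
        next_pos = p + offset
        p += 2
        if group_id < 0:  # group record
            groups_by_id[-group_id] = name
        else:  # parameter record
            elem_size = struct.unpack_from("b", buf, p)[0]
            n_dims = buf[p + 1]
            dims = list(buf[p + 2 : p + 2 + n_dims])
            p += 2 + n_dims
            count = int(np.prod(dims)) if dims else 1
            if elem_size == -1:
                raw = buf[p : p + count]
                if len(dims) <= 1:
                    value: object = raw.decode("ascii", "replace")
                else:
                    width = dims[0]
                    value = [
                        raw[i * width : (i + 1) * width].decode("ascii", "replace")
                        for i in range(count // width)
                    ]
            elif elem_size == 1:
                value = np.frombuffer(buf, np.int8, count, p).reshape(dims[::-1] or [1])
            elif elem_size == 2:
                value = np.frombuffer(buf, "<i2", count, p).reshape(dims[::-1] or [1])
            elif elem_size == 4:
                value = np.frombuffer(buf, "<f4", count, p).reshape(dims[::-1] or [1])
            else:
                raise C3DError(f"bad parameter element size {elem_size}")
            params.append((group_id, name, value))
        if offset == 0:
            break
        pos = next_pos
    out: dict[str, dict[str, object]] = {}
    for gid, pname, value in params:
        gname = groups_by_id.get(gid, f"GROUP{gid}")
        out.setdefault(gname, {})[pname] = value
    return out


def read_c3d(path: str) -> C3DPointData:
    """Read the 3D point section of a C3D file."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 2 * _BLOCK:
        raise C3DError(f"{path}: file too short to be a C3D file")
    param_block, magic = buf[0], buf[1]
    if magic != 0x50:
        raise C3DError(f"{path}: missing C3D magic byte (found {magic:#x})")
    n_points = struct.unpack_from("<H", buf, 2)[0]
    first_frame = struct.unpack_from("<H", buf, 6)[0]
    last_frame = struct.unpack_from("<H", buf, 8)[0]
    header_scale = struct.unpack_from("<f", buf, 12)[0]
    data_block = struct.unpack_from("<H", buf, 16)[0]
    analog_per_frame = struct.unpack_from("<H", buf, 18)[0]
    header_rate = struct.unpack_from("<f", buf, 20)[0]

    pstart = (param_block - 1) * _BLOCK
    groups = _read_param_section(buf, pstart)
    point = groups.get("POINT", {})

    def scalar(name, default):
        v = point.get(name)
        if v is None:
            return default
        return float(np.asarray(v).ravel()[0])

    n_points = int(scalar("USED", n_points))
    n_frames = int(scalar("FRAMES", last_frame - first_frame + 1))
    rate = scalar("RATE", header_rate)
    scale = scalar("SCALE", header_scale)
    data_block = int(scalar("DATA_START", data_block))
    units_raw = point.get("UNITS", "mm")
    if isinstance(units_raw, list):
        units_raw = units_raw[0] if units_raw else "mm"
    units = str(units_raw).strip().lower() or "mm"
    labels_raw = point.get("LABELS", [])
    if isinstance(labels_raw, str):
        labels_raw = [labels_raw]
    labels = [s.strip() for s in labels_raw][:n_points]
    while len(labels) < n_points:
        labels.append(f"M{len(labels):03d}")

    total_analog = struct.unpack_from("<H", buf, 4)[0]
    analog_words = total_analog  # analog samples per 3D frame (all channels)
    dstart = (data_block - 1) * _BLOCK
    words_per_frame = 4 * n_points + analog_words
    if scale < 0:  # floating point storage
        raw = np.frombuffer(buf, "<f4", words_per_frame * n_frames, dstart)
        frames = raw.reshape(n_frames, words_per_frame)
        pts = frames[:, : 4 * n_points].reshape(n_frames, n_points, 4)
        xyz = pts[:, :, :3].astype(float)
        resid = pts[:, :, 3].astype(float)
    else:  # scaled 16-bit integer storage
        raw = np.frombuffer(buf, "<i2", words_per_frame * n_frames, dstart)
        frames = raw.reshape(n_frames, words_per_frame)
        pts = frames[:, : 4 * n_points].reshape(n_frames, n_points, 4)
        xyz = pts[:, :, :3].astype(float) * scale
        resid = pts[:, :, 3].astype(float)
    return C3DPointData(
        labels=labels, rate=rate, units=units, points=xyz,
        residuals=resid, first_frame=first_frame,
    )


# ----------------------------------------------------------------------
# writing
# ----------------------------------------------------------------------

def _param_records(labels: list[str], rate: float, units: str,
                   n_frames: int, data_block: int) -> bytes:
    out = bytearray()

    def record(name: str, group_id: int, payload: bytes, last=False):
        nm = name.encode("ascii")
        rec = struct.pack("bb", len(nm), group_id) + nm
        body = payload + b"\x00"  # zero-length description
        offset = 0 if last else 2 + len(body)
        rec += struct.pack("<h", offset) + body
        out.extend(rec)

    def param(name, elem_size, dims, data: bytes, last=False):
        payload = struct.pack("bB", elem_size, len(dims)) + bytes(dims) + data
        record(name, 1, payload, last=last)

    record("POINT", -1, b"")
    param("USED", 2, [], struct.pack("<h", len(labels)))
    param("FRAMES", 2, [], struct.pack("<H", n_frames))
    param("RATE", 4, [], struct.pack("<f", rate))
    param("SCALE", 4, [], struct.pack("<f", -1.0))
    param("DATA_START", 2, [], struct.pack("<h", data_block))
    u = units.encode("ascii")
    param("UNITS", -1, [len(u)], u)
    width = max(len(s) for s in labels)
    lab = b"".join(s.encode("ascii").ljust(width) for s in labels)
    param("LABELS", -1, [width, len(labels)], lab, last=True)
    return bytes(out)


def write_c3d(path: str, labels: list[str], points: np.ndarray,
              rate: float, units: str = "mm",
              residuals: np.ndarray | None = None) -> None:
    """Write marker trajectories as a float, Intel-order C3D file.

    ``points`` has shape (n_frames, n_points, 3) in the given units;
    non-finite samples (or negative ``residuals``) are stored with a
    residual of -1, the standard occlusion flag.
    """
    points = np.asarray(points, dtype=float)
    n_frames, n_points, _ = points.shape
    if residuals is None:
        residuals = np.where(np.all(np.isfinite(points), axis=2), 0.0, -1.0)

    # layout: header (block 1), parameters, then data
    params_body = _param_records(labels, rate, units, n_frames, data_block=0)
    n_param_blocks = (4 + len(params_body) + _BLOCK - 1) // _BLOCK
    data_block = 2 + n_param_blocks
    params_body = _param_records(labels, rate, units, n_frames, data_block=data_block)

    header = bytearray(_BLOCK)
    header[0], header[1] = 2, 0x50
    struct.pack_into("<H", header, 2, n_points)
    struct.pack_into("<H", header, 4, 0)              # no analog
    struct.pack_into("<H", header, 6, 1)              # first frame
    struct.pack_into("<H", header, 8, n_frames)       # last frame
    struct.pack_into("<H", header, 10, 0)             # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)          # scale (float data)
    struct.pack_into("<H", header, 16, data_block)
    struct.pack_into("<H", header, 18, 0)             # analog per frame
    struct.pack_into("<f", header, 20, rate)

    pheader = struct.pack("BBBB", 0, 0x50, n_param_blocks, _PROC_INTEL)
    psection = pheader + params_body
    psection += b"\x00" * (n_param_blocks * _BLOCK - len(psection))

    frames = np.empty((n_frames, n_points, 4), dtype="<f4")
    frames[:, :, :3] = np.where(np.isfinite(points), points, 0.0)
    frames[:, :, 3] = residuals
    data = frames.tobytes()
    if len(data) % _BLOCK:
        data += b"\x00" * (_BLOCK - len(data) % _BLOCK)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(psection)
        fh.write(data)
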