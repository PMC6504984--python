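"""Minimal DICOM series reader/writer for CT-style voxel volumes.

Implements only the subset needed to round-trip a single-frame monochrome CT
series: explicit VR little endian, signed 16-bit pixels, RescaleSlope /
RescaleIntercept, PixelSpacing / SliceThickness / ImagePositionPatient.
Slices are assembled by z position, so file naming/order on disk is
irrelevant.
"""
from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .phantom import VoxelVolume

_TRANSFER_SYNTAX_LE_EXPLICIT = "1.2.840.10008.1.2.1"
_CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
_UID_ROOT = "1.2.826.0.1.3680043.9.7433"  # arbitrary private root

_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}


class DicomFormatError(ValueError):
    """Raised for unreadable, inconsistent or incomplete DICOM series."""


def _encode_element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in (b"UI", b"OB") else b" "
    head = struct.pack("<HH", group, elem) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + struct.pack("<H", len(value)) + value


def _str(value: str) -> bytes:
    return value.encode("ascii")


def _ds(*values: float) -> bytes:
    return "\\".join(format(v, ".10g") for v in values).encode("ascii")


def write_dicom_series(vol: VoxelVolume, directory: str | Path,
                       rescale_intercept: float = -1024.0,
                       rescale_slope: float = 1.0) -> list[Path]:
    """Write one explicit-VR-LE file per z slice; returns the file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = vol.values.shape
    dx, dy, dz = vol.spacing_mm
    stored = np.round((vol.values - rescale_intercept) / rescale_slope)
    if stored.min() < -32768 or stored.max() > 32767:
        raise DicomFormatError("HU values do not fit signed 16-bit storage")
    stored = stored.astype("<i2")
    paths = []
    for k in range(nz):
        ipp = (vol.origin_mm[0] + 0.5 * dx,
               vol.origin_mm[1] + 0.5 * dy,
               vol.origin_mm[2] + (k + 0.5) * dz)
        # pixel (row r, col c) maps to (x = c, y = r)
        pixels = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        sop_uid = f"{_UID_ROOT}.1.{k + 1}"
        meta = b"".join([
            _encode_element(0x0002, 0x0001, b"OB", b"\x00\x01"),
            _encode_element(0x0002, 0x0002, b"UI", _str(_CT_SOP_CLASS)),
            _encode_element(0x0002, 0x0003, b"UI", _str(sop_uid)),
            _encode_element(0x0002, 0x0010, b"UI", _str(_TRANSFER_SYNTAX_LE_EXPLICIT)),
        ])
        body = b"".join([
            _encode_element(0x0008, 0x0016, b"UI", _str(_CT_SOP_CLASS)),
            _encode_element(0x0008, 0x0018, b"UI", _str(sop_uid)),
            _encode_element(0x0008, 0x0060, b"CS", b"CT"),
            _encode_element(0x0018, 0x0050, b"DS", _ds(dz)),
            _encode_element(0x0020, 0x0013, b"IS", _str(str(k + 1))),
            _encode_element(0x0020, 0x0032, b"DS", _ds(*ipp)),
            _encode_element(0x0020, 0x0037, b"DS", _ds(1, 0, 0, 0, 1, 0)),
            _encode_element(0x0028, 0x0002, b"US", struct.pack("<H", 1)),
            _encode_element(0x0028, 0x0004, b"CS", b"MONOCHROME2"),
            _encode_element(0x0028, 0x0010, b"US", struct.pack("<H", ny)),
            _encode_element(0x0028, 0x0011, b"US", struct.pack("<H", nx)),
            _encode_element(0x0028, 0x0030, b"DS", _ds(dy, dx)),
            _encode_element(0x0028, 0x0100, b"US", struct.pack("<H", 16)),
            _encode_element(0x0028, 0x0101, b"US", struct.pack("<H", 16)),
            _encode_element(0x0028, 0x0102, b"US", struct.pack("<H", 15)),
            _encode_element(0x0028, 0x0103, b"US", struct.pack("<H", 1)),
            _encode_element(0x0028, 0x1052, b"DS", _ds(rescale_intercept)),
            _encode_element(0x0028, 0x1053, b"DS", _ds(rescale_slope)),
            _encode_element(0x7FE0, 0x0010, b"OW", pixels),
        ])
        group_len = _encode_element(0x0002, 0x0000, b"UL",
                                    struct.pack("<I", len(meta)))
        path = directory / f"slice_{k + 1:04d}.dcm"
        path.write_bytes(b"\x00" * 128 + b"DICM" + group_len + meta + body)
        paths.append(path)
    return paths


def _parse_elements(buf: bytes, offset: int) -> dict[tuple[int, int], bytes]:
    elements: dict[tuple[int, int], bytes] = {}
    n = len(buf)
    while offset < n:
        if offset + 8 > n:
            raise DicomFormatError(f"truncated element header at byte {offset}")
        group, elem = struct.unpack_from("<HH", buf, offset)
        vr = buf[offset + 4:offset + 6]
        if vr in _LONG_VRS:
            if offset + 12 > n:
                raise DicomFormatError(f"truncated element header at byte {offset}")
            (length,) = struct.unpack_from("<I", buf, offset + 8)
            start = offset + 12
        else:
            (length,) = struct.unpack_from("<H", buf, offset + 6)
            start = offset + 8
        if start + length > n:
            raise DicomFormatError(
                f"element ({group:04x},{elem:04x}) at byte {offset} overruns file")
        elements[(group, elem)] = buf[start:start + length]
        offset = start + length
    return elements


def _read_slice(path: Path) -> dict:
    buf = path.read_bytes()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise DicomFormatError(f"{path.name}: missing DICM marker")
    # file meta group: first element must be the group length
    group, elem = struct.unpack_from("<HH", buf, 132)
    if (group, elem) != (0x0002, 0x0000):
        raise DicomFormatError(f"{path.name}: missing file meta group length")
    (meta_len,) = struct.unpack_from("<I", buf, 140)
    meta = _parse_elements(buf[144:144 + meta_len], 0)
    ts = meta.get((0x0002, 0x0010), b"").rstrip(b"\x00").decode("ascii")
    if ts != _TRANSFER_SYNTAX_LE_EXPLICIT:
        raise DicomFormatError(f"{path.name}: unsupported transfer syntax {ts!r}")
    elems = _parse_elements(buf, 144 + meta_len)

    def ds(tag: tuple[int, int]) -> list[float]:
        raw = elems.get(tag)
        if raw is None:
            raise DicomFormatError(f"{path.name}: missing tag {tag}")
        return [float(x) for x in raw.decode("ascii").strip().split("\\")]

    def us(tag: tuple[int, int]) -> int:
        return struct.unpack("<H", elems[tag])[0]

    rows, cols = us((0x0028, 0x0010)), us((0x0028, 0x0011))
    pixel_bytes = elems.get((0x7FE0, 0x0010))
    if pixel_bytes is None or len(pixel_bytes) < 2 * rows * cols:
        raise DicomFormatError(f"{path.name}: pixel data missing or short")
    pixels = np.frombuffer(pixel_bytes[:2 * rows * cols],
                           dtype="<i2").reshape(rows, cols)
    slope = ds((0x0028, 0x1053))[0]
    intercept = ds((0x0028, 0x1052))[0]
    return {
        "path": path,
        "ipp": ds((0x0020, 0x0032)),
        "spacing_row_col": ds((0x0028, 0x0030)),
        "thickness": ds((0x0018, 0x0050))[0],
        "hu": pixels.astype(float) * slope + intercept,
    }


def read_dicom_series(directory: str | Path) -> VoxelVolume:
    """Assemble a directory of single-frame slices, ordered by z position."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir()
                   if p.is_file() and p.suffix.lower() == ".dcm")
    if not files:
        raise DicomFormatError(f"no DICOM slices found in {directory}")
    slices = [_read_slice(p) for p in files]
    slices.sort(key=lambda s: s["ipp"][2])

    ref = slices[0]
    dy, dx = ref["spacing_row_col"]
    for s in slices[1:]:
        if s["spacing_row_col"] != ref["spacing_row_col"]:
            raise DicomFormatError(f"{s['path'].name}: pixel spacing differs "
                                   f"from {ref['path'].name}")
        if s["hu"].shape != ref["hu"].shape:
            raise DicomFormatError(f"{s['path'].name}: slice shape differs")
    zs = np.array([s["ipp"][2] for s in slices])
    if len(zs) > 1:
        dz_all = np.diff(zs)
        dz = float(np.median(dz_all))
        if dz <= 0:
            raise DicomFormatError("duplicate slice positions in series")
        bad = np.flatnonzero(np.abs(dz_all - dz) > 1e-6 * max(1.0, abs(dz)))
        if len(bad):
            raise DicomFormatError(
                f"non-uniform slice spacing near {slices[int(bad[0]) + 1]['path'].name}")
    else:
        dz = ref["thickness"]

    values = np.stack([s["hu"].T for s in slices], axis=2)
    origin = np.array([ref["ipp"][0] - 0.5 * dx,
                       ref["ipp"][1] - 0.5 * dy,
                       zs[0] - 0.5 * dz])
    return VoxelVolume(values, np.array([dx, dy, dz]), origin)
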