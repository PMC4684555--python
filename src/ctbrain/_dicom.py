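"""Minimal single-frame CT DICOM codec.

Supports uncompressed little-endian transfer syntaxes (implicit and
explicit VR) only, which covers reconstructed axial CT series as they
come off a scanner.  Only the handful of attributes the loader needs are
interpreted; everything else is skipped structurally.
"""
from __future__ import annotations

import os
import struct
from dataclasses import dataclass

import numpy as np

TS_IMPLICIT_LE = "1.2.840.10008.1.2"
TS_EXPLICIT_LE = "1.2.840.10008.1.2.1"
_CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"

# VRs whose explicit encoding uses a 2-byte reserved field + 4-byte length
_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}

# (group, element) -> key
_WANTED = {
    (0x0008, 0x0060): "modality",
    (0x0018, 0x0050): "slice_thickness",
    (0x0020, 0x0032): "image_position",
    (0x0020, 0x1041): "slice_location",
    (0x0028, 0x0010): "rows",
    (0x0028, 0x0011): "columns",
    (0x0028, 0x0030): "pixel_spacing",
    (0x0028, 0x0100): "bits_allocated",
    (0x0028, 0x0103): "pixel_representation",
    (0x0028, 0x1052): "rescale_intercept",
    (0x0028, 0x1053): "rescale_slope",
    (0x7FE0, 0x0010): "pixel_data",
}


class DicomError(ValueError):
    """Raised on files this codec cannot or refuses to parse."""


@dataclass
class CTSlice:
    """One parsed single-frame CT image."""

    raw: np.ndarray                 # (rows, cols), stored pixel values
    position: tuple[float, float, float] | None
    slice_location: float | None
    pixel_spacing: tuple[float, float] | None   # (row, col) mm
    slice_thickness: float | None
    rescale_slope: float | None
    rescale_intercept: float | None

    @property
    def z(self) -> float:
        if self.position is not None:
            return self.position[2]
        if self.slice_location is not None:
            return self.slice_location
        raise DicomError("slice has no position metadata")


def _parse_ds(value: bytes) -> list[float]:
    text = value.decode("ascii", errors="replace").strip("\x00 ")
    return [float(part) for part in text.split("\\") if part.strip()]


def read_ct_slice(path: str | os.PathLike) -> CTSlice:
    with open(path, "rb") as fh:
        data = fh.read()

    offset = 0
    explicit = True
    if len(data) > 132 and data[128:132] == b"DICM":
        offset = 132
        offset, ts = _read_file_meta(data, offset)
        if ts == TS_IMPLICIT_LE:
            explicit = False
        elif ts != TS_EXPLICIT_LE:
            raise DicomError(f"unsupported transfer syntax {ts!r}")
    # else: raw dataset without preamble; assume explicit LE and hope

    fields = _read_dataset(data, offset, explicit)
    if "pixel_data" not in fields:
        raise DicomError(f"{path}: no PixelData element")
    rows = fields.get("rows")
    cols = fields.get("columns")
    if rows is None or cols is None:
        raise DicomError(f"{path}: missing Rows/Columns")
    bits = fields.get("bits_allocated", 16)
    if bits != 16:
        raise DicomError(f"{path}: only 16-bit pixel data supported (got {bits})")
    signed = fields.get("pixel_representation", 0) == 1
    dtype = np.dtype("<i2") if signed else np.dtype("<u2")
    raw = np.frombuffer(fields["pixel_data"], dtype=dtype)
    if raw.size != rows * cols:
        raise DicomError(f"{path}: pixel data size mismatch")
    raw = raw.reshape(rows, cols)

    pos = fields.get("image_position")
    spacing = fields.get("pixel_spacing")
    return CTSlice(
        raw=raw,
        position=tuple(pos) if pos is not None else None,
        slice_location=fields.get("slice_location"),
        pixel_spacing=(spacing[0], spacing[1]) if spacing is not None else None,
        slice_thickness=fields.get("slice_thickness"),
        rescale_slope=fields.get("rescale_slope"),
        rescale_intercept=fields.get("rescale_intercept"),
    )


def _read_file_meta(data: bytes, offset: int) -> tuple[int, str]:
    """Parse the (always explicit-LE) group-0002 header; return (offset, ts_uid)."""
    ts = ""
    while offset + 8 <= len(data):
        group, elem = struct.unpack_from("<HH", data, offset)
        if group != 0x0002:
            break
        vr = data[offset + 4:offset + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", data, offset + 8)
            value_off = offset + 12
        else:
            (length,) = struct.unpack_from("<H", data, offset + 6)
            value_off = offset + 8
        value = data[value_off:value_off + length]
        if (group, elem) == (0x0002, 0x0010):
            ts = value.decode("ascii").strip("\x00 ")
        offset = value_off + length
    if not ts:
        raise DicomError("file meta header lacks a transfer syntax UID")
    return offset, ts


def _read_dataset(data: bytes, offset: int, explicit: bool) -> dict:
    fields: dict = {}
    n = len(data)
    while offset + 8 <= n:
        group, elem = struct.unpack_from("<HH", data, offset)
        if explicit:
            vr = data[offset + 4:offset + 6]
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", data, offset + 8)
                value_off = offset + 12
            else:
                (length,) = struct.unpack_from("<H", data, offset + 6)
                value_off = offset + 8
        else:
            vr = b""
            (length,) = struct.unpack_from("<I", data, offset + 4)
            value_off = offset + 8
        if length == 0xFFFFFFFF:
            raise DicomError("undefined-length elements are not supported")
        value = data[value_off:value_off + length]
        offset = value_off + length

        key = _WANTED.get((group, elem))
        if key is None:
            continue
        if key == "pixel_data":
            fields[key] = value
            break
        elif key in ("rows", "columns", "bits_allocated", "pixel_representation"):
            fields[key] = struct.unpack("<H", value[:2])[0]
        elif key in ("rescale_slope", "rescale_intercept", "slice_thickness",
                     "slice_location"):
            parsed = _parse_ds(value)
            fields[key] = parsed[0] if parsed else None
        elif key in ("image_position", "pixel_spacing"):
            fields[key] = _parse_ds(value)
        elif key == "modality":
            fields[key] = value.decode("ascii").strip("\x00 ")
    return fields


# ---------------------------------------------------------------------------
# Writer (explicit VR little endian); used for synthetic series and tests.

def _element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr not in (b"UI",) else b"\x00"
    head = struct.pack("<HH", group, elem)
    if vr in _LONG_VRS:
        return head + vr + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + vr + struct.pack("<H", len(value)) + value


def _ds(*vals: float) -> bytes:
    return "\\".join(f"{v:g}" for v in vals).encode("ascii")


def write_ct_slice(
    path: str | os.PathLike,
    pixels: np.ndarray,
    *,
    position: tuple[float, float, float],
    pixel_spacing: tuple[float, float] = (0.469, 0.469),
    slice_thickness: float = 4.0,
    rescale_slope: float | None = 1.0,
    rescale_intercept: float | None = 0.0,
    instance_uid: str | None = None,
) -> None:
    """Write one int16 image as an explicit-VR-LE single-frame CT file.

    Pass ``rescale_slope=None`` / ``rescale_intercept=None`` to omit the
    rescale attributes (produces a file the reader must reject).
    """
    pixels = np.ascontiguousarray(pixels, dtype="<i2")
    rows, cols = pixels.shape
    if instance_uid is None:
        instance_uid = "1.2.826.0.1.3680043.9999." + ".".join(
            str(abs(int(v))) for v in (position[2] * 1000, rows, cols)
        )

    body = b""
    body += _element(0x0008, 0x0016, b"UI", _CT_SOP_CLASS.encode())
    body += _element(0x0008, 0x0018, b"UI", instance_uid.encode())
    body += _element(0x0008, 0x0060, b"CS", b"CT")
    body += _element(0x0018, 0x0050, b"DS", _ds(slice_thickness))
    body += _element(0x0020, 0x0032, b"DS", _ds(*position))
    body += _element(0x0020, 0x0037, b"DS", _ds(1, 0, 0, 0, 1, 0))
    body += _element(0x0020, 0x1041, b"DS", _ds(position[2]))
    body += _element(0x0028, 0x0002, b"US", struct.pack("<H", 1))
    body += _element(0x0028, 0x0010, b"US", struct.pack("<H", rows))
    body += _element(0x0028, 0x0011, b"US", struct.pack("<H", cols))
    body += _element(0x0028, 0x0030, b"DS", _ds(*pixel_spacing))
    body += _element(0x0028, 0x0100, b"US", struct.pack("<H", 16))
    body += _element(0x0028, 0x0101, b"US", struct.pack("<H", 16))
    body += _element(0x0028, 0x0102, b"US", struct.pack("<H", 15))
    body += _element(0x0028, 0x0103, b"US", struct.pack("<H", 1))
    if rescale_intercept is not None:
        body += _element(0x0028, 0x1052, b"DS", _ds(rescale_intercept))
    if rescale_slope is not None:
        body += _element(0x0028, 0x1053, b"DS", _ds(rescale_slope))
    body += _element(0x7FE0, 0x0010, b"OW", pixels.tobytes())

    meta = b""
    meta += _element(0x0002, 0x0001, b"OB", b"\x00\x01")
    meta += _element(0x0002, 0x0002, b"UI", _CT_SOP_CLASS.encode())
    meta += _element(0x0002, 0x0003, b"UI", instance_uid.encode())
    meta += _element(0x0002, 0x0010, b"UI", TS_EXPLICIT_LE.encode())
    meta += _element(0x0002, 0x0012, b"UI", b"1.2.826.0.1.3680043.9999.1")
    group_len = _element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta)))

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        fh.write(group_len + meta + body)
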