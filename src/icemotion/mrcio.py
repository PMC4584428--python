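"""Minimal MRC2014 image/stack I/O (mode 2, float32).

Implements just the dialect this package reads and writes: little-endian
mode-2 (32-bit float) 2D images and 3D stacks, with the pixel size stored
in the standard unit-cell fields (CELLA / MX,MY,MZ).  Frames are the slow
axis; within a frame the layout is row-major with x fastest, matching the
MRC convention.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_mrc", "write_mrc"]

_HEADER_BYTES = 1024


def write_mrc(path, data: np.ndarray, pixel_size: float) -> None:
    """Write ``data`` (2D image or (nz, ny, nx) stack) as mode-2 MRC."""
    data = np.asarray(data, dtype="<f4")
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    nz, ny, nx = data.shape
    header = bytearray(_HEADER_BYTES)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, 2)  # mode 2: float32
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # MX, MY, MZ
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # MAPC, MAPR, MAPS
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<i", header, 88, 0)  # ISPG: image / stack
    struct.pack_into("<i", header, 92, 0)  # NSYMBT
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 0)  # NLABL
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read a mode-2 MRC file; returns (data, pixel_size).

    2D images come back as (ny, nx); stacks as (nz, ny, nx).  The pixel
    size is CELLA_X / MX (0 if the header leaves the cell unset).
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_BYTES:
        raise ValueError(f"{path}: too short to be an MRC file")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    if mode != 2:
        raise ValueError(f"{path}: unsupported MRC mode {mode} (only mode 2)")
    (mx,) = struct.unpack_from("<i", raw, 28)
    (xlen,) = struct.unpack_from("<f", raw, 40)
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    pixel_size = xlen / mx if mx > 0 and xlen > 0 else 0.0
    offset = _HEADER_BYTES + max(nsymbt, 0)
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype="<f4", count=count, offset=offset)
    data = data.reshape(nz, ny, nx).astype(np.float64)
    return (data[0] if nz == 1 else data), pixel_size
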