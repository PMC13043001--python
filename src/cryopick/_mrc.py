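"""Minimal MRC2014 reader/writer for single-frame 2D micrographs.

Supports reading modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16),
and writing mode 2. Only what a particle picker needs: the pixel grid
and the pixel size; extended headers are skipped.
"""

from __future__ import annotations

import struct

import numpy as np

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_HEADER_BYTES = 1024


class MRCError(IOError):
    pass


def read_mrc(path):
    """Return (data[ny, nx] float32, pixel_size or None)."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_BYTES)
        if len(header) < _HEADER_BYTES:
            raise MRCError(f"{path}: truncated MRC header")
        for order in ("<", ">"):
            nx, ny, nz, mode = struct.unpack(order + "4i", header[:16])
            if 0 < nx < 100_000 and 0 < ny < 100_000 and mode in _MODE_DTYPES:
                break
        else:
            raise MRCError(f"{path}: unrecognized MRC header")
        if nz > 1:
            raise MRCError(
                f"{path}: contains a 3D stack (nz={nz}); extract a single "
                "frame before loading"
            )
        mx = struct.unpack(order + "i", header[28:32])[0]
        xlen = struct.unpack(order + "f", header[40:44])[0]
        nsymbt = struct.unpack(order + "i", header[92:96])[0]
        pixel_size = None
        if mx > 0 and xlen > 0:
            ps = xlen / mx
            if np.isfinite(ps) and ps > 0:
                pixel_size = float(ps)
        fh.seek(_HEADER_BYTES + max(nsymbt, 0))
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder(order)
        raw = fh.read(nx * ny * dtype.itemsize)
        if len(raw) < nx * ny * dtype.itemsize:
            raise MRCError(f"{path}: truncated MRC data block")
        data = np.frombuffer(raw, dtype=dtype).reshape(ny, nx)
    return np.ascontiguousarray(data, dtype=np.float32), pixel_size


def write_mrc(path, data, pixel_size=None):
    """Write a 2D float32 array as a mode-2 MRC2014 file."""
    data = np.ascontiguousarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise MRCError("write_mrc expects a 2D array")
    ny, nx = data.shape
    ps = float(pixel_size) if pixel_size else 1.0
    header = bytearray(_HEADER_BYTES)
    struct.pack_into("<4i", header, 0, nx, ny, 1, 2)
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart
    struct.pack_into("<3i", header, 28, nx, ny, 1)  # mx my mz
    struct.pack_into("<3f", header, 40, ps * nx, ps * ny, ps)  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # axis order
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<2i", header, 88, 0, 0)  # ispg, nsymbt
    struct.pack_into("<4s", header, 104, b"MRCO")  # exttyp
    struct.pack_into("<i", header, 108, 20140)  # nversion
    struct.pack_into("<3f", header, 196, 0.0, 0.0, 0.0)  # origin
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 0)  # nlabl
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(data.tobytes())
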