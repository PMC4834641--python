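"""Minimal MRC2014 volume I/O (mode 2, float32, little-endian).

Covers what the pipeline needs: lossless round-trips of (slice, row, col)
float volumes with voxel size carried in the cell dimensions.  Axis mapping
follows the MRC convention that X is the fastest axis, so a numpy array of
shape (nz, ny, nx) maps directly onto the on-disk layout.
"""

from __future__ import annotations

import struct

import numpy as np

HEADER_SIZE = 1024
_MODE_FLOAT32 = 2


class MRCParseError(ValueError):
    """Malformed or truncated MRC file."""


def write_mrc(path, volume: np.ndarray, voxel_size_nm: float | tuple[float, float, float] = 1.0) -> None:
    """Write a 3-D float volume as MRC2014 mode 2.

    ``voxel_size_nm`` may be a scalar or (z, y, x) tuple; stored in the cell
    dimensions in Angstrom per the format.
    """
    vol = np.ascontiguousarray(volume, dtype="<f4")
    if vol.ndim == 2:
        vol = vol[None]
    if vol.ndim != 3:
        raise ValueError("volume must be 2-D or 3-D")
    nz, ny, nx = vol.shape
    if np.isscalar(voxel_size_nm):
        vz = vy = vx = float(voxel_size_nm)
    else:
        vz, vy, vx = (float(v) for v in voxel_size_nm)

    header = bytearray(HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, _MODE_FLOAT32)
    # nxstart/nystart/nzstart = 0; mx, my, mz = sampling grid
    struct.pack_into("<3i", header, 28, nx, ny, nz)
    # cell dimensions in Angstrom (1 nm = 10 A), cell angles 90 deg
    struct.pack_into("<3f", header, 40, nx * vx * 10.0, ny * vy * 10.0, nz * vz * 10.0)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(vol.min()), float(vol.max()), float(vol.mean())
    )
    struct.pack_into("<i", header, 88, 0)  # ispg
    struct.pack_into("<i", header, 92, 0)  # nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(vol.std()))

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(vol.tobytes())


def read_mrc(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read an MRC volume; returns (volume (nz, ny, nx) float32,
    voxel size (z, y, x) in nm)."""
    with open(path, "rb") as fh:
        header = fh.read(HEADER_SIZE)
        if len(header) < HEADER_SIZE:
            raise MRCParseError(f"{path}: truncated header ({len(header)} bytes)")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise MRCParseError(f"{path}: missing MAP identifier")
        if mode != _MODE_FLOAT32:
            raise MRCParseError(f"{path}: unsupported MRC mode {mode} (only mode 2)")
        if min(nx, ny, nz) < 1:
            raise MRCParseError(f"{path}: invalid dimensions {(nx, ny, nz)}")
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        xlen, ylen, zlen = struct.unpack_from("<3f", header, 40)
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        fh.seek(HEADER_SIZE + nsymbt)
        count = nx * ny * nz
        data = np.frombuffer(fh.read(count * 4), dtype="<f4")
        if data.size != count:
            raise MRCParseError(
                f"{path}: truncated data section ({data.size} of {count} voxels)"
            )
    vx = xlen / mx / 10.0 if mx > 0 and xlen > 0 else 1.0
    vy = ylen / my / 10.0 if my > 0 and ylen > 0 else 1.0
    vz = zlen / mz / 10.0 if mz > 0 and zlen > 0 else 1.0
    return data.reshape(nz, ny, nx).copy(), (vz, vy, vx)
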