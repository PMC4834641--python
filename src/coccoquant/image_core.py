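"""Shared image containers, stack I/O and processing primitives.

Conventions used throughout the package: axis order is (slice, row, col),
indices are 0-based, coordinates are voxel-centered, and grey values are held
as floating point regardless of the on-disk integer type.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from . import mrcio


class ImageValidationError(ValueError):
    pass


@dataclass
class ImageStack:
    """A 2-D/3-D grey-value stack with physical pixel geometry.

    ``modality`` tags the acquisition channel: ``bse-inlens`` (secondary
    electron in-lens), ``bse-esb`` (energy-selective backscatter) or ``xray``.
    """

    voxels: np.ndarray  # (slice, row, col) float
    pixel_size_nm: float = 1.0
    slice_thickness_nm: float = 1.0
    modality: str = "bse-esb"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ImageValidationError("stack must be 2-D or 3-D with all dims >= 1")
        if self.pixel_size_nm <= 0 or self.slice_thickness_nm <= 0:
            raise ImageValidationError("pixel sizes must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ImageValidationError("stack contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]


@dataclass
class EnergyStack:
    """An energy-resolved image series: one frame per photon energy (eV)."""

    frames: ImageStack
    energies_eV: np.ndarray
    flat_field: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.energies_eV = np.asarray(self.energies_eV, dtype=float)
        if self.energies_eV.ndim != 1 or len(self.energies_eV) != self.frames.n_frames:
            raise ImageValidationError("need one energy per frame")
        if np.any(self.energies_eV <= 0):
            raise ImageValidationError("energies must be positive")
        if self.flat_field is not None:
            self.flat_field = np.asarray(self.flat_field, dtype=float)
            if self.flat_field.shape != self.frames.voxels.shape[1:]:
                raise ImageValidationError("flat field shape mismatch")

    def frame_at(self, energy_eV: float, tol: float = 0.2) -> tuple[int, np.ndarray]:
        """Index and pixels of the frame nearest ``energy_eV`` (within tol)."""
        idx = int(np.argmin(np.abs(self.energies_eV - energy_eV)))
        if abs(self.energies_eV[idx] - energy_eV) > tol:
            raise ImageValidationError(
                f"no frame within {tol} eV of {energy_eV} eV "
                f"(nearest: {self.energies_eV[idx]} eV)"
            )
        return idx, self.frames.voxels[idx]


@dataclass
class RegionMask:
    voxels: np.ndarray  # boolean, congruent with the target stack
    label: str = "region"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)


@dataclass
class RegionStats:
    mean: float
    sd: float
    count: int


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path, fmt: str | None = None) -> None:
    """Write a stack as multi-page TIFF or MRC, with physical metadata echoed
    into a JSON sidecar (TIFF) or the MRC header."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    meta = {
        "pixel_size_nm": stack.pixel_size_nm,
        "slice_thickness_nm": stack.slice_thickness_nm,
        "modality": stack.modality,
    }
    if fmt in ("tif", "tiff"):
        tifffile.imwrite(path, stack.voxels.astype(np.float32), photometric="minisblack")
        _sidecar(path).write_text(json.dumps(meta))
    elif fmt == "mrc":
        mrcio.write_mrc(
            path,
            stack.voxels,
            (stack.slice_thickness_nm, stack.pixel_size_nm, stack.pixel_size_nm),
        )
        _sidecar(path).write_text(json.dumps(meta))
    else:
        raise ValueError(f"unsupported format {fmt!r} (use tiff or mrc)")


def read_stack(path, fmt: str | None = None) -> ImageStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    if fmt in ("tif", "tiff"):
        try:
            voxels = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - surface the offending file
            raise ImageValidationError(f"cannot parse TIFF {path}: {exc}") from exc
        return ImageStack(
            np.asarray(voxels, dtype=float),
            pixel_size_nm=meta.get("pixel_size_nm", 1.0),
            slice_thickness_nm=meta.get("slice_thickness_nm", 1.0),
            modality=meta.get("modality", "bse-esb"),
        )
    if fmt == "mrc":
        voxels, (vz, vy, vx) = mrcio.read_mrc(path)
        return ImageStack(
            voxels.astype(float),
            pixel_size_nm=meta.get("pixel_size_nm", vx),
            slice_thickness_nm=meta.get("slice_thickness_nm", vz),
            modality=meta.get("modality", "bse-esb"),
        )
    raise ValueError(f"unsupported format {fmt!r} (use tiff or mrc)")


def read_mask(path) -> RegionMask:
    """Read a region mask (8-bit TIFF or MRC); nonzero voxels are True."""
    stack = read_stack(path)
    return RegionMask(stack.voxels != 0, label=Path(path).stem)


def write_mask(mask: RegionMask, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask.voxels.astype(np.uint8), photometric="minisblack")
    else:
        mrcio.write_mrc(path, mask.voxels.astype(np.float32))


# ---------------------------------------------------------------------------
# Optical density
# ---------------------------------------------------------------------------

def to_optical_density(frame: np.ndarray, flat_field: np.ndarray) -> np.ndarray:
    """Flat-field normalization to optical density, OD = -ln(I / I0).

    Pixels where I <= 0 or I0 <= 0 are invalid and returned as NaN rather
    than clamped; region statistics exclude them.
    """
    frame = np.asarray(frame, dtype=float)
    flat_field = np.asarray(flat_field, dtype=float)
    if frame.shape != flat_field.shape:
        raise ImageValidationError(
            f"frame shape {frame.shape} != flat field shape {flat_field.shape}"
        )
    valid = (frame > 0) & (flat_field > 0)
    od = np.full(frame.shape, np.nan)
    od[valid] = -np.log(frame[valid] / flat_field[valid])
    return od


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _apply_shift(frame: np.ndarray, shift: tuple[float, float], wrap: bool) -> np.ndarray:
    if wrap and float(shift[0]).is_integer() and float(shift[1]).is_integer():
        return np.roll(frame, (int(shift[0]), int(shift[1])), axis=(0, 1))
    mode = "grid-wrap" if wrap else "nearest"
    return ndimage.shift(frame, shift, order=1, mode=mode)


def align_translation(
    stack: ImageStack,
    reference: str | int = "middle",
    upsample_factor: int = 1,
    wrap: bool = True,
) -> tuple[ImageStack, np.ndarray]:
    """Translation-only alignment of all frames to a reference frame by phase
    correlation.

    Returns the aligned stack and the per-frame (row, col) shifts that were
    applied; applying those shifts to the input reproduces the output.
    The reference frame defaults to the middle of the stack.
    """
    frames = stack.voxels
    if stack.n_frames < 2:
        raise ImageValidationError("alignment needs at least 2 frames")
    ref_idx = stack.n_frames // 2 if reference == "middle" else int(reference)
    ref = frames[ref_idx]
    aligned = np.empty_like(frames)
    shifts = np.zeros((stack.n_frames, 2))
    for i, frame in enumerate(frames):
        if i == ref_idx:
            aligned[i] = frame
            continue
        if np.ptp(frame) == 0 or np.ptp(ref) == 0:
            warnings.warn("featureless frame: assuming zero shift", stacklevel=2)
            aligned[i] = frame
            continue
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None
        )
        shifts[i] = shift
        aligned[i] = _apply_shift(frame, tuple(shift), wrap)
    out = ImageStack(
        aligned,
        pixel_size_nm=stack.pixel_size_nm,
        slice_thickness_nm=stack.slice_thickness_nm,
        modality=stack.modality,
    )
    return out, shifts


def apply_shifts(stack: ImageStack, shifts: np.ndarray, wrap: bool = True) -> ImageStack:
    """Apply previously measured per-frame shifts to a paired stack (e.g. the
    in-lens channel follows the EsB channel's alignment)."""
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (stack.n_frames, 2):
        raise ImageValidationError("one (row, col) shift per frame required")
    aligned = np.stack(
        [_apply_shift(f, tuple(s), wrap) for f, s in zip(stack.voxels, shifts)]
    )
    return ImageStack(
        aligned,
        pixel_size_nm=stack.pixel_size_nm,
        slice_thickness_nm=stack.slice_thickness_nm,
        modality=stack.modality,
    )


# ---------------------------------------------------------------------------
# Destriping
# ---------------------------------------------------------------------------

def destripe_vertical(
    frame: np.ndarray, notch_halfwidth: int = 1, protect_bins: int = 2
) -> np.ndarray:
    """Remove vertical stripe artifacts (FIB 'waterfall' curtaining) by a
    Fourier notch.

    Vertical stripes (grey depending on the column only) concentrate their
    energy on the zero-row-frequency line of the 2-D spectrum; that line is
    suppressed within ``notch_halfwidth`` row-frequency bins.  The lowest
    ``protect_bins`` column frequencies (and DC) are left untouched so wide
    genuine structure and the mean grey level are preserved.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ImageValidationError("destriping expects a 2-D frame")
    spec = np.fft.fft2(frame)
    nrows, ncols = frame.shape
    for r in range(-notch_halfwidth, notch_halfwidth + 1):
        line = spec[r % nrows].copy()
        line[protect_bins + 1 : ncols - protect_bins] = 0.0
        spec[r % nrows] = line
    return np.real(np.fft.ifft2(spec))


# ---------------------------------------------------------------------------
# Region statistics
# ---------------------------------------------------------------------------

def region_stats(voxels: np.ndarray | ImageStack, mask: RegionMask | np.ndarray) -> RegionStats:
    """Mean, population s.d. and voxel count over a masked region.

    NaN voxels (e.g. invalid OD pixels) are excluded from the statistics.
    """
    if isinstance(voxels, ImageStack):
        voxels = voxels.voxels
    m = mask.voxels if isinstance(mask, RegionMask) else np.asarray(mask, dtype=bool)
    voxels = np.asarray(voxels, dtype=float)
    if voxels.shape != m.shape:
        raise ImageValidationError(
            f"mask shape {m.shape} does not match data shape {voxels.shape}"
        )
    values = voxels[m]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ImageValidationError("empty region mask (or all pixels invalid)")
    return RegionStats(float(values.mean()), float(values.std()), int(values.size))
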