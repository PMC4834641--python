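"""Resolution estimation by Fourier shell correlation (FSC).

Two independent half-volumes (e.g. reconstructions from even and odd
projections) are correlated shell-by-shell in Fourier space; the spatial
frequency where the correlation first drops below a threshold (0.25 here by
default) defines the resolution, reported as half pitch = 1 / (2 f_c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class FSCError(ValueError):
    pass


@dataclass
class FSCCurve:
    shell_freqs: np.ndarray  # 1/nm, shell centers
    correlation: np.ndarray  # in [-1, 1]
    voxel_size_nm: float
    shell_counts: np.ndarray | None = None  # Fourier voxels per shell

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.voxel_size_nm)


@dataclass
class ResolutionEstimate:
    resolution_nm: float  # half pitch
    crossing_freq: float  # 1/nm
    threshold: float
    nyquist_limited: bool = False


def fsc(vol_a: np.ndarray, vol_b: np.ndarray, voxel_size_nm: float = 1.0,
        n_shells: int | None = None) -> FSCCurve:
    """Per-shell normalized cross-correlation of Fourier coefficients:
    Re<F_a conj(F_b)> / sqrt(<|F_a|^2><|F_b|^2>).
    """
    a = np.asarray(vol_a, dtype=float)
    b = np.asarray(vol_b, dtype=float)
    if a.shape != b.shape:
        raise FSCError(f"volume shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 3:
        raise FSCError("FSC expects 3-D volumes")
    if len(set(a.shape)) != 1:
        # pad to cubic so shells are spherical
        n = max(a.shape)
        pad = [(0, n - s) for s in a.shape]
        a = np.pad(a, pad)
        b = np.pad(b, pad)
    n = a.shape[0]
    if n_shells is None:
        n_shells = n // 2

    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    freqs = np.fft.fftfreq(n)  # cycles per voxel
    fz, fy, fx = np.meshgrid(freqs, freqs, freqs, indexing="ij")
    radius = np.sqrt(fz**2 + fy**2 + fx**2)  # in cycles/voxel, max ~0.866
    # shells cover [0, 0.5] cycles/voxel (Nyquist)
    bins = np.minimum((radius / 0.5 * n_shells).astype(int), n_shells)
    valid = bins < n_shells

    num = np.bincount(bins[valid], weights=np.real(fa * np.conj(fb))[valid],
                      minlength=n_shells)
    den_a = np.bincount(bins[valid], weights=(np.abs(fa) ** 2)[valid], minlength=n_shells)
    den_b = np.bincount(bins[valid], weights=(np.abs(fb) ** 2)[valid], minlength=n_shells)
    counts = np.bincount(bins[valid], minlength=n_shells)

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / np.sqrt(den_a * den_b)
    corr = np.where(counts > 0, np.nan_to_num(corr), 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    # shell center frequencies in 1/nm
    shell_freqs = (np.arange(n_shells) + 0.5) / n_shells * 0.5 / voxel_size_nm
    return FSCCurve(shell_freqs, corr, voxel_size_nm, counts)


def resolution_at_threshold(curve: FSCCurve, threshold: float = 0.25) -> ResolutionEstimate:
    """Half-pitch resolution from the first threshold crossing.

    The crossing frequency f_c is located by linear interpolation between the
    bracketing shells; resolution = 1 / (2 f_c).  If the curve never drops
    below the threshold the Nyquist-limited value (2 * voxel size) is
    returned, flagged.
    """
    c = curve.correlation
    f = curve.shell_freqs
    below = np.nonzero(c < threshold)[0]
    below = below[below > 0]  # ignore the DC shell
    if below.size == 0:
        return ResolutionEstimate(
            2.0 * curve.voxel_size_nm, curve.nyquist, threshold, nyquist_limited=True
        )
    i = int(below[0])
    f0, f1 = f[i - 1], f[i]
    c0, c1 = c[i - 1], c[i]
    if c0 == c1:
        fc = f1
    else:
        fc = f0 + (c0 - threshold) * (f1 - f0) / (c0 - c1)
    return ResolutionEstimate(1.0 / (2.0 * fc), float(fc), threshold)
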