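"""Ca K-edge XANES preprocessing and linear-combination fitting.

Workflow: average repeat scans, locate the absorption edge E0 (maximum of the
third peak of the first derivative — the pre-edge features of Ca K-edge
spectra contribute the first two derivative peaks), normalize with a linear
pre-edge and quadratic post-edge, then express a cell spectrum as a convex
combination of reference standards (free Ca ions, amorphous calcium
carbonate, calcite).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import nnls
from scipy.signal import find_peaks, savgol_filter


class SpectrumError(ValueError):
    pass


@dataclass
class Spectrum:
    """A 1-D absorption spectrum (energy in eV vs intensity) with a
    preprocessing state flag (raw | averaged | normalized)."""

    energies_eV: np.ndarray
    intensity: np.ndarray
    state: str = "raw"
    e0: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.energies_eV = np.asarray(self.energies_eV, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.energies_eV.shape != self.intensity.shape or self.energies_eV.ndim != 1:
            raise SpectrumError("energy and intensity must be 1-D and equal length")
        if np.any(np.diff(self.energies_eV) <= 0):
            raise SpectrumError("energies must be strictly increasing")

    def interp(self, energies_eV: np.ndarray) -> np.ndarray:
        return np.interp(energies_eV, self.energies_eV, self.intensity)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["energy_eV", "intensity"])
            for e, i in zip(self.energies_eV, self.intensity):
                w.writerow([f"{e:.6g}", f"{i:.8g}"])

    @classmethod
    def from_csv(cls, path, state: str = "raw") -> "Spectrum":
        e, i = [], []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if len(header) < 2:
                raise SpectrumError(f"{path}: expected 2-column CSV")
            for row in reader:
                e.append(float(row[0]))
                i.append(float(row[1]))
        return cls(np.array(e), np.array(i), state=state, label=Path(path).stem)


@dataclass
class LCFResult:
    """Weights of a constrained linear-combination fit."""

    weights: dict[str, float]
    residual: float  # sum of squared misfit over the fit window
    nonneg: bool = True
    sum_to_one: bool = True
    window_eV: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.nonneg and any(w < -1e-12 for w in self.weights.values()):
            raise SpectrumError("negative weight under non-negativity constraint")
        if self.sum_to_one and abs(sum(self.weights.values()) - 1.0) > 1e-6:
            raise SpectrumError("weights do not sum to 1 under simplex constraint")


def average_scans(spectra: list[Spectrum], interpolate: bool = False) -> Spectrum:
    """Pointwise mean of repeat scans (signal-to-noise improvement).

    Without ``interpolate`` all scans must share the energy grid; with it,
    scans are linearly interpolated onto the first scan's grid.
    """
    if not spectra:
        raise SpectrumError("need at least one spectrum")
    grid = spectra[0].energies_eV
    rows = []
    for s in spectra:
        if s.energies_eV.shape == grid.shape and np.allclose(s.energies_eV, grid):
            rows.append(s.intensity)
        elif interpolate:
            rows.append(s.interp(grid))
        else:
            raise SpectrumError("incompatible energy grids (pass interpolate=True)")
    return Spectrum(grid.copy(), np.mean(rows, axis=0), state="averaged",
                    label=spectra[0].label)


def find_edge(
    spectrum: Spectrum,
    smooth_width_eV: float = 1.0,
    prominence_frac: float = 0.05,
) -> float:
    """Edge energy E0 = position of the third peak of the first derivative.

    The derivative is smoothed with a local quadratic (Savitzky-Golay) filter
    of width ``smooth_width_eV``; peaks must have prominence >= 5% of the
    derivative range.  With fewer than three peaks the global derivative
    maximum is used (with a warning).
    """
    e, mu = spectrum.energies_eV, spectrum.intensity
    step = float(np.median(np.diff(e)))
    win = max(int(round(smooth_width_eV / step)) | 1, 5)  # odd, >= 5 points
    if win >= len(e):
        win = (len(e) - 1) | 1
    deriv = savgol_filter(mu, win, polyorder=2, deriv=1, delta=step)
    prominence = prominence_frac * float(np.ptp(deriv))
    peaks, _ = find_peaks(deriv, prominence=prominence)
    if len(peaks) >= 3:
        return float(e[peaks[2]])
    warnings.warn(
        f"only {len(peaks)} derivative peaks found; falling back to the global "
        "derivative maximum",
        stacklevel=2,
    )
    return float(e[int(np.argmax(deriv))])


def normalize(
    spectrum: Spectrum,
    e0: float | None = None,
    pre_edge_eV: tuple[float, float] = (25.0, 13.0),
    post_edge_eV: tuple[float, float] = (26.0, 90.0),
) -> Spectrum:
    """Edge-step normalization.

    A line is fit over [E0 - 25, E0 - 13] eV and a quadratic over
    [E0 + 26, E0 + 90] eV; the pre-edge line is subtracted and the intensity
    divided by the edge step (post-edge polynomial minus pre-edge line,
    evaluated at E0), leaving the post-edge fluctuating about 1.  The output
    is invariant to affine transforms of the raw intensity.
    """
    if e0 is None:
        e0 = spectrum.e0 if spectrum.e0 is not None else find_edge(spectrum)
    e, mu = spectrum.energies_eV, spectrum.intensity
    for name, (lo, hi) in (
        ("pre-edge", (e0 - pre_edge_eV[0], e0 - pre_edge_eV[1])),
        ("post-edge", (e0 + post_edge_eV[0], e0 + post_edge_eV[1])),
    ):
        if e[0] > lo + 1e-9 or e[-1] < hi - 1e-9:
            raise SpectrumError(
                f"spectrum [{e[0]:.1f}, {e[-1]:.1f}] eV does not span the "
                f"{name} window [{lo:.1f}, {hi:.1f}] eV"
            )
    pre = (e >= e0 - pre_edge_eV[0]) & (e <= e0 - pre_edge_eV[1])
    post = (e >= e0 + post_edge_eV[0]) & (e <= e0 + post_edge_eV[1])
    if pre.sum() < 2 or post.sum() < 3:
        raise SpectrumError("too few points in the normalization windows")
    pre_line = np.poly1d(np.polyfit(e[pre], mu[pre], 1))
    post_poly = np.poly1d(np.polyfit(e[post], mu[post], 2))
    step = post_poly(e0) - pre_line(e0)
    if step <= 0:
        raise SpectrumError("non-positive edge step; not an absorption edge?")
    norm = (mu - pre_line(e)) / step
    return replace(spectrum, intensity=norm, state="normalized", e0=float(e0))


def lcf(
    target: Spectrum,
    references: list[Spectrum],
    window_eV: tuple[float, float] | None = None,
    nonneg: bool = True,
    sum_to_one: bool = True,
) -> LCFResult:
    """Constrained linear-combination fit of a target onto reference spectra.

    Weights minimize the squared misfit over the window subject to w_i >= 0
    and sum w_i = 1 (both on by default; the sum constraint is imposed as a
    heavily weighted extra equation on the non-negative solver).  The default
    window is [E0 - 20, E0 + 60] eV around the target's edge.
    """
    if len(references) < 2:
        raise SpectrumError("need at least 2 references")
    for s in (target, *references):
        if s.state != "normalized":
            raise SpectrumError(f"spectrum {s.label!r} is not normalized")
    if window_eV is None:
        e0 = target.e0
        if e0 is None:
            lo = max(s.energies_eV[0] for s in (target, *references))
            hi = min(s.energies_eV[-1] for s in (target, *references))
            window_eV = (lo, hi)
        else:
            window_eV = (e0 - 20.0, e0 + 60.0)
    sel = (target.energies_eV >= window_eV[0]) & (target.energies_eV <= window_eV[1])
    if sel.sum() < len(references) + 1:
        raise SpectrumError("fit window contains too few points")
    grid = target.energies_eV[sel]
    y = target.intensity[sel]
    A = np.column_stack([r.interp(grid) for r in references])
    if np.linalg.matrix_rank(A, tol=1e-8 * np.linalg.norm(A)) < A.shape[1]:
        warnings.warn("reference set is ill-conditioned (near-identical spectra)",
                      stacklevel=2)

    if nonneg and sum_to_one:
        lam = 1e6 * max(np.abs(y).max(), 1.0)
        A_aug = np.vstack([A, lam * np.ones(A.shape[1])])
        y_aug = np.append(y, lam)
        w, _ = nnls(A_aug, y_aug)
        w = w / w.sum() if w.sum() > 0 else w
    elif nonneg:
        w, _ = nnls(A, y)
    elif sum_to_one:
        # eliminate the constraint: w_n = 1 - sum(w_1..n-1)
        base = A[:, -1]
        B = A[:, :-1] - base[:, None]
        coef, *_ = np.linalg.lstsq(B, y - base, rcond=None)
        w = np.append(coef, 1.0 - coef.sum())
    else:
        w, *_ = np.linalg.lstsq(A, y, rcond=None)

    residual = float(np.sum((y - A @ w) ** 2))
    names = []
    for i, r in enumerate(references):
        name = r.label or f"ref{i}"
        if name in names:  # duplicate labels must not collapse in the dict
            name = f"{name}_{i}"
        names.append(name)
    return LCFResult(
        dict(zip(names, (float(v) for v in w))),
        residual,
        nonneg=nonneg,
        sum_to_one=sum_to_one,
        window_eV=(float(window_eV[0]), float(window_eV[1])),
    )


def compare_reference_sets(
    target: Spectrum,
    sets: list[list[Spectrum]],
    window_eV: tuple[float, float] | None = None,
    tie_tol: float = 1e-8,
    **kwargs,
) -> list[tuple[list[Spectrum], LCFResult]]:
    """Fit the target with each candidate reference set and rank by residual
    (ascending); residual ties within ``tie_tol`` prefer the smaller set."""
    fits = [(refs, lcf(target, refs, window_eV=window_eV, **kwargs)) for refs in sets]
    return sorted(fits, key=lambda fr: (int(fr[1].residual / tie_tol), len(fr[0])))


def scan_difference(scan_a: Spectrum, scan_b: Spectrum) -> float:
    """Maximum absolute intensity difference between two repeat scans — the
    radiation-damage check (a repeated scan should reproduce the first)."""
    if not np.allclose(scan_a.energies_eV, scan_b.energies_eV):
        raise SpectrumError("scans must share the energy grid")
    return float(np.max(np.abs(scan_a.intensity - scan_b.intensity)))
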