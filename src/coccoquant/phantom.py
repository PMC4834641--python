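"""Ground-truthed synthetic phantoms for every pipeline stage.

A labelled 3-D cell (medium, cytoplasm, nucleus, chloroplast, lipid bodies,
a coccolith, a concentrated Ca-P body and an optional dilute Ca cloud) is
rendered forward into

* EsB-like backscatter slice stacks (grey affine in the effective
  backscatter coefficient, Gaussian noise),
* soft X-ray energy stacks obeying Beer-Lambert absorption with a
  phenomenological Ca L-edge (arctan continuum step + white lines; the
  calcite crystal-field peaks at 347.9/351.3 eV appear only for crystalline
  labels),
* Ca K-edge XANES spectra as noisy convex mixtures of three reference
  end-members (calcite-like, ACC-like, free-ion-like).

Every render is deterministic under a fixed seed, so each quantification
stage can be validated by closed-loop parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_core import EnergyStack, ImageStack
from .materials import (
    ElectrolyteModel,
    Material,
    build_electrolyte,
    ca_mass_fraction_for_molarity,
    calcite,
    calcite_ca_molarity,
    eta_eff,
    lipid,
    seawater_medium,
    water,
)
from .xanes import Spectrum


class PhantomConfigError(ValueError):
    pass


LABEL_NAMES = {
    0: "medium",
    1: "cytoplasm",
    2: "nucleus",
    3: "chloroplast",
    4: "lipid",
    5: "coccolith",
    6: "ca_body",
    7: "cloud",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}


@dataclass
class PhantomConfig:
    """Cell geometry (voxel units, axis order slice/row/col), planted
    concentrations and render noise levels.

    Defaults plant the measured regimes: a Ca-P body at 10 M occupying
    1.5 um^3, a dilute cloud at 1.5 M, and calcite coccolith material at its
    intrinsic ~27 M.  The default geometry is laid out for the default
    ``shape``; all positions are validated (inside the cell, pairwise
    disjoint) at build time.
    """

    shape: tuple[int, int, int] = (64, 96, 96)
    voxel_size_nm: float = 40.0
    seed: int = 0

    body_molarity_M: float = 10.0
    body_volume_um3: float = 1.5
    cloud_molarity_M: float = 1.5
    include_cloud: bool = True

    cell_semi_axes: tuple[float, float, float] = (28.0, 44.0, 44.0)
    nucleus_center: tuple[float, float, float] = (32.0, 72.0, 66.0)
    nucleus_radius: float = 10.0
    chloroplast_center: tuple[float, float, float] = (32.0, 82.0, 40.0)
    chloroplast_semi_axes: tuple[float, float, float] = (12.0, 5.0, 14.0)
    lipid_centers: tuple[tuple[float, float, float], ...] = ((32.0, 44.0, 80.0), (14.0, 48.0, 44.0))
    lipid_radii: tuple[float, ...] = (6.0, 5.0)
    coccolith_center: tuple[float, float, float] = (32.0, 28.0, 64.0)
    coccolith_outer_radius: float = 10.0
    coccolith_inner_radius: float = 5.0
    coccolith_half_thickness: float = 3.0
    body_center: tuple[float, float, float] = (32.0, 60.0, 30.0)
    cloud_center: tuple[float, float, float] = (40.0, 26.0, 26.0)
    cloud_radius: float = 8.0

    electrolyte: ElectrolyteModel = field(default_factory=ElectrolyteModel)

    def __post_init__(self) -> None:
        if min(self.shape) < 8 or self.voxel_size_nm <= 0:
            raise PhantomConfigError("invalid grid geometry")
        if self.body_molarity_M < 0 or self.cloud_molarity_M < 0:
            raise PhantomConfigError("molarities must be >= 0")
        if self.body_volume_um3 <= 0:
            raise PhantomConfigError("body volume must be positive")


@dataclass
class LabelVolume:
    labels: np.ndarray  # int labels, (slice, row, col)
    voxel_size_nm: float
    names: dict[int, str] = field(default_factory=lambda: dict(LABEL_NAMES))

    def mask(self, label: int | str) -> np.ndarray:
        if isinstance(label, str):
            label = NAME_TO_LABEL[label]
        return self.labels == label


@dataclass
class GroundTruth:
    volume: LabelVolume
    materials: dict[int, Material]
    molarity: dict[int, float]  # Ca mol/L per label
    crystalline: dict[int, bool]
    config: PhantomConfig

    def mask(self, label: int | str) -> np.ndarray:
        return self.volume.mask(label)


def _coords(shape):
    return np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")


def _sphere(shape, center, radius):
    z, y, x = _coords(shape)
    return (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2 <= radius**2


def _ellipsoid(shape, center, semi):
    z, y, x = _coords(shape)
    return (
        ((z - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((x - center[2]) / semi[2]) ** 2
    ) <= 1.0


def make_cell_phantom(config: PhantomConfig | None = None) -> tuple[LabelVolume, GroundTruth]:
    """Build the labelled cell volume and its ground truth.

    The Ca-P body is constructed from the N grid voxels nearest its centre,
    with N chosen so the discretized volume matches ``body_volume_um3`` to
    within half a voxel.  Mandatory organelles may only replace cytoplasm;
    any overlap or protrusion outside the cell raises a config error.
    """
    config = config or PhantomConfig()
    shape = config.shape
    center = tuple(s / 2.0 for s in shape)
    labels = np.zeros(shape, dtype=np.int16)

    cell = _ellipsoid(shape, center, config.cell_semi_axes)
    labels[cell] = NAME_TO_LABEL["cytoplasm"]

    def paint(mask: np.ndarray, name: str) -> None:
        if not mask.any():
            raise PhantomConfigError(f"{name} mask is empty")
        clashes = labels[mask]
        bad = clashes != NAME_TO_LABEL["cytoplasm"]
        if bad.any():
            hit = LABEL_NAMES[int(clashes[bad][0])]
            raise PhantomConfigError(f"{name} overlaps {hit} or leaves the cell")
        labels[mask] = NAME_TO_LABEL[name]

    paint(_sphere(shape, config.nucleus_center, config.nucleus_radius), "nucleus")
    paint(_ellipsoid(shape, config.chloroplast_center, config.chloroplast_semi_axes), "chloroplast")
    for c, r in zip(config.lipid_centers, config.lipid_radii):
        paint(_sphere(shape, c, r), "lipid")

    z, y, x = _coords(shape)
    cz, cy, cx = config.coccolith_center
    lateral = np.sqrt((y - cy) ** 2 + (x - cx) ** 2)
    ring = (
        (lateral <= config.coccolith_outer_radius)
        & (lateral >= config.coccolith_inner_radius)
        & (np.abs(z - cz) <= config.coccolith_half_thickness)
    )
    paint(ring, "coccolith")

    # body: the N nearest voxels to the body centre, N from the target volume
    voxel_um3 = (config.voxel_size_nm * 1e-3) ** 3
    n_body = int(round(config.body_volume_um3 / voxel_um3))
    bz, by, bx = config.body_center
    dist2 = (z - bz) ** 2 + (y - by) ** 2 + (x - bx) ** 2
    order = np.argpartition(dist2.ravel(), n_body)[:n_body]
    body = np.zeros(shape, dtype=bool)
    body.ravel()[order] = True
    paint(body, "ca_body")

    if config.include_cloud:
        paint(_sphere(shape, config.cloud_center, config.cloud_radius), "cloud")

    w_body = ca_mass_fraction_for_molarity(config.body_molarity_M, config.electrolyte)
    w_cloud = ca_mass_fraction_for_molarity(config.cloud_molarity_M, config.electrolyte)
    materials = {
        0: seawater_medium(),
        1: Material.from_components("cytoplasm", {"H2O": 0.80, "C5H7NO2": 0.20}),
        2: Material.from_components("nucleoplasm", {"H2O": 0.75, "C5H7NO2": 0.25}),
        3: Material.from_components("chloroplast", {"H2O": 0.70, "C5H7NO2": 0.30}),
        4: lipid(),
        5: calcite(),
        6: build_electrolyte(w_body, config.electrolyte) if w_body > 0 else water(),
        7: build_electrolyte(w_cloud, config.electrolyte) if w_cloud > 0 else water(),
    }
    molarity = {
        0: 0.01,  # 10 mM CaCl2 medium
        1: 0.0,
        2: 0.0,
        3: 0.0,
        4: 0.0,
        5: calcite_ca_molarity(),
        6: config.body_molarity_M,
        7: config.cloud_molarity_M if config.include_cloud else 0.0,
    }
    crystalline = {k: (k == 5) for k in LABEL_NAMES}
    volume = LabelVolume(labels, config.voxel_size_nm)
    return volume, GroundTruth(volume, materials, molarity, crystalline, config)


# ---------------------------------------------------------------------------
# BSE forward model
# ---------------------------------------------------------------------------

def eta_map(truth: GroundTruth) -> np.ndarray:
    """Per-voxel effective backscatter coefficient."""
    lut = np.zeros(max(LABEL_NAMES) + 1)
    for lab, mat in truth.materials.items():
        lut[lab] = eta_eff(mat)
    return lut[truth.volume.labels]


def grey_span(truth: GroundTruth, gain: float) -> float:
    """Grey dynamic range between the least and most backscattering phantom
    materials; reference scale for relative noise levels."""
    etas = [eta_eff(m) for m in truth.materials.values()]
    return abs(gain) * (max(etas) - min(etas))


def render_bse(
    truth: GroundTruth,
    gain: float = 1000.0,
    offset: float = 100.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[ImageStack, ImageStack]:
    """Render the EsB and in-lens channels of a FIB-SEM series.

    EsB grey is affine in the effective backscatter coefficient per voxel
    plus Gaussian noise.  The in-lens channel (qualitative only) renders the
    same contrast at reduced gain with label boundaries darkened, mimicking
    membranes.
    """
    if gain == 0:
        raise PhantomConfigError("gain must be nonzero")
    rng = np.random.default_rng(seed)
    eta = eta_map(truth)
    esb = gain * eta + offset
    if noise_sd > 0:
        esb = esb + rng.normal(0.0, noise_sd, size=esb.shape)
    labels = truth.volume.labels
    boundary = np.zeros(labels.shape, dtype=bool)
    for ax in (1, 2):
        boundary |= np.roll(labels, 1, axis=ax) != labels
    inlens = 0.5 * gain * eta + offset
    inlens[boundary] *= 0.6
    if noise_sd > 0:
        inlens = inlens + rng.normal(0.0, noise_sd, size=inlens.shape)
    px = truth.volume.voxel_size_nm
    return (
        ImageStack(esb, pixel_size_nm=px, slice_thickness_nm=px, modality="bse-esb"),
        ImageStack(inlens, pixel_size_nm=px, slice_thickness_nm=px, modality="bse-inlens"),
    )


# ---------------------------------------------------------------------------
# Soft X-ray forward model (Ca L-edge)
# ---------------------------------------------------------------------------

#: Phenomenological per-molar Ca absorbance at the L2,3-edge, nm^-1 M^-1:
#: continuum step + L3/L2 white lines; crystal-field satellites only for
#: crystalline phases.  Self-consistent with the quantification, which uses
#: only the 353.2 - 342 eV difference (identical for both phases).
L_EDGE = {
    "step_amp": 8.0e-5,
    "step_center": 349.0,
    "step_width": 0.4,
    "l3_amp": 6.0e-5,
    "l3_center": 349.3,
    "l2_amp": 5.0e-5,
    "l2_center": 353.2,
    "line_sigma": 0.35,
    "cf_amp": 2.5e-5,
    "cf_sigma": 0.30,
    "cf_centers": (347.9, 351.3),
    "cf_rel": (1.0, 0.6),
}

#: Energy-independent background absorbance per label (organic/water matrix),
#: nm^-1.  Cancels exactly in the L-edge difference map.
BACKGROUND_MU = {
    0: 1.6e-4,
    1: 2.0e-4,
    2: 2.2e-4,
    3: 2.4e-4,
    4: 3.0e-4,
    5: 2.0e-4,
    6: 2.0e-4,
    7: 1.9e-4,
}


def _gauss(e, center, sigma):
    return np.exp(-0.5 * ((e - center) / sigma) ** 2)


def ca_edge_kappa(energies_eV: np.ndarray, crystalline: bool) -> np.ndarray:
    """Per-molar Ca absorbance (nm^-1 M^-1) across the L2,3-edge."""
    e = np.asarray(energies_eV, dtype=float)
    p = L_EDGE
    k = p["step_amp"] * (0.5 + np.arctan((e - p["step_center"]) / p["step_width"]) / np.pi)
    k = k + p["l3_amp"] * _gauss(e, p["l3_center"], p["line_sigma"])
    k = k + p["l2_amp"] * _gauss(e, p["l2_center"], p["line_sigma"])
    if crystalline:
        for c, rel in zip(p["cf_centers"], p["cf_rel"]):
            k = k + rel * p["cf_amp"] * _gauss(e, c, p["cf_sigma"])
    return k


def render_xray(
    truth: GroundTruth,
    energies_eV: np.ndarray,
    flux: float = 2000.0,
    noise_model: str | None = "poisson",
    seed: int | None = None,
    jitter_px: int = 0,
    tilt_deg: float = 0.0,
    axis: int = 0,
) -> EnergyStack:
    """Beer-Lambert transmission images across the Ca L-edge.

    I(pixel, E) = I0 * exp(-sum_path mu(material, E) dl) with
    mu = background + molarity * kappa(E).  ``jitter_px`` adds random integer
    per-frame translations (the first frame stays fixed as the alignment
    reference); ``tilt_deg`` rotates the volume about the row axis before
    projecting along ``axis``.  Noise is Poisson (photon counting) or
    Gaussian (sd = sqrt(flux)); the flat field is returned noise-free.
    """
    energies = np.asarray(energies_eV, dtype=float)
    if np.any(energies < 330.0) or np.any(energies > 360.0):
        raise PhantomConfigError("energies outside the L-edge model validity (330-360 eV)")
    rng = np.random.default_rng(seed)
    labels = truth.volume.labels
    if tilt_deg != 0.0:
        labels = ndimage.rotate(
            labels, tilt_deg, axes=(0, 2), reshape=False, order=0, mode="constant", cval=0
        )
    voxel = truth.volume.voxel_size_nm

    # path length per label (nm), then OD(E) as a per-label weighted sum
    path = {lab: (labels == lab).sum(axis=axis) * voxel for lab in LABEL_NAMES}
    od_bg = sum(BACKGROUND_MU[lab] * path[lab] for lab in LABEL_NAMES)
    frames = np.empty((len(energies),) + od_bg.shape)
    kappa = {
        lab: ca_edge_kappa(energies, truth.crystalline[lab]) * truth.molarity.get(lab, 0.0)
        for lab in LABEL_NAMES
        if truth.molarity.get(lab, 0.0) > 0
    }
    for i, _e in enumerate(energies):
        od = od_bg + sum(k[i] * path[lab] for lab, k in kappa.items())
        frames[i] = flux * np.exp(-od)

    if jitter_px > 0:
        for i in range(1, len(energies)):
            dz = rng.integers(-jitter_px, jitter_px + 1, size=2)
            frames[i] = np.roll(frames[i], tuple(dz), axis=(0, 1))
    if noise_model == "poisson":
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    elif noise_model == "gaussian":
        frames = frames + rng.normal(0.0, np.sqrt(flux), size=frames.shape)
    elif noise_model is not None:
        raise PhantomConfigError(f"unknown noise model {noise_model!r}")

    stack = ImageStack(frames, pixel_size_nm=voxel, slice_thickness_nm=voxel, modality="xray")
    flat = np.full(od_bg.shape, flux)
    return EnergyStack(stack, energies, flat_field=flat)


def l_edge_scan_energies(
    start: float = 347.7, stop: float = 354.7, step: float = 0.15, below_edge: float = 342.0
) -> np.ndarray:
    """Default energy list: one below-edge frame plus the fine L-edge scan."""
    scan = np.arange(start, stop + 1e-9, step)
    return np.concatenate([[below_edge], scan])


# ---------------------------------------------------------------------------
# Ca K-edge XANES mixtures
# ---------------------------------------------------------------------------

K_EDGE_E0 = 4048.0


def _kedge_grid() -> np.ndarray:
    return np.arange(4000.0, 4140.0 + 1e-9, 0.25)


def kedge_reference_spectra() -> list[Spectrum]:
    """Three fixed, normalized K-edge end-members: calcite-like, ACC-like and
    free-ion-like (dilute CaCl2).  Shapes are parameterized curves — arctan
    edge at 4048 eV, phase-specific white lines and post-edge oscillations —
    not beamline data."""
    e = _kedge_grid()
    rel = e - K_EDGE_E0
    post = np.where(rel > 0, rel, 0.0)

    def edge(width):
        return 0.5 + np.arctan(rel / width) / np.pi

    pre_bumps = 0.030 * _gauss(e, 4040.3, 0.8) + 0.040 * _gauss(e, 4044.0, 0.9)

    calcite_like = (
        edge(0.8)
        + pre_bumps
        + 1.10 * _gauss(e, 4052.0, 1.2)
        + 0.25 * _gauss(e, 4060.0, 1.5)
        + 0.12 * np.sin(2 * np.pi * post / 16.0) * np.exp(-post / 70.0)
    )
    acc_like = (
        edge(1.6)
        + pre_bumps
        + 0.90 * _gauss(e, 4051.0, 2.6)
        + 0.05 * np.sin(2 * np.pi * post / 24.0) * np.exp(-post / 60.0)
    )
    ion_like = edge(2.0) + pre_bumps + 1.05 * _gauss(e, 4050.0, 3.6)

    return [
        Spectrum(e, calcite_like, state="normalized", e0=K_EDGE_E0, label="calcite"),
        Spectrum(e, acc_like, state="normalized", e0=K_EDGE_E0, label="acc"),
        Spectrum(e, ion_like, state="normalized", e0=K_EDGE_E0, label="free_ion"),
    ]


def synth_kedge_mixture(
    weights: dict[str, float] | tuple[float, float, float],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[Spectrum, list[Spectrum]]:
    """Noisy convex mixture of the K-edge end-members plus the references.

    ``weights`` maps {calcite, acc, free_ion} (or is an ordered triple) and
    must lie on the simplex.
    """
    refs = kedge_reference_spectra()
    if not isinstance(weights, dict):
        weights = dict(zip([r.label for r in refs], weights))
    w = np.array([weights.get(r.label, 0.0) for r in refs])
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise PhantomConfigError(f"weights must lie on the simplex, got {weights}")
    rng = np.random.default_rng(seed)
    mix = sum(wi * r.intensity for wi, r in zip(w, refs))
    if noise_sd > 0:
        mix = mix + rng.normal(0.0, noise_sd, size=mix.shape)
    target = Spectrum(
        refs[0].energies_eV.copy(), mix, state="normalized", e0=K_EDGE_E0, label="mixture"
    )
    return target, refs
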