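# Methods

This note documents the models behind each quantification stage, the
parameters that matter, what the synthetic phantoms do and do not emulate,
and the numerical choices made where the design was open.

## Backscatter quantification (EsB channel)

**Model.** The energy-selective backscattered electron signal is assumed
affine in the effective backscatter coefficient of the material in the
interaction volume: grey = a·η_eff + b. η_eff follows the mixture rule
η_eff = Σᵢ ηᵢcᵢ over elemental *weight* fractions cᵢ; there is
deliberately no mole-fraction API. Atomic coefficients come from the
empirical Heinrich cubic

    η(Z) = −0.0254 + 0.016 Z − 1.86·10⁻⁴ Z² + 8.3·10⁻⁷ Z³,

treated as beam-energy independent — a good approximation for the light
elements (Z < 20) that dominate biological matrices, and adequate at
Z = 20 (Ca). The cubic extrapolates slightly negative at Z = 1, so values
are floored at 10⁻⁴; this keeps η ∈ (0, 1) and strictly increasing over
Z = 1…92. The coefficients are module constants and can be swapped for an
alternative fit. A linear detector response is assumed throughout.

**Calibration.** a and b are fit by least squares to internal standards —
regions of known composition *in the same stack*: lipid bodies (linear
hydrocarbon, CH₂), the artificial seawater medium, and coccolith calcite.
With two standards the line is exact; the API enforces same-stack
measurement because inter-acquisition gain drift would otherwise silently
bias the inversion.

**Inversion.** A body's mean grey maps to η_eff through the line, and
η_eff maps to concentration under an electrolyte model: a solution with a
fixed Ca:P atomic ratio (default 1:2) of Ca ions and metaphosphate (PO₃)
chain units — a calcium-polyphosphate-like pool — with water filling the
remainder. η_eff is strictly monotone in the Ca weight fraction, so the
inverse is found by bracketed root finding (`brentq`, xtol 10⁻⁹ in weight
fraction; unconditionally robust, no derivatives needed). Below pure-water
η the estimate saturates at 0 M with a warning; above the most
concentrated consistent solution (w_Ca ≈ 0.202, ≈ 23.3 M) a range error is
raised. The weight fraction converts to mol/L through the harmonic
density-mixing rule 1/ρ_s = Σᵢ cᵢ/ρᵢ with ion densities modelled as
sphere-packing densities from tabulated ionic radii (Shannon radii for
simple ions; an effective 200 pm radius for the PO₃ unit, since no Shannon
value exists for molecular anions — both are data files and overridable).
The molarity is 1000·ρ_s·c_Ca/M_Ca; applied to pure calcite
(ρ = 2.71 g/cm³, M = 100.09 g/mol) the same formula gives the 27.08 M
internal-standard value used everywhere.

**Dispersion.** Reported as the region's grey s.d. propagated through the
numerically differentiated inverse map (first-order delta method) — a
sensitivity measure, not a calibrated confidence interval.

**No counterions** are added for charge balance by default; the density
model tolerates the imbalance, and the choice only matters through the
composition-to-η and composition-to-density maps, which use the same
species set on both the forward and inverse paths.

## Soft X-ray quantification (Ca L₂,₃-edge)

**Model.** Transmission imaging obeys Beer–Lambert absorption; flat-field
normalization gives OD = −ln(I/I₀) per pixel, with non-positive
intensities masked invalid (NaN) rather than clamped, and excluded from
region statistics. Calcium is isolated by ΔOD between an on-edge image
(353.2 eV, the second white line) and a below-edge image (342 eV, where Ca
is nearly transparent); the energy-flat organic/water background cancels
in the difference. ΔOD is proportional to molarity × chord length, so

    c = c_cal · (ΔOD/L) / (ΔOD_cal/L_cal),

with intracellular coccolith calcite (27 M) as internal standard. Region
*means* of ΔOD and L are used rather than per-pixel ratios: one value per
body is reported and per-pixel division amplifies noise at thin rims.

**Registration.** Two stages of translation-only phase correlation
(replacing feature-based alignment; the acquisitions differ only by drift):
(i) the on-edge frame is aligned to the below-edge frame using
phase-normalized correlation on OD images smoothed with a σ = 2 px
Gaussian — whitening makes the correlation peak sharp, smoothing keeps it
above the photon-noise floor; (ii) the ΔOD map is registered onto the
template formed by the projected chord-length maps of the body and
calibration masks. The masks come from an independently reconstructed
volume, so a residual rigid offset is expected; because ΔOD is
proportional to the Ca chord length, the template correlation is unbiased.
Stage (ii) matters most for thin calibration regions (a coccolith ring a
few pixels wide), where a 2 px offset alone would bias the areal ratio.

**Path lengths** are voxel counts along the viewing axis times the voxel
size, taken from the segmentation at zero tilt by default (orientation
configurable). **Radiation damage** is checked, not corrected: a repeat
energy scan is compared to the first by maximum absolute difference.

**Spectra.** Region spectra are mask-averaged OD per scan energy.
Crystal-field peak detection uses local-maximum prominence within
±0.25 eV of 347.9 and 351.3 eV; crystalline calcite shows the peaks,
amorphous Ca phases do not.

## Ca K-edge XANES

**Preprocessing.** Repeat scans are averaged pointwise (optional linear
interpolation onto the first grid). The edge energy E₀ is the third peak
of the first derivative — Ca K-edge spectra carry two pre-edge features
whose derivative maxima precede the main-edge maximum. The derivative is a
Savitzky–Golay local quadratic of 1 eV width; peaks need prominence ≥ 5%
of the derivative range; with fewer than three peaks the global derivative
maximum is used with a warning. Normalization fits a line over
[E₀−25, E₀−13] eV and a quadratic over [E₀+26, E₀+90] eV, subtracts the
pre-edge line and divides by the edge step evaluated at E₀. The output is
invariant to affine transforms of the raw intensity. No post-edge
flattening is applied; for edges whose post-edge settles slowly (1/x-type
tails) the extrapolated quadratic can overshoot the step by some percent —
irrelevant for fitting, where target and references share the convention.

**Linear-combination fitting.** Weights minimize the squared misfit over a
window (default [E₀−20, E₀+60] eV) subject to wᵢ ≥ 0 and Σwᵢ = 1. The
simplex constraint is on by default (fractional phase contributions) and
configurable off. The equality is imposed as a heavily weighted extra
equation on a non-negative least-squares solve, then renormalized —
deterministic and exact to the solver tolerance. Near-identical references
trigger an ill-conditioning warning but still return valid simplex
weights. Reference sets are ranked by residual; ties within tolerance go
to the smaller set, so an unneeded reference never wins.

## Fourier shell correlation

FSC(s) = Re⟨F_a·F_b*⟩ / √(⟨|F_a|²⟩⟨|F_b|²⟩) over spherical Fourier shells
(non-cubic volumes are zero-padded to cubic; shells span up to Nyquist,
one shell per 0.5/n_shells cycles/voxel). Resolution is the *first*
crossing of the threshold (default 0.25, fixed-threshold criterion, not
0.25-bit), located by linear interpolation between bracketing shells and
reported as half pitch, 1/(2·f_c). A curve that never crosses returns the
Nyquist-limited value 2·voxel, flagged. Even/odd splitting of tilt series
and reconstruction are out of scope; the operator takes two volumes.

## Image-processing conventions

Axis order (slice, row, col), 0-based, voxel-centered; grey values are
float in memory regardless of on-disk type. Stack I/O: multi-page TIFF
with a JSON metadata sidecar, or MRC2014 mode-2 float32 with the voxel
size in the cell dimensions (a minimal reader/writer is built in).
Alignment is translation-only phase correlation against a configurable
reference frame (middle of the stack by default; first frame for energy
scans whose first frame anchors the coordinate system); measured shifts
can be replayed onto a paired channel (in-lens follows EsB). Destriping
notches the zero-row-frequency line of the 2-D spectrum (vertical FIB
curtaining concentrates there) while protecting the DC and the lowest two
column frequencies, so the mean grey and wide genuine structure survive.

## The phantom generator

`phantom.make_cell_phantom` builds a labelled ellipsoidal cell (~2.2 × 3.5
× 3.5 μm at 40 nm voxels) in seawater medium, containing a nucleus,
chloroplast, two lipid bodies, a calcite coccolith ring, a concentrated
Ca-P body and an optional dilute Ca cloud. Default planted concentrations
are the measured regimes of the study system — body 10 M, cloud 1.5 M,
calcite at its intrinsic 27.08 M — and the body is constructed from the N
grid voxels nearest its centre with N chosen to hit the requested volume
(default 1.5 μm³) within half a voxel. Organelle placements are validated:
inside the cell, pairwise disjoint, and with projection footprints of
body/coccolith/cloud disjoint so the quantification regions do not shadow
each other. Cytoplasm and organelles are water/biomass mixtures (C₅H₇NO₂
at 20–30 wt%).

Forward models: EsB grey is exactly affine in η_eff plus Gaussian noise
(the in-lens channel is qualitative: reduced gain, darkened label
boundaries). X-ray frames follow Beer–Lambert with a phenomenological
per-molar L-edge absorbance (arctan continuum step at 349.0 eV, Gaussian
white lines at 349.3 and 353.2 eV, crystal-field satellites at
347.9/351.3 eV for crystalline labels only; amplitudes ~10⁻⁴ nm⁻¹M⁻¹ sized
so a coccolith-thickness calcite path gives ΔOD ≈ 1) plus an
energy-independent per-label background; noise is Poisson at a default
flat-field flux of 2000 counts/pixel; per-frame integer jitter (first
frame fixed) exercises the alignment. K-edge mixtures are convex
combinations of three fixed parameterized end-members (calcite-like,
ACC-like, free-ion-like; arctan edges at 4048 eV with phase-specific white
lines and post-edge oscillations on a 4000–4140 eV grid, wide enough for
the stated normalization windows) plus Gaussian noise.

**What the phantoms do not emulate:** real beamline optics and tabulated
cross sections (the edge model is self-consistent, not absolute),
membrane ultrastructure, partial-volume and charging artifacts, detector
nonlinearity, deformable drift, or reconstruction artifacts in the 3-D
masks. Closed-loop recovery therefore demonstrates that the inverse chains
are correct and noise-stable, not that the forward models match a
particular instrument.

## Problem sizes and determinism

Default grids are 64×96×96 voxels (BSE/X-ray phantoms), 48-frame energy
scans (347.7–354.7 eV in 0.15 eV steps plus one 342 eV frame), 48³ FSC
test volumes, and 20/10/50-seed repetitions for the backscatter, X-ray and
LCF recovery loops — sizes at which every closed loop is statistically
stable while the whole suite runs in seconds. All randomness flows through
`numpy.random.default_rng` seeds; every render is bit-reproducible for a
fixed seed.

## Known limitations

* The electrolyte inversion is only as good as its compositional
  assumptions (Ca:P ratio, phosphate speciation, ionic radii); these are
  parameters, not fitted quantities.
* The delta-method dispersion ignores calibration-line uncertainty.
* Grey values are assumed detector-linear; no linearization step is
  provided.
* The X-ray estimate assumes the calibration and body regions share the
  illumination and that their projection footprints do not overlap other
  Ca-bearing structures.
* `find_edge` requires resolvable pre-edge derivative peaks; heavily
  smoothed or coarse-gridded spectra fall back to the global derivative
  maximum.
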