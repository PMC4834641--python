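"""FIB-SEM backscatter quantification of calcium concentration.

The chain mirrors in-image calibration against internal standards: grey
values of regions with known composition (lipid bodies ~ CH2, the seawater
culture medium, coccolith calcite) define a line grey = slope * eta_eff +
intercept; the line is inverted at a body of interest to an effective
backscatter coefficient, and that coefficient is inverted — under a
concentrated Ca:P 1:2 electrolyte model — to a Ca weight fraction and hence
a molarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .image_core import ImageStack, RegionMask, region_stats
from .materials import (
    ElectrolyteModel,
    Material,
    build_electrolyte,
    electrolyte_molarity,
    eta_eff,
    water,
)
from .results import ConcentrationEstimate


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationStandard:
    """An internal standard: a material of known composition measured in the
    same image stack as the body of interest."""

    name: str
    material: Material
    mean_grey: float
    grey_sd: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_grey):
            raise CalibrationError(f"standard {self.name!r} has non-finite grey")

    @property
    def eta(self) -> float:
        return eta_eff(self.material)


@dataclass
class BackscatterCalibration:
    slope: float  # grey per unit eta
    intercept: float  # grey offset
    standards: list[CalibrationStandard] = field(default_factory=list)
    residual_norm: float = 0.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise CalibrationError("calibration slope must be nonzero")


def fit_calibration(standards: list[CalibrationStandard]) -> BackscatterCalibration:
    """Least-squares line grey = slope * eta_eff + intercept through the
    standards; exact with two standards."""
    if len(standards) < 2:
        raise CalibrationError("need at least 2 standards")
    etas = np.array([s.eta for s in standards])
    greys = np.array([s.mean_grey for s in standards])
    if np.ptp(etas) < 1e-12:
        raise CalibrationError("standards have degenerate eta_eff spread")
    A = np.vstack([etas, np.ones_like(etas)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, greys, rcond=None)
    residual_norm = float(np.sqrt(res[0])) if res.size else 0.0
    return BackscatterCalibration(float(slope), float(intercept), list(standards), residual_norm)


def grey_to_eta(grey: float, calibration: BackscatterCalibration) -> float:
    """Invert the calibration line at a grey value."""
    return (grey - calibration.intercept) / calibration.slope


def eta_to_ca_molarity(
    eta: float,
    electrolyte: ElectrolyteModel | None = None,
    region: str = "body",
    xtol: float = 1e-9,
) -> ConcentrationEstimate:
    """Invert an effective backscatter coefficient to a Ca molarity.

    Solves for the Ca weight fraction whose Ca:P electrolyte reproduces
    ``eta`` under the mixture rule (eta_eff is monotone in concentration, so
    a bracketed root find is robust), then converts to mol/L through the
    density-mixing rule.  Below the pure-water eta the estimate saturates at
    0 M with a warning; above the most concentrated consistent solution a
    range error is raised.
    """
    electrolyte = electrolyte or ElectrolyteModel()
    eta_water = eta_eff(water())
    w_max = electrolyte.max_ca_mass_fraction() - 1e-9
    eta_max = eta_eff(build_electrolyte(w_max, electrolyte))
    if eta <= eta_water:
        if eta < eta_water - 1e-12:
            warnings.warn(
                f"eta {eta:.5f} below pure-water eta {eta_water:.5f}; reporting 0 M",
                stacklevel=2,
            )
        return ConcentrationEstimate(region, 0.0, method="bse")
    if eta > eta_max:
        raise CalibrationError(
            f"eta {eta:.5f} above the electrolyte model's maximum {eta_max:.5f}"
        )
    w = brentq(
        lambda wf: eta_eff(build_electrolyte(wf, electrolyte)) - eta, 0.0, w_max, xtol=xtol
    )
    molarity = electrolyte_molarity(float(w), electrolyte)
    return ConcentrationEstimate(
        region,
        molarity,
        method="bse",
        provenance={"ca_mass_fraction": float(w), "eta_eff": float(eta)},
    )


def _molarity_of_grey(
    grey: float, calibration: BackscatterCalibration, electrolyte: ElectrolyteModel
) -> float:
    return eta_to_ca_molarity(grey_to_eta(grey, calibration), electrolyte).ca_molarity


def quantify_body(
    stack: ImageStack,
    body_mask: RegionMask,
    standards: list[tuple[str, Material, RegionMask]],
    electrolyte: ElectrolyteModel | None = None,
) -> ConcentrationEstimate:
    """Full in-image chain: region stats -> calibration fit -> line inversion
    -> electrolyte inversion.

    ``standards`` couples each known material with its mask *on the same
    stack* (internal standards).  The dispersion of the estimate is the grey
    s.d. propagated through the numerically differentiated inverse map
    (first-order delta method).
    """
    if stack.modality != "bse-esb":
        raise CalibrationError(
            f"quantification uses the EsB channel, got modality {stack.modality!r}"
        )
    electrolyte = electrolyte or ElectrolyteModel()
    cal_standards = []
    for name, material, mask in standards:
        st = region_stats(stack, mask)
        cal_standards.append(CalibrationStandard(name, material, st.mean, st.sd))
    calibration = fit_calibration(cal_standards)
    body = region_stats(stack, body_mask)
    estimate = eta_to_ca_molarity(
        grey_to_eta(body.mean, calibration), electrolyte, region=body_mask.label
    )
    # delta method: sd_M = sd_grey * |dM/dgrey| at the body grey
    dg = max(abs(body.mean) * 1e-4, 1e-6)
    try:
        m_hi = _molarity_of_grey(body.mean + dg, calibration, electrolyte)
        m_lo = _molarity_of_grey(body.mean - dg, calibration, electrolyte)
        slope_inv = (m_hi - m_lo) / (2 * dg)
    except CalibrationError:
        slope_inv = 0.0
    estimate.dispersion = abs(slope_inv) * body.sd
    estimate.provenance.update(
        {
            "calibration": {
                "slope": calibration.slope,
                "intercept": calibration.intercept,
                "residual_norm": calibration.residual_norm,
                "standards": {
                    s.name: {"eta_eff": s.eta, "mean_grey": s.mean_grey}
                    for s in calibration.standards
                },
            },
            "body_mean_grey": body.mean,
            "body_grey_sd": body.sd,
            "body_voxels": body.count,
        }
    )
    return estimate
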