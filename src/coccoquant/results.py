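"""Result containers shared across quantification modules."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class ConcentrationEstimate:
    """A region's calcium concentration estimate.

    ``method`` is "bse" (backscatter calibration) or "xray" (L-edge
    absorbance); ``provenance`` records the calibration inputs that produced
    the number.
    """

    region: str
    ca_molarity: float  # mol/L
    dispersion: float = 0.0  # mol/L
    method: str = "bse"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ca_molarity < 0:
            raise ValueError("ca_molarity must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)
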