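"""Cellular calcium budget arithmetic.

The unit identity 1 um^3 x 1 mol/L = 1 fmol makes the compartment budget a
product: a 1.5 um^3 compartment filled at 10 M holds 15 fmol Ca, about
two-thirds of the ~22.5 fmol a single coccolith requires.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Ca demand of one average coccolith (fmol).
PER_COCCOLITH_FMOL = 22.5


def ca_amount(volume_um3: float, molarity_M: float) -> float:
    """Ca amount in fmol of a compartment: volume (um^3) x molarity (mol/L)."""
    if volume_um3 < 0 or molarity_M < 0:
        raise ValueError("volume and molarity must be >= 0")
    return volume_um3 * molarity_M


def fraction_of_coccolith(amount_fmol: float, per_coccolith_fmol: float = PER_COCCOLITH_FMOL) -> float:
    """Stored amount as a fraction of one coccolith's Ca demand."""
    if per_coccolith_fmol <= 0:
        raise ValueError("per-coccolith amount must be positive")
    if amount_fmol < 0:
        raise ValueError("amount must be >= 0")
    return amount_fmol / per_coccolith_fmol


@dataclass
class CaBudget:
    volume_um3: float
    molarity_M: float
    per_coccolith_fmol: float = PER_COCCOLITH_FMOL

    @property
    def amount_fmol(self) -> float:
        return ca_amount(self.volume_um3, self.molarity_M)

    @property
    def fraction_of_coccolith(self) -> float:
        return fraction_of_coccolith(self.amount_fmol, self.per_coccolith_fmol)

    def to_dict(self) -> dict:
        return {
            "volume_um3": self.volume_um3,
            "molarity_M": self.molarity_M,
            "amount_fmol": self.amount_fmol,
            "per_coccolith_fmol": self.per_coccolith_fmol,
            "fraction_of_coccolith": self.fraction_of_coccolith,
        }
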