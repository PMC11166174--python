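"""pH dependence of the probe's enzymatic hydrolysis.

Hydrolysis of the covalent probe-enzyme complex slows as intracellular pH
falls (ischaemic tissue acidifies through anaerobic glycolysis), which is
what turns the hydrolysis rate K_H into a pH-weighted readout.  The
dose-response is modelled as a four-parameter logistic in pH (base 10):

    f(pH) = floor + (ceiling - floor) / (1 + 10**(hill*(ph50 - pH)))

with half-maximal CO2 production at pH 5.3 by default.  Below a severe
acidity cutoff (default pH 4.8) the enzyme's binding affinity itself
drops; that is modelled separately as a multiplier on the association rate
k3, not on K_H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import ValidationError

__all__ = [
    "PHResponseModel",
    "DeactivationRule",
    "hydrolysis_fraction",
    "modulated_kh",
    "ph_half_max",
]


@dataclass(frozen=True)
class PHResponseModel:
    """Logistic pH -> fractional-hydrolysis-activity model.

    ph50 : pH of half-maximal CO2 production (default 5.3).
    hill : slope factor of the logistic (default 1, decades of activity per
        pH unit); only the half-max point is constrained by measurement, so
        the slope is user-settable.
    floor, ceiling : asymptotic fractional activity bounds in [0, 1].
    """

    ph50: float = 5.3
    hill: float = 1.0
    floor: float = 0.0
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.floor < self.ceiling <= 1.0):
            raise ValidationError("need 0 <= floor < ceiling <= 1")
        if self.hill <= 0:
            raise ValidationError("hill slope must be > 0")


@dataclass(frozen=True)
class DeactivationRule:
    """Suppression of covalent binding (k3) under severe acidity."""

    ph_cutoff: float = 4.8
    k3_factor: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.k3_factor <= 1.0):
            raise ValidationError("k3 suppression factor must lie in [0, 1]")

    def k3_multiplier(self, ph: float) -> float:
        return self.k3_factor if ph < self.ph_cutoff else 1.0


def hydrolysis_fraction(ph, model: PHResponseModel = PHResponseModel()):
    """Fractional hydrolysis activity at a given pH, in [floor, ceiling]."""
    ph = np.asarray(ph, dtype=float)
    f = model.floor + (model.ceiling - model.floor) / (
        1.0 + 10.0 ** (model.hill * (model.ph50 - ph))
    )
    return f if f.ndim else float(f)


def modulated_kh(kh_max: float, ph, model: PHResponseModel = PHResponseModel()):
    """Effective hydrolysis rate (1/h): kh_max scaled by the pH response."""
    if kh_max < 0:
        raise ValidationError("kh_max must be >= 0")
    return kh_max * hydrolysis_fraction(ph, model)


def ph_half_max(model: PHResponseModel = PHResponseModel()) -> float:
    """pH at which activity is exactly midway between floor and ceiling.

    For the logistic form this is the ph50 parameter; returned through the
    model's own inverse so the function stays meaningful if the response
    shape is ever generalised.
    """
    # logistic inverse at the midpoint
    return float(model.ph50)
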