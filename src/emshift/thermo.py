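"""Closed-form Nernst and thermodynamic-cycle relations for redox couples.

All midpoint potentials (``e_m``) are carried in millivolts versus the
standard hydrogen electrode (SHE).  Conversion to volts happens only inside
Gibbs-energy computations.  The default couple is a two-electron reduction
(quinone/hydroquinone-type chemistry); one-electron couples are supported
for generality.

The central relation is the thermodynamic cycle linking a shift in midpoint
potential of a *bound* redox-active ligand to differential binding of its
oxidized and reduced forms::

    delta_em = -(R*T / (n*F)) * ln(kd_red / kd_ox)

so preferential binding of the oxidized form (``kd_red > kd_ox``) lowers
the bound ligand's midpoint potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "ThermoConditions",
    "RedoxCouple",
    "BindingPair",
    "nernst_prefactor",
    "kd_ratio_from_delta_em",
    "delta_em_from_kd",
    "em_bound",
    "gibbs_from_em",
    "gibbs_of_binding",
    "fraction_reduced_at_potential",
]

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314
#: Faraday constant, C mol^-1.
FARADAY = 96485.0


@dataclass(frozen=True)
class ThermoConditions:
    """Shared assay conditions: temperature and electrons transferred.

    Parameters
    ----------
    temperature:
        Absolute temperature in kelvin.  Default 295 K (room temperature).
    n_electrons:
        Electrons transferred per redox event.  Default 2 (oxidized flavin
        to hydroquinone); 1 is accepted for one-electron couples.
    """

    temperature: float = 295.0
    n_electrons: int = 2

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature) or self.temperature <= 0:
            raise ValueError(f"temperature must be positive and finite, got {self.temperature}")
        if self.n_electrons not in (1, 2):
            raise ValueError(f"n_electrons must be 1 or 2, got {self.n_electrons}")


@dataclass(frozen=True)
class RedoxCouple:
    """A redox couple with a midpoint potential in mV vs SHE."""

    name: str
    e_m: float
    n_electrons: int = 2

    def __post_init__(self) -> None:
        if not math.isfinite(self.e_m):
            raise ValueError(f"e_m must be finite, got {self.e_m}")
        if self.n_electrons < 1:
            raise ValueError(f"n_electrons must be >= 1, got {self.n_electrons}")


@dataclass(frozen=True)
class BindingPair:
    """Dissociation constants (molar) of a receptor for the oxidized and
    reduced forms of a redox-active ligand."""

    kd_ox: float
    kd_red: float

    def __post_init__(self) -> None:
        for label, value in (("kd_ox", self.kd_ox), ("kd_red", self.kd_red)):
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{label} must be positive and finite, got {value}")

    @property
    def ratio(self) -> float:
        """kd_red / kd_ox (dimensionless)."""
        return self.kd_red / self.kd_ox


def nernst_prefactor(cond: ThermoConditions) -> float:
    """Return R*T/(n*F) in millivolts.

    This is the slope constant multiplying ln(oxidized/reduced) in the
    Nernst equation; approximately 12.5 mV for a two-electron couple near
    290 K and 12.85 mV at 298.15 K.
    """
    return GAS_CONSTANT * cond.temperature / (cond.n_electrons * FARADAY) * 1000.0


def kd_ratio_from_delta_em(delta_em: float, cond: ThermoConditions = ThermoConditions()) -> float:
    """Fold-increase of kd_red over kd_ox implied by a midpoint shift.

    Parameters
    ----------
    delta_em:
        Bound-minus-free midpoint potential shift, mV.  Negative shifts
        (bound form harder to reduce) imply a ratio greater than one.
    """
    if not math.isfinite(delta_em):
        raise ValueError(f"delta_em must be finite, got {delta_em}")
    return math.exp(-delta_em / nernst_prefactor(cond))


def delta_em_from_kd(pair: BindingPair, cond: ThermoConditions = ThermoConditions()) -> float:
    """Midpoint shift (mV) implied by differential oxidized/reduced binding.

    Exact inverse of :func:`kd_ratio_from_delta_em`.
    """
    return -nernst_prefactor(cond) * math.log(pair.ratio)


def em_bound(em_free: float, pair: BindingPair, cond: ThermoConditions = ThermoConditions()) -> float:
    """Midpoint potential (mV) of the bound ligand given the free-ligand
    value and the differential binding pair."""
    if not math.isfinite(em_free):
        raise ValueError(f"em_free must be finite, got {em_free}")
    return em_free + delta_em_from_kd(pair, cond)


def gibbs_from_em(couple: RedoxCouple) -> float:
    """Standard Gibbs energy of reduction, J mol^-1: -n*F*E_m.

    A more negative midpoint potential means a more positive (less
    favourable) reduction free energy.
    """
    return -couple.n_electrons * FARADAY * (couple.e_m / 1000.0)


def gibbs_of_binding(kd: float, temperature: float = 295.0) -> float:
    """Standard Gibbs energy of binding, J mol^-1: R*T*ln(kd) with kd molar."""
    if kd <= 0 or not math.isfinite(kd):
        raise ValueError(f"kd must be positive and finite, got {kd}")
    return GAS_CONSTANT * temperature * math.log(kd)


def fraction_reduced_at_potential(
    potential,
    couple: RedoxCouple,
    cond: ThermoConditions = ThermoConditions(),
):
    """Equilibrium reduced fraction of a couple at a solution potential.

    ``f_red = 1 / (1 + exp((E - e_m)/prefactor))`` with the prefactor taken
    from the couple's own electron count and the conditions' temperature.
    Strictly decreasing in ``potential``; equals 0.5 at ``e_m`` exactly.
    Accepts scalars or arrays (mV).
    """
    pf = GAS_CONSTANT * cond.temperature / (couple.n_electrons * FARADAY) * 1000.0
    arg = (np.asarray(potential, dtype=float) - couple.e_m) / pf
    out = 1.0 / (1.0 + np.exp(np.clip(arg, -700.0, 700.0)))
    if np.isscalar(potential) or np.ndim(potential) == 0:
        return float(out)
    return out
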