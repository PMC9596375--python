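"""Synthetic-data generators for the dual-indicator equilibration assay and
for the binding-isotherm fitters.

The assay simulator models an enzyme-driven reducing system delivering
electron equivalents at a constant rate into a cuvette containing one
redox-active ligand (optionally aptamer-bound) and one reference dye.  Both
couples are assumed to stay at redox equilibrium with a shared solution
potential throughout, so at every timepoint the potential is found by
conserving delivered equivalents across the couples.  Absorbance spectra
are linear combinations of oxidized/reduced basis envelopes (1 cm path).

Spectral envelopes are sums of Gaussian bands in wavelength.  No published
molar absorptivities are reproduced here: amplitudes and widths are
simulator conventions chosen to give realistic peak structure and are fully
configurable.  Declared isosbestic wavelengths are enforced exactly by
rescaling the reduced envelope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .thermo import RedoxCouple, ThermoConditions, fraction_reduced_at_potential

__all__ = [
    "DEFAULT_WAVELENGTHS",
    "BasisSpectrum",
    "AssaySpecies",
    "AssayConfig",
    "TimeSeriesSpectra",
    "Thermogram",
    "TitrationCurve",
    "build_basis_spectrum",
    "electron_schedule",
    "partition_electrons",
    "simulate_assay",
    "itc_heats",
    "simulate_itc",
    "simulate_quench",
    "simulate_inline_probing",
    "BASIS_PRESETS",
]

log = logging.getLogger(__name__)

#: Default wavelength grid, nm (1-nm step).
DEFAULT_WAVELENGTHS = np.arange(290.0, 751.0)


@dataclass(frozen=True, eq=False)
class BasisSpectrum:
    """Oxidized/reduced molar-absorptivity envelopes on a wavelength grid.

    Absorptivities are in AU per µM per cm.  ``isosbestic_nm`` lists
    wavelengths where the two envelopes are constrained to coincide.
    """

    wavelengths: np.ndarray
    eps_ox: np.ndarray
    eps_red: np.ndarray
    isosbestic_nm: tuple = ()
    isosbestic_tol: float = 1e-9

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ox = np.asarray(self.eps_ox, dtype=float)
        red = np.asarray(self.eps_red, dtype=float)
        if wl.shape != ox.shape or wl.shape != red.shape:
            raise ValueError("wavelength / eps_ox / eps_red grids are not aligned")
        if np.any(ox < 0) or np.any(red < 0):
            raise ValueError("absorptivities must be non-negative")
        for lam in self.isosbestic_nm:
            i = self.index_of(lam)
            if abs(ox[i] - red[i]) >= self.isosbestic_tol:
                raise ValueError(
                    f"isosbestic constraint violated at {lam} nm: "
                    f"|eps_ox - eps_red| = {abs(ox[i] - red[i]):.3e}"
                )

    def index_of(self, wavelength: float) -> int:
        """Index of an on-grid wavelength; raises if off-grid."""
        idx = np.searchsorted(self.wavelengths, wavelength)
        if idx >= len(self.wavelengths) or abs(self.wavelengths[idx] - wavelength) > 1e-9:
            raise ValueError(f"wavelength {wavelength} nm not on grid")
        return int(idx)


@dataclass(frozen=True, eq=False)
class AssaySpecies:
    """One redox-active assay component: couple, concentration and spectra."""

    couple: RedoxCouple
    concentration: float  # µM
    basis: BasisSpectrum
    role: str  # "flavin" | "reference_dye"

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"concentration must be > 0, got {self.concentration}")
        if self.role not in ("flavin", "reference_dye"):
            raise ValueError(f"role must be 'flavin' or 'reference_dye', got {self.role!r}")


@dataclass(eq=False)
class AssayConfig:
    """Configuration for one simulated equilibration run.

    ``electron_capacity`` is the total deliverable µM-equivalents from the
    reductant pool (e.g. 700 µM of a two-electron donor -> 1400); it is
    normally far above the acceptors' capacity so full reduction is reached.
    """

    species: Sequence[AssaySpecies]
    electron_capacity: float = 1400.0
    delivery_rate: float = 0.6  # µM-equivalents per minute
    timepoints: np.ndarray = field(default_factory=lambda: np.arange(0.0, 181.0))
    noise_sd: float = 0.0
    seed: int = 0
    conditions: ThermoConditions = field(default_factory=ThermoConditions)
    isosbestic_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        roles = [s.role for s in self.species]
        if roles.count("flavin") != 1 or roles.count("reference_dye") != 1:
            raise ValueError("config requires exactly one flavin and one reference dye")
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be non-empty and strictly increasing")
        self.timepoints = t
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.delivery_rate < 0:
            raise ValueError("delivery_rate must be >= 0")
        grid = self.species[0].basis.wavelengths
        for s in self.species[1:]:
            if not np.array_equal(s.basis.wavelengths, grid):
                raise ValueError("all species must share one wavelength grid")
        for lam in self.isosbestic_map.values():
            self.species[0].basis.index_of(lam)

    @property
    def acceptor_capacity(self) -> float:
        """Total µM-equivalents the redox couples can absorb."""
        return sum(s.concentration * s.couple.n_electrons for s in self.species)


@dataclass(eq=False)
class TimeSeriesSpectra:
    """Time-resolved absorbance: ``absorbance[i_time, i_wavelength]``."""

    times: np.ndarray  # minutes
    wavelengths: np.ndarray  # nm
    absorbance: np.ndarray  # AU, time x wavelength
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (self.times.size, self.wavelengths.size):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"axes ({self.times.size}, {self.wavelengths.size})"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    def index_of(self, wavelength: float) -> int:
        idx = np.searchsorted(self.wavelengths, wavelength)
        if idx >= len(self.wavelengths) or abs(self.wavelengths[idx] - wavelength) > 1e-9:
            raise ValueError(f"wavelength {wavelength} nm not on grid")
        return int(idx)


@dataclass(eq=False)
class Thermogram:
    """Per-injection heats from a titration-calorimetry experiment."""

    injection_index: np.ndarray
    injection_volume_ul: float
    molar_ratio: np.ndarray
    heat_ucal: np.ndarray
    cell_conc_um: float
    syringe_conc_um: float
    cell_volume_ml: float
    temperature: float  # K

    def __post_init__(self) -> None:
        self.injection_index = np.asarray(self.injection_index, dtype=int)
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        self.heat_ucal = np.asarray(self.heat_ucal, dtype=float)
        if np.any(np.diff(self.molar_ratio) < 0):
            raise ValueError("molar_ratio must be non-decreasing")
        if not np.all(np.isfinite(self.heat_ucal)):
            raise ValueError("heats must be finite")


@dataclass(eq=False)
class TitrationCurve:
    """Dose-response points: ligand concentration (M) vs response."""

    ligand_conc: np.ndarray
    response: np.ndarray
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if np.any(self.ligand_conc <= 0):
            raise ValueError("ligand concentrations must be > 0")
        if self.ligand_conc.shape != self.response.shape:
            raise ValueError("concentration and response arrays differ in length")


# ---------------------------------------------------------------------------
# Basis-spectrum presets
# ---------------------------------------------------------------------------
# Band tuples are (center nm, gaussian width nm, amplitude AU/µM/cm).
# Amplitudes are conventions, not measured absorptivities.  The reduced
# envelopes are rescaled so declared isosbestic wavelengths hold exactly.
BASIS_PRESETS: dict[str, dict] = {
    # oxidized ligand: visible maximum 450 nm, second peak 377 nm;
    # reduced form bleached in the visible with a residual near-UV band
    "free-FAD": {
        "bands_ox": [(450.0, 22.0, 0.050), (377.0, 22.0, 0.042)],
        "bands_red": [(340.0, 28.0, 0.025)],
        "isosbestic_nm": (335.0,),
    },
    # aptamer-bound ligand: red-shifted maximum 456 nm with shoulders at
    # 482/430 nm and a second peak at 384 nm
    "X2B2-bound-FAD": {
        "bands_ox": [
            (456.0, 18.0, 0.050),
            (482.0, 15.0, 0.016),
            (430.0, 15.0, 0.016),
            (384.0, 22.0, 0.045),
        ],
        "bands_red": [(340.0, 28.0, 0.025)],
        "isosbestic_nm": (335.0,),
    },
    # tighter-binding point variant: maximum at 458 nm, shoulders +/- 26 nm
    "C14U-bound-flavin": {
        "bands_ox": [
            (458.0, 18.0, 0.050),
            (484.0, 15.0, 0.016),
            (432.0, 15.0, 0.016),
            (384.0, 22.0, 0.045),
        ],
        "bands_red": [(340.0, 28.0, 0.025)],
        "isosbestic_nm": (335.0,),
    },
    # anthraquinone-2-sulfonate reference dye; isosbestic point at 355 nm
    "AQS": {
        "bands_ox": [(330.0, 25.0, 0.045)],
        "bands_red": [(390.0, 30.0, 0.028)],
        "isosbestic_nm": (355.0,),
    },
    # phenosafranin reference dye; leuco (reduced) form nearly colourless
    "PSF": {
        "bands_ox": [(520.0, 30.0, 0.050), (320.0, 20.0, 0.015)],
        "bands_red": [(318.0, 22.0, 0.008)],
        "isosbestic_nm": (),
    },
}


def _gaussian_sum(wavelengths: np.ndarray, bands) -> np.ndarray:
    out = np.zeros_like(wavelengths, dtype=float)
    lo, hi = wavelengths[0], wavelengths[-1]
    for center, width, amplitude in bands:
        if center < lo or center > hi:
            raise ValueError(f"band center {center} nm lies outside grid [{lo}, {hi}] nm")
        if width <= 0 or amplitude < 0:
            raise ValueError(f"invalid band ({center}, {width}, {amplitude})")
        out += amplitude * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    return out


def build_basis_spectrum(
    preset: str | None = None,
    *,
    bands_ox=None,
    bands_red=None,
    isosbestic_nm: Sequence[float] = (),
    wavelengths: np.ndarray | None = None,
) -> BasisSpectrum:
    """Construct a :class:`BasisSpectrum` from a preset name or band lists.

    Declared isosbestic constraints are enforced exactly by a global
    rescaling of the reduced envelope (so at most one constraint can be
    enforced this way; presets declare at most one).
    """
    if wavelengths is None:
        wavelengths = DEFAULT_WAVELENGTHS
    wavelengths = np.asarray(wavelengths, dtype=float)
    if preset is not None:
        if bands_ox is not None or bands_red is not None:
            raise ValueError("give either a preset name or explicit bands, not both")
        try:
            spec = BASIS_PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(BASIS_PRESETS)}"
            ) from None
        bands_ox = spec["bands_ox"]
        bands_red = spec["bands_red"]
        isosbestic_nm = spec["isosbestic_nm"]
    if bands_ox is None or bands_red is None:
        raise ValueError("bands_ox and bands_red are required when no preset is given")

    eps_ox = _gaussian_sum(wavelengths, bands_ox)
    eps_red = _gaussian_sum(wavelengths, bands_red)
    isosbestic_nm = tuple(float(x) for x in isosbestic_nm)
    if len(isosbestic_nm) > 1:
        raise ValueError("at most one isosbestic constraint can be enforced by rescaling")
    for lam in isosbestic_nm:
        idx = np.searchsorted(wavelengths, lam)
        if idx >= len(wavelengths) or abs(wavelengths[idx] - lam) > 1e-9:
            raise ValueError(f"isosbestic wavelength {lam} nm not on grid")
        if eps_ox[idx] <= 0 or eps_red[idx] <= 0:
            raise ValueError(
                f"impossible isosbestic constraint at {lam} nm: zero absorptivity"
            )
        eps_red = eps_red * (eps_ox[idx] / eps_red[idx])
        eps_red[idx] = eps_ox[idx]  # exact to the last bit
    return BasisSpectrum(wavelengths, eps_ox, eps_red, isosbestic_nm)


# ---------------------------------------------------------------------------
# Equilibration assay
# ---------------------------------------------------------------------------

def electron_schedule(config: AssayConfig) -> np.ndarray:
    """Delivered µM-equivalents at each timepoint: min(rate*t, capacity)."""
    return np.minimum(config.delivery_rate * config.timepoints, config.electron_capacity)


def partition_electrons(
    delivered: float,
    species: Sequence[AssaySpecies],
    cond: ThermoConditions = ThermoConditions(),
    tol: float = 1e-9,
) -> tuple[np.ndarray, float]:
    """Partition delivered equivalents among couples sharing one potential.

    Solves for the unique solution potential E (mV) such that

        sum_i c_i * n_i * f_red,i(E) == delivered

    and returns (reduced fractions per species, E).  E is strictly
    decreasing in ``delivered``.  Delivered amounts above the acceptors'
    total capacity are clamped (with a warning); at the boundaries the
    potential is +/- infinity and the fractions are exact 0s / 1s.
    """
    total = sum(s.concentration * s.couple.n_electrons for s in species)
    if delivered < 0:
        raise ValueError(f"delivered must be >= 0, got {delivered}")
    if delivered > total + tol:
        log.warning(
            "delivered %.6g µM-eq exceeds acceptor capacity %.6g µM-eq; clamping",
            delivered,
            total,
        )
        delivered = total
    if delivered <= 0:
        return np.zeros(len(species)), math.inf
    if delivered >= total:
        return np.ones(len(species)), -math.inf

    def excess(E: float) -> float:
        return (
            sum(
                s.concentration
                * s.couple.n_electrons
                * fraction_reduced_at_potential(E, s.couple, cond)
                for s in species
            )
            - delivered
        )

    ems = [s.couple.e_m for s in species]
    lo, hi = min(ems) - 2000.0, max(ems) + 2000.0
    E = brentq(excess, lo, hi, xtol=1e-12, rtol=8.9e-16)
    fractions = np.array(
        [fraction_reduced_at_potential(E, s.couple, cond) for s in species]
    )
    return fractions, float(E)


def simulate_assay(config: AssayConfig) -> TimeSeriesSpectra:
    """Simulate the dual-indicator equilibration assay.

    The first frame is fully oxidized; once delivered equivalents reach the
    acceptors' capacity the frames are fully reduced (and identical, up to
    noise).  Noise is i.i.d. Gaussian per (time, wavelength) point from a
    generator seeded with ``config.seed``.
    """
    delivered = electron_schedule(config)
    capacity = config.acceptor_capacity
    if delivered[-1] < capacity:
        log.info(
            "run ends before full reduction: delivered %.3g of %.3g µM-eq",
            delivered[-1],
            capacity,
        )
    clamped = np.minimum(delivered, capacity)
    wavelengths = config.species[0].basis.wavelengths
    absorbance = np.zeros((config.timepoints.size, wavelengths.size))
    for k, d in enumerate(clamped):
        fractions, _ = partition_electrons(float(d), config.species, config.conditions)
        for s, f_red in zip(config.species, fractions):
            absorbance[k] += s.concentration * (
                (1.0 - f_red) * s.basis.eps_ox + f_red * s.basis.eps_red
            )
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        absorbance = absorbance + rng.normal(0.0, config.noise_sd, absorbance.shape)
    dye = next(s for s in config.species if s.role == "reference_dye")
    flavin = next(s for s in config.species if s.role == "flavin")
    provenance = {
        "reference_dye": dye.couple.name,
        "reference_dye_e_m": dye.couple.e_m,
        "flavin": flavin.couple.name,
        "flavin_e_m": flavin.couple.e_m,
        "concentrations_um": {s.couple.name: s.concentration for s in config.species},
        "delivery_rate": config.delivery_rate,
        "electron_capacity": config.electron_capacity,
        "temperature": config.conditions.temperature,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    return TimeSeriesSpectra(config.timepoints, wavelengths, absorbance, provenance)


# ---------------------------------------------------------------------------
# Titration calorimetry and titration curves
# ---------------------------------------------------------------------------

def itc_heats(
    ka: float,
    dh_kcal: float,
    n_sites: float,
    cell_conc_um: float,
    syringe_conc_um: float,
    n_injections: int,
    injection_volume_ul: float,
    cell_volume_ml: float,
    dilution_heat_ucal: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact single-site per-injection heats with displaced-volume correction.

    Concentrations after injection i account for the perfusion-cell
    displacement (standard cell-overflow convention):

        Mt_i = M0 * (1 - v/2V0) / (1 + v/2V0),   v = i * dV
        Xt_i = X0 * (v/V0) / (1 + v/2V0)

    The bound concentration is the root of the single-site quadratic; the
    heat of injection i is the change in cell heat content plus a
    correction for heat carried out with the displaced volume, plus a
    constant per-injection dilution heat.  Returns (molar_ratio, heats µcal).
    """
    if ka <= 0 or cell_conc_um <= 0 or syringe_conc_um <= 0:
        raise ValueError("ka and concentrations must be > 0")
    if n_sites <= 0 or injection_volume_ul <= 0 or cell_volume_ml <= 0 or n_injections < 1:
        raise ValueError("nonphysical ITC geometry")
    kd = 1.0 / ka  # M
    m0 = cell_conc_um * 1e-6
    x0 = syringe_conc_um * 1e-6
    v0 = cell_volume_ml * 1e-3  # L
    dv = injection_volume_ul * 1e-6  # L
    heats = np.empty(n_injections)
    ratios = np.empty(n_injections)
    q_prev = 0.0
    for i in range(1, n_injections + 1):
        frac = i * dv / v0
        mt = m0 * (1.0 - frac / 2.0) / (1.0 + frac / 2.0)
        xt = x0 * frac / (1.0 + frac / 2.0)
        sites = n_sites * mt
        b = sites + xt + kd
        bound = (b - math.sqrt(b * b - 4.0 * sites * xt)) / 2.0
        q = bound * dh_kcal * v0 * 1e9  # kcal -> µcal
        dq = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
        heats[i - 1] = dq + dilution_heat_ucal
        ratios[i - 1] = xt / mt
        q_prev = q
    return ratios, heats


def simulate_itc(
    *,
    kd: float | None = None,
    ka: float | None = None,
    dh_kcal: float,
    n_sites: float = 1.0,
    cell_conc_um: float = 10.0,
    syringe_conc_um: float = 150.0,
    n_injections: int = 26,
    injection_volume_ul: float = 10.0,
    cell_volume_ml: float = 1.4155,
    temperature: float = 303.15,
    dilution_heat_ucal: float = 0.0,
    noise_sd_ucal: float = 0.0,
    seed: int = 0,
) -> Thermogram:
    """Simulate a single-site thermogram (default 26 injections, 30 °C)."""
    if (kd is None) == (ka is None):
        raise ValueError("give exactly one of kd (M) or ka (1/M)")
    if kd is not None:
        if kd <= 0:
            raise ValueError("kd must be > 0")
        ka = 1.0 / kd
    ratios, heats = itc_heats(
        ka,
        dh_kcal,
        n_sites,
        cell_conc_um,
        syringe_conc_um,
        n_injections,
        injection_volume_ul,
        cell_volume_ml,
        dilution_heat_ucal,
    )
    if noise_sd_ucal > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd_ucal, heats.shape)
    return Thermogram(
        injection_index=np.arange(1, n_injections + 1),
        injection_volume_ul=injection_volume_ul,
        molar_ratio=ratios,
        heat_ucal=heats,
        cell_conc_um=cell_conc_um,
        syringe_conc_um=syringe_conc_um,
        cell_volume_ml=cell_volume_ml,
        temperature=temperature,
    )


def simulate_quench(
    kd: float,
    hill_h: float,
    conc: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicate_id: int = 0,
) -> TitrationCurve:
    """Fraction-bound titration with a Hill response and b_max = 1."""
    if kd <= 0 or hill_h <= 0:
        raise ValueError("kd and hill_h must be > 0")
    conc = np.asarray(conc, dtype=float)
    response = conc**hill_h / (kd**hill_h + conc**hill_h)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        response = response + rng.normal(0.0, noise_sd, response.shape)
    return TitrationCurve(conc, response, replicate_id)


def simulate_inline_probing(
    kd_ox: float,
    kd_red: float,
    shared_bmax: float,
    conc: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[TitrationCurve, TitrationCurve]:
    """One-site saturation curves for oxidized/reduced ligand, shared b_max.

    ``kd_red = inf`` models a non-binder (flat curve at zero).
    """
    if kd_ox <= 0 or kd_red <= 0 or shared_bmax <= 0:
        raise ValueError("kds and shared_bmax must be > 0")
    conc = np.asarray(conc, dtype=float)
    rng = np.random.default_rng(seed)
    curves = []
    for rep, kd in enumerate((kd_ox, kd_red)):
        response = np.zeros_like(conc) if math.isinf(kd) else shared_bmax * conc / (kd + conc)
        if noise_sd > 0:
            response = response + rng.normal(0.0, noise_sd, response.shape)
        curves.append(TitrationCurve(conc, response, replicate_id=rep))
    return curves[0], curves[1]
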