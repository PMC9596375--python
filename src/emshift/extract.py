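"""Midpoint-potential inference from dual-indicator spectral time series.

Pipeline: anchor each species' oxidized fraction between the first
(fully-oxidized) frame and the plateau (fully-reduced) frame at the
*other* species' isosbestic wavelength, convert fractions to Nernst terms
``prefactor * ln(ox/red)``, regress the reference-dye terms on the ligand
terms, and read the ligand midpoint potential off the intercept:

    intercept b = E_m(ligand) - E_m(dye)   =>   E_m(ligand) = E_m(dye) + b

For a low-potential dye whose own absorbance overlaps the ligand's
measurement wavelength, the dye contribution is subtracted explicitly
from that channel using the dye's basis spectrum and its fraction trace.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import AssaySpecies, TimeSeriesSpectra
from .thermo import RedoxCouple, ThermoConditions, nernst_prefactor

__all__ = [
    "FractionTrace",
    "NernstFit",
    "EmResult",
    "SemiquinoneCheck",
    "AssayProtocol",
    "detect_plateau",
    "fraction_from_values",
    "fraction_oxidized_trace",
    "subtract_reference_contribution",
    "nernst_terms",
    "fit_nernst",
    "em_from_fit",
    "semiquinone_check",
    "run_em_pipeline",
]


@dataclass(eq=False)
class FractionTrace:
    """Per-time oxidized fraction of one species, anchored so the first
    frame is 1 and the plateau frame 0.  Raw values are not clipped and may
    slightly exceed [0, 1] under noise."""

    times: np.ndarray
    fraction_oxidized: np.ndarray
    species_role: str
    wavelength_used: float


@dataclass(eq=False)
class NernstFit:
    """Paired Nernst log-ratio terms (mV) and the regression through them.

    The dye terms are regressed on the ligand (flavin) terms, so the
    intercept is E_m(ligand) - E_m(dye) in mV and the slope equals
    n_dye/n_ligand (1 for matched two-electron couples).
    """

    flavin_terms: np.ndarray
    dye_terms: np.ndarray
    slope: float
    intercept_b: float
    r_squared: float
    mask: np.ndarray

    @property
    def n_used(self) -> int:
        return int(np.sum(self.mask))


@dataclass(eq=False)
class EmResult:
    """Replicate-averaged midpoint potential, mV vs SHE."""

    e_m: float
    sd: float
    n_replicates: int
    reference_dye: RedoxCouple
    delta_em_vs_free: float | None = None
    per_run_e_m: np.ndarray = field(default_factory=lambda: np.empty(0))
    fits: list = field(default_factory=list)


@dataclass(frozen=True)
class SemiquinoneCheck:
    passed: bool
    max_excess_au: float
    threshold_au: float


@dataclass(eq=False)
class AssayProtocol:
    """Everything the pipeline needs to know about how a run was measured."""

    dye: RedoxCouple
    dye_wavelength: float
    flavin_wavelength: float
    subtract_dye: bool = False
    dye_species: AssaySpecies | None = None
    conditions: ThermoConditions = field(default_factory=ThermoConditions)
    mask_bounds: tuple[float, float] = (0.05, 0.95)
    plateau_tol: float = 1e-3
    plateau_window: int = 5
    band_halfwidth: float = 0.0
    free_em: float | None = None


def detect_plateau(ts: TimeSeriesSpectra, tol: float = 1e-3, window: int = 5) -> int:
    """Earliest timepoint index from which frame-to-frame change stays small.

    A frame's change is the max absolute difference to the previous frame
    over all wavelengths.  Returns the earliest index ``i`` such that the
    next ``window`` changes are all below ``tol``.  If the series never
    settles, returns the last index and emits a warning.
    """
    n = ts.times.size
    if n < 2:
        raise ValueError("need at least 2 timepoints to detect a plateau")
    diffs = np.max(np.abs(np.diff(ts.absorbance, axis=0)), axis=1)
    quiet = diffs < tol
    window = min(window, diffs.size)
    for i in range(diffs.size - window + 1):
        if quiet[i : i + window].all():
            return i
    warnings.warn(
        f"series never settled (tol={tol} AU over {window} frames); "
        "using the last frame as the fully-reduced anchor",
        stacklevel=2,
    )
    return n - 1


def fraction_from_values(values: np.ndarray, t_ox: int, t_red: int, tol: float = 1e-12) -> np.ndarray:
    """Anchor a scalar trace between its oxidized and reduced frames."""
    values = np.asarray(values, dtype=float)
    denom = values[t_ox] - values[t_red]
    if abs(denom) < tol:
        raise ValueError(
            f"degenerate anchors: |A(t_ox) - A(t_red)| = {abs(denom):.3e} AU"
        )
    return (values - values[t_red]) / denom


def fraction_oxidized_trace(
    ts: TimeSeriesSpectra,
    wavelength: float,
    t_ox: int,
    t_red: int,
    species_role: str = "flavin",
    band_halfwidth: float = 0.0,
) -> FractionTrace:
    """Oxidized-fraction trace read at one wavelength (optionally a small
    band average for noise robustness), anchored at the given frames."""
    idx = ts.index_of(wavelength)
    if band_halfwidth > 0:
        sel = np.abs(ts.wavelengths - wavelength) <= band_halfwidth + 1e-9
        values = ts.absorbance[:, sel].mean(axis=1)
    else:
        values = ts.absorbance[:, idx]
    try:
        frac = fraction_from_values(values, t_ox, t_red)
    except ValueError as exc:
        raise ValueError(f"at {wavelength} nm: {exc}") from None
    return FractionTrace(ts.times, frac, species_role, wavelength)


def subtract_reference_contribution(
    ts: TimeSeriesSpectra,
    measure_wavelength: float,
    dye_trace: FractionTrace,
    dye_species: AssaySpecies | None,
) -> np.ndarray:
    """Remove the reference dye's absorbance from one measurement channel.

    Uses the fraction-weighted dye basis:
    ``A_corr(t) = A(t) - c * (f_ox * eps_ox + (1 - f_ox) * eps_red)``
    evaluated at the measurement wavelength.
    """
    if dye_species is None:
        raise ValueError(
            "dye basis spectrum required for subtraction; provide dye_species "
            "(e.g. calibrated from a dye-only run)"
        )
    idx = ts.index_of(measure_wavelength)
    bidx = dye_species.basis.index_of(measure_wavelength)
    f_ox = dye_trace.fraction_oxidized
    dye_a = dye_species.concentration * (
        f_ox * dye_species.basis.eps_ox[bidx]
        + (1.0 - f_ox) * dye_species.basis.eps_red[bidx]
    )
    return ts.absorbance[:, idx] - dye_a


def nernst_terms(trace: FractionTrace, cond: ThermoConditions) -> np.ndarray:
    """Per-time Nernst terms ``prefactor * ln(f_ox / (1 - f_ox))`` in mV.

    Points with fractions outside the open interval (0, 1) are returned as
    NaN (flagged, not silently dropped).
    """
    pf = nernst_prefactor(cond)
    f = np.asarray(trace.fraction_oxidized, dtype=float)
    terms = np.full_like(f, np.nan)
    ok = (f > 0.0) & (f < 1.0)
    terms[ok] = pf * np.log(f[ok] / (1.0 - f[ok]))
    return terms


def fit_nernst(
    flavin_trace: FractionTrace,
    dye_trace: FractionTrace,
    cond: ThermoConditions,
    mask_bounds: tuple[float, float] = (0.05, 0.95),
) -> NernstFit:
    """Ordinary least squares of dye Nernst terms on ligand Nernst terms.

    Points where either species' fraction falls outside ``mask_bounds``
    (where the log terms diverge) are excluded.  Requires >= 3 surviving
    points.
    """
    lo, hi = mask_bounds
    y = nernst_terms(dye_trace, cond)
    x = nernst_terms(flavin_trace, cond)
    ff = flavin_trace.fraction_oxidized
    fd = dye_trace.fraction_oxidized
    mask = (
        np.isfinite(x)
        & np.isfinite(y)
        & (ff >= lo)
        & (ff <= hi)
        & (fd >= lo)
        & (fd <= hi)
    )
    n = int(mask.sum())
    if n < 3:
        raise ValueError(
            f"only {n} paired points survive masking to [{lo}, {hi}]; need >= 3"
        )
    xm, ym = x[mask], y[mask]
    xbar, ybar = xm.mean(), ym.mean()
    sxx = np.sum((xm - xbar) ** 2)
    slope = float(np.sum((xm - xbar) * (ym - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = ym - (slope * xm + intercept)
    ss_tot = float(np.sum((ym - ybar) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return NernstFit(x, y, slope, intercept, r2, mask)


def em_from_fit(fit: NernstFit, dye: RedoxCouple) -> float:
    """Ligand midpoint potential: dye midpoint plus the fit intercept."""
    return dye.e_m + fit.intercept_b


def semiquinone_check(
    ts: TimeSeriesSpectra,
    band: tuple[float, float] = (590.0, 610.0),
    t_ox: int = 0,
    t_red: int | None = None,
    threshold: float = 0.01,
) -> SemiquinoneCheck:
    """Flag transient absorbance in a band (default around 600 nm) that
    exceeds both the fully-oxidized and fully-reduced anchor frames.

    A one-electron intermediate would appear as a mid-run bump not present
    in either anchor; the check fails if the excess exceeds ``threshold``.
    """
    lo, hi = band
    sel = (ts.wavelengths >= lo) & (ts.wavelengths <= hi)
    if not sel.any():
        raise ValueError(f"band [{lo}, {hi}] nm not within the wavelength grid")
    if t_red is None:
        t_red = ts.times.size - 1
    band_mean = ts.absorbance[:, sel].mean(axis=1)
    anchor = max(band_mean[t_ox], band_mean[t_red])
    max_excess = float(np.max(band_mean) - anchor)
    return SemiquinoneCheck(max_excess <= threshold, max_excess, threshold)


def _single_run_em(ts: TimeSeriesSpectra, protocol: AssayProtocol) -> tuple[float, NernstFit]:
    i_ox = 0
    i_red = detect_plateau(ts, protocol.plateau_tol, protocol.plateau_window)
    dye_trace = fraction_oxidized_trace(
        ts,
        protocol.dye_wavelength,
        i_ox,
        i_red,
        "reference_dye",
        protocol.band_halfwidth,
    )
    if protocol.subtract_dye:
        corrected = subtract_reference_contribution(
            ts, protocol.flavin_wavelength, dye_trace, protocol.dye_species
        )
        flavin_trace = FractionTrace(
            ts.times,
            fraction_from_values(corrected, i_ox, i_red),
            "flavin",
            protocol.flavin_wavelength,
        )
    else:
        flavin_trace = fraction_oxidized_trace(
            ts,
            protocol.flavin_wavelength,
            i_ox,
            i_red,
            "flavin",
            protocol.band_halfwidth,
        )
    fit = fit_nernst(flavin_trace, dye_trace, protocol.conditions, protocol.mask_bounds)
    return em_from_fit(fit, protocol.dye), fit


def run_em_pipeline(runs, protocol: AssayProtocol) -> EmResult:
    """Full inference over one or more replicate runs.

    Per run: plateau detection, fraction anchoring, optional dye
    subtraction, Nernst regression and intercept read-out.  The reported
    midpoint is the replicate mean with the sample standard deviation.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("need at least one run")
    dyes = {r.provenance.get("reference_dye") for r in runs} - {None}
    if len(dyes) > 1:
        raise ValueError(f"runs use mixed reference dyes: {sorted(dyes)}")
    ems, fits = [], []
    for ts in runs:
        em, fit = _single_run_em(ts, protocol)
        ems.append(em)
        fits.append(fit)
    ems = np.asarray(ems)
    sd = float(np.std(ems, ddof=1)) if len(ems) > 1 else 0.0
    mean = float(np.mean(ems))
    delta = None if protocol.free_em is None else mean - protocol.free_em
    if not math.isfinite(mean):
        raise ValueError("midpoint estimate is non-finite")
    return EmResult(
        e_m=mean,
        sd=sd,
        n_replicates=len(ems),
        reference_dye=protocol.dye,
        delta_em_vs_free=delta,
        per_run_e_m=ems,
        fits=fits,
    )
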