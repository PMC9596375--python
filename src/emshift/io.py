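"""CSV file formats, validated run configuration and provenance plumbing.

Spectra tables are plain CSV: first column ``wavelength_nm``, one column
per timepoint named ``t_<minutes>``.  Thermograms and titration tables are
flat CSV with fixed column names.  Configuration files are YAML validated
against pydantic schemas that reject unknown keys.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .extract import AssayProtocol
from .simulate import (
    AssayConfig,
    AssaySpecies,
    Thermogram,
    TimeSeriesSpectra,
    TitrationCurve,
    build_basis_spectrum,
)
from .thermo import RedoxCouple, ThermoConditions

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_thermogram",
    "write_thermogram",
    "read_titration",
    "write_titration",
    "SpeciesConfig",
    "RunConfig",
    "ExtractConfig",
    "assay_config_from_run_config",
    "protocol_from_extract_config",
    "config_hash",
    "write_provenance",
]

_TIME_COL = re.compile(r"^t_(-?\d+(?:\.\d+)?)$")

THERMOGRAM_COLUMNS = [
    "injection_index",
    "injection_volume_ul",
    "molar_ratio",
    "heat_ucal",
    "cell_conc_um",
    "syringe_conc_um",
    "cell_volume_ml",
    "temperature_k",
]

TITRATION_COLUMNS = ["ligand_conc_m", "response", "replicate_id"]


def write_spectra(ts: TimeSeriesSpectra, path) -> None:
    df = pd.DataFrame(
        ts.absorbance.T,
        columns=[f"t_{t:g}" for t in ts.times],
    )
    df.insert(0, "wavelength_nm", ts.wavelengths)
    df.to_csv(path, index=False, float_format="%.12g")


def read_spectra(path) -> TimeSeriesSpectra:
    """Parse a spectra CSV, validating axes and reporting bad cells."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.shape[1] < 2 or df.columns[0] != "wavelength_nm":
        raise ValueError(
            f"{path}: first column must be 'wavelength_nm' followed by t_<minutes> columns"
        )
    times = []
    for col in df.columns[1:]:
        m = _TIME_COL.match(col)
        if not m:
            raise ValueError(f"{path}: column {col!r} does not match 't_<minutes>'")
        times.append(float(m.group(1)))
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(values.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: malformed numeric cell at data row {r + 1}, column {df.columns[c]!r}"
        )
    wl = values["wavelength_nm"].to_numpy()
    dw = np.diff(wl)
    if np.any(dw <= 0):
        row = int(np.argmax(dw <= 0)) + 2
        raise ValueError(f"{path}: wavelengths not strictly increasing at data row {row}")
    if wl.size > 1 and not np.allclose(dw, dw[0]):
        import warnings

        warnings.warn(f"{path}: non-uniform wavelength step", stacklevel=2)
    absorbance = values.iloc[:, 1:].to_numpy().T
    return TimeSeriesSpectra(np.asarray(times), wl, absorbance, {"source": str(path)})


def write_thermogram(tg: Thermogram, path) -> None:
    pd.DataFrame(
        {
            "injection_index": tg.injection_index,
            "injection_volume_ul": tg.injection_volume_ul,
            "molar_ratio": tg.molar_ratio,
            "heat_ucal": tg.heat_ucal,
            "cell_conc_um": tg.cell_conc_um,
            "syringe_conc_um": tg.syringe_conc_um,
            "cell_volume_ml": tg.cell_volume_ml,
            "temperature_k": tg.temperature,
        }
    ).to_csv(path, index=False, float_format="%.12g")


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_thermogram(path) -> Thermogram:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    _require_columns(df, THERMOGRAM_COLUMNS, path)
    for col in ("cell_conc_um", "syringe_conc_um", "cell_volume_ml", "injection_volume_ul"):
        if (df[col] <= 0).any():
            raise ValueError(f"{path}: column {col!r} must be positive")
    return Thermogram(
        injection_index=df["injection_index"].to_numpy(),
        injection_volume_ul=float(df["injection_volume_ul"].iloc[0]),
        molar_ratio=df["molar_ratio"].to_numpy(),
        heat_ucal=df["heat_ucal"].to_numpy(),
        cell_conc_um=float(df["cell_conc_um"].iloc[0]),
        syringe_conc_um=float(df["syringe_conc_um"].iloc[0]),
        cell_volume_ml=float(df["cell_volume_ml"].iloc[0]),
        temperature=float(df["temperature_k"].iloc[0]),
    )


def write_titration(curve: TitrationCurve, path) -> None:
    pd.DataFrame(
        {
            "ligand_conc_m": curve.ligand_conc,
            "response": curve.response,
            "replicate_id": curve.replicate_id,
        }
    ).to_csv(path, index=False, float_format="%.12g")


def read_titration(path) -> TitrationCurve:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    _require_columns(df, TITRATION_COLUMNS[:2], path)
    if (df["ligand_conc_m"] <= 0).any():
        raise ValueError(f"{path}: ligand concentrations must be positive")
    rep = int(df["replicate_id"].iloc[0]) if "replicate_id" in df.columns else 0
    return TitrationCurve(
        df["ligand_conc_m"].to_numpy(), df["response"].to_numpy(), rep
    )


# ---------------------------------------------------------------------------
# Validated configuration
# ---------------------------------------------------------------------------

class SpeciesConfig(BaseModel):
    """One assay species: a spectral preset plus redox parameters."""

    model_config = ConfigDict(extra="forbid")

    preset: str
    e_m_mv: float
    concentration_um: float = Field(20.0, gt=0)
    n_electrons: int = Field(2, ge=1)
    name: str | None = None


class RunConfig(BaseModel):
    """Configuration for ``simulate-assay``.  Temperatures in kelvin only."""

    model_config = ConfigDict(extra="forbid")

    flavin: SpeciesConfig
    reference_dye: SpeciesConfig
    temperature_k: float = Field(295.0, gt=0)
    delivery_rate_um_per_min: float = Field(0.6, gt=0)
    electron_capacity_um: float = Field(1400.0, gt=0)
    time_start_min: float = 0.0
    time_stop_min: float = 180.0
    time_step_min: float = Field(1.0, gt=0)
    noise_sd_au: float = Field(0.0, ge=0)
    seed: int = 0
    replicates: int = Field(1, ge=1)

    @model_validator(mode="after")
    def _check_times(self):
        if self.time_stop_min <= self.time_start_min:
            raise ValueError("time_stop_min must exceed time_start_min")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


class ExtractConfig(BaseModel):
    """Configuration for ``extract-em``."""

    model_config = ConfigDict(extra="forbid")

    dye_name: str
    dye_e_m_mv: float
    dye_wavelength_nm: float
    flavin_wavelength_nm: float
    subtract_dye: bool = False
    dye_preset: str | None = None
    dye_concentration_um: float = Field(20.0, gt=0)
    dye_n_electrons: int = Field(2, ge=1)
    temperature_k: float = Field(295.0, gt=0)
    n_electrons: int = Field(2, ge=1)
    mask_lo: float = Field(0.05, ge=0, lt=1)
    mask_hi: float = Field(0.95, gt=0, le=1)
    plateau_tol_au: float = Field(1e-3, gt=0)
    plateau_window: int = Field(5, ge=1)
    band_halfwidth_nm: float = Field(0.0, ge=0)
    free_em_mv: float | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.mask_hi <= self.mask_lo:
            raise ValueError("mask_hi must exceed mask_lo")
        if self.subtract_dye and self.dye_preset is None:
            raise ValueError("subtract_dye requires dye_preset for the dye basis spectrum")
        return self

    @classmethod
    def from_yaml(cls, path) -> "ExtractConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _species_from_config(sc: SpeciesConfig, role: str) -> AssaySpecies:
    return AssaySpecies(
        couple=RedoxCouple(sc.name or sc.preset, sc.e_m_mv, sc.n_electrons),
        concentration=sc.concentration_um,
        basis=build_basis_spectrum(sc.preset),
        role=role,
    )


def assay_config_from_run_config(rc: RunConfig, seed: int | None = None) -> AssayConfig:
    times = np.arange(
        rc.time_start_min, rc.time_stop_min + rc.time_step_min / 2, rc.time_step_min
    )
    return AssayConfig(
        species=[
            _species_from_config(rc.flavin, "flavin"),
            _species_from_config(rc.reference_dye, "reference_dye"),
        ],
        electron_capacity=rc.electron_capacity_um,
        delivery_rate=rc.delivery_rate_um_per_min,
        timepoints=times,
        noise_sd=rc.noise_sd_au,
        seed=rc.seed if seed is None else seed,
        conditions=ThermoConditions(rc.temperature_k, 2),
    )


def protocol_from_extract_config(ec: ExtractConfig) -> AssayProtocol:
    dye = RedoxCouple(ec.dye_name, ec.dye_e_m_mv, ec.dye_n_electrons)
    dye_species = None
    if ec.dye_preset is not None:
        dye_species = AssaySpecies(
            couple=dye,
            concentration=ec.dye_concentration_um,
            basis=build_basis_spectrum(ec.dye_preset),
            role="reference_dye",
        )
    return AssayProtocol(
        dye=dye,
        dye_wavelength=ec.dye_wavelength_nm,
        flavin_wavelength=ec.flavin_wavelength_nm,
        subtract_dye=ec.subtract_dye,
        dye_species=dye_species,
        conditions=ThermoConditions(ec.temperature_k, ec.n_electrons),
        mask_bounds=(ec.mask_lo, ec.mask_hi),
        plateau_tol=ec.plateau_tol_au,
        plateau_window=ec.plateau_window,
        band_halfwidth=ec.band_halfwidth_nm,
        free_em=ec.free_em_mv,
    )


def config_hash(config: BaseModel) -> str:
    """Stable short hash of a config for provenance records."""
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_provenance(config: BaseModel, seed: int, path) -> None:
    record = {
        "config": config.model_dump(),
        "seed": seed,
        "config_hash": config_hash(config),
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
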