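import numpy as np
import pytest

from emshift import (
    AssayConfig,
    AssayProtocol,
    AssaySpecies,
    RedoxCouple,
    ThermoConditions,
    build_basis_spectrum,
    simulate_assay,
)

AQS = RedoxCouple("AQS", -225.0)
PSF = RedoxCouple("PSF", -252.0)


@pytest.fixture
def cond295():
    return ThermoConditions(295.0, 2)


@pytest.fixture
def aqs_species():
    return AssaySpecies(AQS, 20.0, build_basis_spectrum("AQS"), "reference_dye")


@pytest.fixture
def psf_species():
    return AssaySpecies(PSF, 20.0, build_basis_spectrum("PSF"), "reference_dye")


def make_flavin(e_m, preset="free-FAD", conc=20.0, n_electrons=2):
    return AssaySpecies(
        RedoxCouple("flavin", e_m, n_electrons), conc, build_basis_spectrum(preset), "flavin"
    )


def make_config(flavin, dye, *, noise_sd=0.0, seed=0, cond=ThermoConditions(295.0, 2), **kw):
    return AssayConfig([flavin, dye], noise_sd=noise_sd, seed=seed, conditions=cond, **kw)


def aqs_protocol(cond=ThermoConditions(295.0, 2), **kw):
    """Dye read at the ligand isosbestic (335 nm), ligand at the dye
    isosbestic (355 nm); no subtraction needed."""
    return AssayProtocol(
        dye=AQS, dye_wavelength=335.0, flavin_wavelength=355.0, conditions=cond, **kw
    )


def psf_protocol(psf_species, cond=ThermoConditions(295.0, 2), **kw):
    """Dye read at 540 nm, ligand at 456 nm with explicit dye subtraction."""
    return AssayProtocol(
        dye=PSF,
        dye_wavelength=540.0,
        flavin_wavelength=456.0,
        subtract_dye=True,
        dye_species=psf_species,
        conditions=cond,
        **kw,
    )


@pytest.fixture
def free_fad_aqs_run(aqs_species, cond295):
    """Noiseless free-ligand run: flavin -209 mV against the -225 mV dye."""
    cfg = make_config(make_flavin(-209.0), aqs_species, cond=cond295)
    return simulate_assay(cfg), cfg


@pytest.fixture
def conc_grid():
    return np.geomspace(1e-8, 1e-3, 16)
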