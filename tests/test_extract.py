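import numpy as np
import pytest

from emshift import (
    AssaySpecies,
    FractionTrace,
    RedoxCouple,
    ThermoConditions,
    build_basis_spectrum,
    detect_plateau,
    electron_schedule,
    em_bound,
    em_from_fit,
    fit_nernst,
    fraction_oxidized_trace,
    nernst_prefactor,
    nernst_terms,
    partition_electrons,
    run_em_pipeline,
    semiquinone_check,
    simulate_assay,
    subtract_reference_contribution,
)
from emshift.extract import NernstFit, fraction_from_values
from emshift.simulate import TimeSeriesSpectra

from .conftest import AQS, PSF, aqs_protocol, make_config, make_flavin, psf_protocol


def constant_series(n_times=12, value=0.3):
    wl = np.arange(290.0, 751.0)
    a = np.full((n_times, wl.size), value)
    return TimeSeriesSpectra(np.arange(float(n_times)), wl, a)


class TestDetectPlateau:
    def test_constant_series_index_zero(self):
        assert detect_plateau(constant_series()) == 0

    def test_never_settling_returns_last_with_warning(self):
        wl = np.arange(290.0, 751.0)
        a = np.linspace(0, 1, 30)[:, None] * np.ones(wl.size)
        ts = TimeSeriesSpectra(np.arange(30.0), wl, a)
        with pytest.warns(UserWarning, match="never settled"):
            assert detect_plateau(ts, tol=1e-6) == 29

    def test_noiseless_run_settles_at_full_reduction(self, free_fad_aqs_run):
        ts, cfg = free_fad_aqs_run
        idx = detect_plateau(ts)
        delivered = electron_schedule(cfg)
        assert delivered[idx] >= cfg.acceptor_capacity

    def test_too_few_timepoints_rejected(self):
        wl = np.arange(290.0, 751.0)
        ts = TimeSeriesSpectra(np.array([0.0]), wl, np.zeros((1, wl.size)))
        with pytest.raises(ValueError):
            detect_plateau(ts)


class TestFractionTrace:
    def test_anchors_exact(self, free_fad_aqs_run):
        ts, _ = free_fad_aqs_run
        i_red = detect_plateau(ts)
        trace = fraction_oxidized_trace(ts, 355.0, 0, i_red)
        assert trace.fraction_oxidized[0] == 1.0
        assert trace.fraction_oxidized[i_red] == 0.0

    def test_midway_absorbance_gives_half(self):
        values = np.array([1.0, 0.75, 0.5, 0.25, 0.0])
        frac = fraction_from_values(values, 0, 4)
        assert frac[2] == 0.5

    def test_matches_simulator_fractions(self, free_fad_aqs_run, cond295):
        ts, cfg = free_fad_aqs_run
        i_red = detect_plateau(ts)
        trace = fraction_oxidized_trace(ts, 355.0, 0, i_red)
        delivered = np.minimum(electron_schedule(cfg), cfg.acceptor_capacity)
        truth = np.array(
            [1.0 - partition_electrons(float(d), cfg.species, cond295)[0][0] for d in delivered]
        )
        assert np.allclose(trace.fraction_oxidized, truth, atol=1e-6)

    def test_degenerate_anchors_rejected(self):
        ts = constant_series()
        with pytest.raises(ValueError, match="500"):
            fraction_oxidized_trace(ts, 500.0, 0, 5)

    def test_off_grid_wavelength_rejected(self, free_fad_aqs_run):
        ts, _ = free_fad_aqs_run
        with pytest.raises(ValueError, match="not on grid"):
            fraction_oxidized_trace(ts, 355.5, 0, 10)


class TestSubtractReference:
    def _psf_run(self, psf_species, cond295, flavin_em=-251.0):
        flavin = make_flavin(flavin_em, preset="C14U-bound-flavin")
        cfg = make_config(flavin, psf_species, cond=cond295)
        return simulate_assay(cfg), cfg

    def test_zero_dye_concentration_is_identity(self, psf_species, cond295):
        ts, _ = self._psf_run(psf_species, cond295)
        trace = FractionTrace(ts.times, np.linspace(1, 0, ts.times.size), "reference_dye", 540.0)
        tiny_dye = AssaySpecies(PSF, 1e-12, psf_species.basis, "reference_dye")
        corrected = subtract_reference_contribution(ts, 456.0, trace, tiny_dye)
        assert np.allclose(corrected, ts.absorbance[:, ts.index_of(456.0)], atol=1e-10)

    def test_recovers_flavin_only_signal(self, psf_species, cond295):
        ts, cfg = self._psf_run(psf_species, cond295)
        i_red = detect_plateau(ts)
        dye_trace = fraction_oxidized_trace(ts, 540.0, 0, i_red, "reference_dye")
        corrected = subtract_reference_contribution(ts, 456.0, dye_trace, psf_species)
        flavin = cfg.species[0]
        idx = flavin.basis.index_of(456.0)
        delivered = np.minimum(electron_schedule(cfg), cfg.acceptor_capacity)
        expected = []
        for d in delivered:
            f_red = partition_electrons(float(d), cfg.species, cond295)[0][0]
            expected.append(
                flavin.concentration
                * ((1 - f_red) * flavin.basis.eps_ox[idx] + f_red * flavin.basis.eps_red[idx])
            )
        assert np.allclose(corrected, expected, atol=1e-6)

    def test_fully_oxidized_frame_removes_ox_contribution(self, psf_species, cond295):
        ts, _ = self._psf_run(psf_species, cond295)
        i_red = detect_plateau(ts)
        dye_trace = fraction_oxidized_trace(ts, 540.0, 0, i_red, "reference_dye")
        corrected = subtract_reference_contribution(ts, 456.0, dye_trace, psf_species)
        idx = psf_species.basis.index_of(456.0)
        removed = ts.absorbance[0, ts.index_of(456.0)] - corrected[0]
        assert removed == pytest.approx(
            psf_species.concentration * psf_species.basis.eps_ox[idx], abs=1e-9
        )

    def test_missing_dye_basis_instructive_error(self, psf_species, cond295):
        ts, _ = self._psf_run(psf_species, cond295)
        trace = FractionTrace(ts.times, np.linspace(1, 0, ts.times.size), "reference_dye", 540.0)
        with pytest.raises(ValueError, match="dye-only"):
            subtract_reference_contribution(ts, 456.0, trace, None)


class TestNernstTerms:
    def test_half_oxidized_is_zero(self, cond295):
        trace = FractionTrace(np.array([0.0]), np.array([0.5]), "flavin", 355.0)
        assert nernst_terms(trace, cond295)[0] == 0.0

    def test_90_percent_at_prefactor_12p5(self):
        cond = ThermoConditions(290.0, 2)
        trace = FractionTrace(np.array([0.0]), np.array([0.9]), "flavin", 355.0)
        term = nernst_terms(trace, cond)[0]
        assert term == pytest.approx(nernst_prefactor(cond) * np.log(9.0))
        assert term == pytest.approx(27.5, abs=0.1)

    def test_boundary_fractions_flagged_not_dropped(self, cond295):
        trace = FractionTrace(
            np.arange(4.0), np.array([1.0, 0.5, 0.0, -0.1]), "flavin", 355.0
        )
        terms = nernst_terms(trace, cond295)
        assert np.isnan(terms[[0, 2, 3]]).all()
        assert np.isfinite(terms[1])


class TestFitNernst:
    def _traces_from_run(self, ts, dye_wl=335.0, flavin_wl=355.0):
        i_red = detect_plateau(ts)
        dye = fraction_oxidized_trace(ts, dye_wl, 0, i_red, "reference_dye")
        flavin = fraction_oxidized_trace(ts, flavin_wl, 0, i_red, "flavin")
        return flavin, dye

    def test_identical_couples_give_slope_one_intercept_zero(self, cond295):
        # same midpoint on both axes: the paired terms lie on y = x
        dye = AssaySpecies(
            RedoxCouple("AQS", -220.0), 20.0, build_basis_spectrum("AQS"), "reference_dye"
        )
        ts = simulate_assay(make_config(make_flavin(-220.0), dye, cond=cond295))
        flavin_tr, dye_tr = self._traces_from_run(ts)
        fit = fit_nernst(flavin_tr, dye_tr, cond295)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept_b == pytest.approx(0.0, abs=1e-9)

    def test_psf_complex_intercept_plus_18(self, psf_species, cond295):
        cfg = make_config(make_flavin(-234.0, "C14U-bound-flavin"), psf_species, cond=cond295)
        ts = simulate_assay(cfg)
        res = run_em_pipeline([ts], psf_protocol(psf_species, cond295))
        fit = res.fits[0]
        assert fit.intercept_b == pytest.approx(18.0, abs=0.1)
        assert fit.slope == pytest.approx(1.0, abs=0.01)

    def test_free_fad_aqs_intercept_plus_16(self, free_fad_aqs_run, cond295):
        ts, _ = free_fad_aqs_run
        flavin_tr, dye_tr = self._traces_from_run(ts)
        fit = fit_nernst(flavin_tr, dye_tr, cond295)
        assert fit.intercept_b == pytest.approx(16.0, abs=0.1)

    def test_too_few_points_reports_count(self, cond295):
        flavin = FractionTrace(np.arange(3.0), np.array([1.0, 0.5, 0.0]), "flavin", 355.0)
        dye = FractionTrace(np.arange(3.0), np.array([1.0, 0.6, 0.0]), "reference_dye", 335.0)
        with pytest.raises(ValueError, match="only 1 paired"):
            fit_nernst(flavin, dye, cond295)

    def test_one_electron_dye_gives_half_slope(self, cond295):
        # dye couple transfers one electron while terms use the ligand's
        # two-electron prefactor: slope halves
        dye = AssaySpecies(
            RedoxCouple("1e-dye", -225.0, n_electrons=1),
            20.0,
            build_basis_spectrum("AQS"),
            "reference_dye",
        )
        ts = simulate_assay(make_config(make_flavin(-215.0), dye, cond=cond295))
        flavin_tr, dye_tr = self._traces_from_run(ts)
        fit = fit_nernst(flavin_tr, dye_tr, cond295)
        assert fit.slope == pytest.approx(0.5, abs=0.01)


class TestEmFromFit:
    def _fit(self, b):
        return NernstFit(np.empty(0), np.empty(0), 1.0, b, 1.0, np.empty(0, dtype=bool))

    def test_zero_intercept_returns_dye_em(self):
        assert em_from_fit(self._fit(0.0), AQS) == -225.0

    def test_plus_one_with_psf(self):
        assert em_from_fit(self._fit(1.0), PSF) == -251.0

    def test_plus_16_with_aqs(self):
        assert em_from_fit(self._fit(16.0), AQS) == -209.0


class TestSemiquinoneCheck:
    def test_two_electron_run_passes(self, free_fad_aqs_run):
        ts, _ = free_fad_aqs_run
        assert semiquinone_check(ts).passed

    def test_mid_run_600nm_spike_fails(self, free_fad_aqs_run):
        ts, _ = free_fad_aqs_run
        a = ts.absorbance.copy()
        sel = (ts.wavelengths >= 590) & (ts.wavelengths <= 610)
        a[len(ts.times) // 2, sel] += 0.05
        spiked = TimeSeriesSpectra(ts.times, ts.wavelengths, a, ts.provenance)
        check = semiquinone_check(spiked)
        assert not check.passed
        assert check.max_excess_au == pytest.approx(0.05, abs=1e-3)

    def test_infinite_threshold_always_passes(self, free_fad_aqs_run):
        ts, _ = free_fad_aqs_run
        a = ts.absorbance.copy()
        a[5, :] += 10.0
        spiked = TimeSeriesSpectra(ts.times, ts.wavelengths, a, ts.provenance)
        assert semiquinone_check(spiked, threshold=np.inf).passed


class TestPipeline:
    def test_three_identical_runs_zero_sd(self, free_fad_aqs_run, cond295):
        ts, _ = free_fad_aqs_run
        res = run_em_pipeline([ts, ts, ts], aqs_protocol(cond295))
        assert res.sd == 0.0
        assert res.n_replicates == 3
        assert res.e_m == pytest.approx(-209.0, abs=0.2)

    def test_noisy_triplicate_within_2mv(self, psf_species, cond295):
        from emshift import BindingPair

        true_em = em_bound(-211.0, BindingPair(1e-7, 23e-7), cond295)
        runs = []
        for seed in (1, 2, 3):
            cfg = make_config(
                make_flavin(true_em, "C14U-bound-flavin"),
                psf_species,
                noise_sd=0.003,
                seed=seed,
                cond=cond295,
            )
            runs.append(simulate_assay(cfg))
        with pytest.warns(UserWarning):  # noisy series never strictly settles
            res = run_em_pipeline(runs, psf_protocol(psf_species, cond295, free_em=-211.0))
        assert res.e_m == pytest.approx(true_em, abs=2.0)
        assert round(res.delta_em_vs_free) == pytest.approx(-40, abs=2)

    def test_mixed_dyes_rejected(self, free_fad_aqs_run, psf_species, cond295):
        ts_aqs, _ = free_fad_aqs_run
        cfg = make_config(make_flavin(-251.0, "C14U-bound-flavin"), psf_species, cond=cond295)
        ts_psf = simulate_assay(cfg)
        with pytest.raises(ValueError, match="mixed reference dyes"):
            run_em_pipeline([ts_aqs, ts_psf], aqs_protocol(cond295))

    def test_empty_run_list_rejected(self, cond295):
        with pytest.raises(ValueError, match="at least one"):
            run_em_pipeline([], aqs_protocol(cond295))

    @pytest.mark.parametrize("flavin_em", [-209.0, -215.0, -225.0, -240.0])
    def test_noiseless_recovery_grid_aqs(self, flavin_em, aqs_species, cond295):
        cfg = make_config(make_flavin(flavin_em), aqs_species, cond=cond295)
        res = run_em_pipeline([simulate_assay(cfg)], aqs_protocol(cond295))
        assert abs(res.e_m - flavin_em) < 0.2
        assert 0.99 <= res.fits[0].slope <= 1.01

    def test_mask_tightening_changes_little(self, free_fad_aqs_run, cond295):
        ts, _ = free_fad_aqs_run
        loose = run_em_pipeline([ts], aqs_protocol(cond295, mask_bounds=(0.05, 0.95)))
        tight = run_em_pipeline([ts], aqs_protocol(cond295, mask_bounds=(0.10, 0.90)))
        assert abs(loose.e_m - tight.e_m) < 0.1
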