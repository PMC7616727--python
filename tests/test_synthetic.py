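import math

import numpy as np
import pytest

from dynmrs.dynamic import get_model, model_ball_two_sticks, parse_config
from dynmrs.fitting import FitOptions, fit_dynamic, fit_independent
from dynmrs.io import FIDSeries
from dynmrs.synthetic import (
    DMRS_BVALS,
    DMRS_TRUTH,
    MEGA_METABOLITES,
    MULTIB_BVALS,
    PseudoBasisSpec,
    ScenarioSpec,
    fibonacci_directions,
    gen_dmrs_directions,
    gen_dmrs_multib,
    gen_fmrs_cohort,
    gen_fmrs_spectrum,
    gen_mega,
    gen_two_peak,
    matched_filter_noise_sd,
    measure_snr,
    mega_basis,
    mega_diff_basis,
)


class TestPseudoBasisSpec:
    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            PseudoBasisSpec({"x": [(1.0, -0.5, 0.0)]})

    def test_antiphase_via_phase(self, grid):
        spec = PseudoBasisSpec({"x": [(3.0, 1.0, math.pi)]}, linewidth_hz=2.0)
        basis = spec.build(grid)
        assert basis.fids[0, 0].real == pytest.approx(-1.0)


class TestScenarioSpec:
    def test_unknown_case_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("cs9_nope", 1)

    def test_seed_mandatory(self):
        with pytest.raises(ValueError):
            ScenarioSpec("cs1_toy", None)


class TestGenTwoPeak:
    def test_truth_ratio_is_20_percent(self):
        _, _, truth = gen_two_peak(0.1, 20.0, seed=0)
        b0, b1 = truth["beta"]["peakB"]
        assert b1 / b0 == pytest.approx(0.2)

    def test_shape_and_plateau_structure(self):
        series, tvar, truth = gen_two_peak(0.1, np.inf, seed=0)
        assert series.n_transients == 64
        nl = truth["noiseless"]
        # transients 1-16 and 49-64 (rest blocks) share one expected spectrum
        assert np.allclose(nl[0], nl[15])
        assert np.allclose(nl[0], nl[63])
        assert not np.allclose(nl[0], nl[32])

    def test_separation_outside_window_rejected(self):
        with pytest.raises(ValueError):
            gen_two_peak(10.0, 20.0, seed=0)

    def test_bit_reproducible(self):
        s1, _, _ = gen_two_peak(0.1, 20.0, seed=42)
        s2, _, _ = gen_two_peak(0.1, 20.0, seed=42)
        assert np.array_equal(s1.transients, s2.transients)


class TestGenFmrsSpectrum:
    def test_only_target_modulates(self):
        _, _, truth = gen_fmrs_spectrum("NAA", 6.0, seed=0)
        for name, (b0, b1) in truth["betas"].items():
            if name == "NAA":
                assert b1 == pytest.approx(0.2 * b0)
            else:
                assert b1 == 0.0

    def test_unknown_metabolite_rejected(self):
        with pytest.raises(ValueError):
            gen_fmrs_spectrum("Unobtainium", 6.0, seed=0)

    def test_wider_linewidth_gives_broader_fitted_gamma(self):
        opts = FitOptions(ppm_range=(0.5, 4.2), baseline_order=-1)
        gammas = {}
        for lw in (6.0, 10.0):
            vals = []
            for seed in range(3):
                series, _, truth = gen_fmrs_spectrum("NAA", lw, seed=seed, snr=40.0)
                fit = fit_independent(
                    FIDSeries(series.grid, series.transients[:1]), truth["basis"], opts
                )[0]
                vals.append(fit["gamma_0"])
            gammas[lw] = np.mean(vals)
        assert gammas[10.0] > gammas[6.0]

    def test_seed_reproducible(self):
        a, _, _ = gen_fmrs_spectrum("Glu", 6.0, seed=9)
        b, _, _ = gen_fmrs_spectrum("Glu", 6.0, seed=9)
        assert np.array_equal(a.transients, b.transients)


class TestGenMega:
    def test_nineteen_metabolites(self):
        basis = mega_basis()
        assert basis.n_metabolites == 19
        assert set(basis.names) == set(MEGA_METABOLITES)

    def test_off_half_variance(self):
        on, off, offh, truth = gen_mega(5.0, 100.0, seed=3)
        res_pair = off.transients[0] - truth["noiseless_off"]
        res_half = offh.transients[0] - truth["noiseless_off"]
        v_pair = np.var(np.concatenate([res_pair.real, res_pair.imag]))
        v_half = np.var(np.concatenate([res_half.real, res_half.imag]))
        assert v_half / v_pair == pytest.approx(0.5, rel=0.15)

    def test_diff_of_non_edited_metabolites_vanishes(self):
        basis = mega_basis()
        off_b, on_b = basis.per_timepoint
        for name in ("Cr", "PCr", "Ins", "Lac", "Tau"):
            k = basis.names.index(name)
            assert np.allclose(on_b.fids[k], off_b.fids[k])
        # and the edited ones do differ
        for name in ("GABA", "Glu", "Gln", "NAA"):
            k = basis.names.index(name)
            assert not np.allclose(on_b.fids[k], off_b.fids[k])

    def test_diff_basis_restricted_to_edited(self):
        db = mega_diff_basis()
        assert set(db.names) == {"GABA", "Glu", "Gln", "NAA"}

    def test_noiseless_diff_fit_recovers_gaba(self):
        on, off, offh, truth = gen_mega(5.0, np.inf, seed=0)
        basis = truth["basis"]
        db = mega_diff_basis(basis)
        diff = truth["noiseless_on"] - truth["noiseless_off"]
        opts = FitOptions(ppm_range=(0.5, 4.2), baseline_order=2)
        fit = fit_independent(FIDSeries(basis.grid, diff), db, opts)[0]
        assert fit["conc_GABA"] == pytest.approx(truth["conc"]["GABA"], rel=1e-3)

    def test_measured_snr_within_10_percent(self):
        # NAA-singlet matched-filter SNR: measure on the NAA component plus
        # the actual noise realization of the generated OFF transient
        target = 60.0
        on, off, offh, truth = gen_mega(5.0, target, seed=5)
        basis = truth["basis"]
        k = basis.names.index("NAA")
        naa_only = (
            basis.per_timepoint[0].fids[k]
            * np.exp(-truth["gamma"] * basis.grid.tau)
            * truth["conc"]["NAA"]
        )
        noise = off.transients[0] - truth["noiseless_off"]
        got = measure_snr(naa_only + noise, off.grid, 5.0)
        assert got == pytest.approx(target, rel=0.10)


class TestGenDmrsDirections:
    @pytest.mark.parametrize("n_dir", [6, 60])
    def test_transient_count(self, n_dir):
        series, tvar, truth = gen_dmrs_directions(n_dir, seed=0)
        assert series.n_transients == 2 * n_dir + 1
        assert tvar["b"][0] == 0.0

    def test_invalid_direction_count(self):
        with pytest.raises(ValueError):
            gen_dmrs_directions(12, seed=0)

    def test_b0_unattenuated(self):
        series, tvar, truth = gen_dmrs_directions(6, seed=0, snr=np.inf)
        basis = truth["basis"]
        conc0 = np.array([DMRS_TRUTH[n][0] for n in basis.names])
        expected = (conc0 @ basis.fids) * np.exp(-truth["gamma"] * basis.grid.tau)
        assert np.allclose(truth["noiseless"][0], expected)

    def test_attenuation_matches_closed_form_along_stick(self):
        c0, f1, f2, d, t1, p1, t2, p2 = DMRS_TRUTH["NAA"]
        from dynmrs.dynamic import spherical_to_cartesian

        v1 = spherical_to_cartesian(np.asarray(t1), np.asarray(p1))
        b = DMRS_BVALS[1]
        s = model_ball_two_sticks(f1, f2, d, (t1, p1, t2, p2), b, v1)
        a2 = float(v1 @ spherical_to_cartesian(np.asarray(t2), np.asarray(p2)))
        expected = (
            (1 - f1 - f2) * math.exp(-b * d)
            + f1 * math.exp(-b * d)
            + f2 * math.exp(-b * d * a2**2)
        )
        assert s == pytest.approx(expected)

    def test_60_direction_noise_variance_10x(self):
        _, _, t6 = gen_dmrs_directions(6, seed=0)
        _, _, t60 = gen_dmrs_directions(60, seed=0)
        assert (t60["noise_sd"] / t6["noise_sd"]) ** 2 == pytest.approx(10.0)

    def test_directions_unit_norm_and_deterministic(self):
        d1 = fibonacci_directions(60)
        d2 = fibonacci_directions(60)
        assert np.array_equal(d1, d2)
        assert np.allclose(np.linalg.norm(d1, axis=1), 1.0)


class TestGenDmrsMultib:
    def test_b_grid_endpoints(self):
        series, tvar, truth = gen_dmrs_multib(seed=0)
        assert tvar["b"][0] == pytest.approx(0.02)
        assert tvar["b"][-1] == pytest.approx(50.0)
        assert len(tvar["b"]) == 7

    def test_macromolecule_log_signal_linear_in_b(self):
        b = MULTIB_BVALS
        amp, adc = 8.0, 0.004
        vals = get_model("exp").evaluate(np.array([amp, adc]), {"b": b})
        slope = np.polyfit(b, np.log(vals), 1)[0]
        assert slope == pytest.approx(-adc)
        assert np.allclose(np.polyval([slope, math.log(amp)], b), np.log(vals))

    def test_noiseless_biexponential_recovery(self):
        series, tvar, truth = gen_dmrs_multib(seed=1, snr=np.inf)
        cfg = parse_config(
            {
                "behaviors": {
                    "conc_NAA": {"model": "biexp", "covariates": ["b"]},
                    "conc_Ins": {"model": "biexp", "covariates": ["b"]},
                    "conc_MM": {"model": "exp", "covariates": ["b"]},
                    "baseline_re_0": {"model": "exp_offset", "covariates": ["b"]},
                }
            }
        )
        res = fit_dynamic(series, truth["basis"], cfg, tvar, FitOptions(baseline_order=0))
        for met in ("NAA", "Ins"):
            kind, th = truth["params"][met]
            for suffix, v in zip(("amp", "frac", "adc1", "adc2"), th):
                assert res[f"conc_{met}_{suffix}"] == pytest.approx(v, rel=1e-3), (met, suffix)


class TestGenFmrsCohort:
    def test_design_has_four_regressors(self):
        scans, design, truth = gen_fmrs_cohort(2, seed=0, n_transients=40)
        assert design.X.shape[1] == 4
        assert len(scans) == 2

    def test_control_condition_truth_betas_zero(self):
        scans, design, truth = gen_fmrs_cohort(2, seed=0, n_transients=40)
        stim_cols = [design.regressor_names.index(c) for c in ("stimA", "stimB")]
        for scan_truth in truth["per_scan"]:
            if scan_truth["condition"] == "control":
                assert np.all(scan_truth["betas"][:, stim_cols] == 0.0)
                assert np.all(scan_truth["gamma_beta"][stim_cols] == 0.0)

    def test_gamma_stimulation_effect_negative_in_stim_scans(self):
        scans, design, truth = gen_fmrs_cohort(2, seed=0, n_transients=40)
        stim_cols = [design.regressor_names.index(c) for c in ("stimA", "stimB")]
        stim_truths = [t for t in truth["per_scan"] if t["condition"] == "stim"]
        for t in stim_truths:
            assert np.all(t["gamma_beta"][stim_cols] < 0.0)

    def test_reproducible(self):
        a, _, _ = gen_fmrs_cohort(2, seed=7, n_transients=40)
        b, _, _ = gen_fmrs_cohort(2, seed=7, n_transients=40)
        assert np.array_equal(a[0][0].transients, b[0][0].transients)


class TestNoiseCalibration:
    def test_matched_filter_snr_round_trip(self, rng):
        from dynmrs.synthetic import MEGA_GRID, gamma_for_linewidth, mega_basis

        basis = mega_basis()
        grid = basis.grid
        lw = 7.0
        gamma = gamma_for_linewidth(lw)
        k = basis.names.index("NAA")
        ref = basis.per_timepoint[0].fids[k] * np.exp(-gamma * grid.tau) * 12.0
        sd = matched_filter_noise_sd(ref, grid, lw, snr=50.0)
        noisy = ref + sd * (rng.standard_normal(grid.n_points)
                            + 1j * rng.standard_normal(grid.n_points))
        assert measure_snr(noisy, grid, lw) == pytest.approx(50.0, rel=0.10)
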