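import numpy as np
import pytest

from dynmrs.dynamic import ParameterMapping, parse_config
from dynmrs.fitting import (
    DynamicProblem,
    FitOptions,
    estimate_covariance,
    fit_dynamic,
    fit_independent,
    init_spectral,
    initialize_dynamic,
)
from dynmrs.io import FIDSeries
from dynmrs.spectral import SpectralParams, forward_spectrum
from dynmrs.synthetic import gen_two_peak


GLM_CONFIG = {"behaviors": {"conc": {"model": "glm", "covariates": ["const", "stim"]}}}


class TestFitOptions:
    def test_validation(self):
        with pytest.raises(ValueError):
            FitOptions(ppm_range=(4.0, 1.0))
        with pytest.raises(ValueError):
            FitOptions(max_iter=0)
        with pytest.raises(ValueError):
            FitOptions(baseline_order=-2)


class TestFitIndependent:
    def test_noiseless_recovery_at_interior_point(self, two_peak):
        true = SpectralParams(
            conc=[1.3, 0.8], gamma=[4.0, 2.5], eps=[6.0, -3.0], phi0=0.1,
            phi1=5e-5, baseline=np.zeros(0),
        )
        spec = forward_spectrum(true, two_peak)
        fid = two_peak.grid.spec_to_fid(spec)
        series = FIDSeries(two_peak.grid, fid)
        fit = fit_independent(series, two_peak, FitOptions(baseline_order=-1))[0]
        assert fit.converged
        expect = {
            "conc_A": 1.3, "conc_B": 0.8, "gamma_0": 4.0, "gamma_1": 2.5,
            "eps_0": 6.0, "eps_1": -3.0, "phi0": 0.1, "phi1": 5e-5,
        }
        for k, v in expect.items():
            assert fit[k] == pytest.approx(v, rel=1e-6, abs=1e-8), k

    def test_identical_transients_give_identical_estimates(self, two_peak, rng):
        fid = two_peak.fids.sum(axis=0)
        fid = fid + 0.01 * (rng.standard_normal(len(fid)) + 1j * rng.standard_normal(len(fid)))
        series = FIDSeries(two_peak.grid, np.stack([fid, fid]))
        fits = fit_independent(series, two_peak, FitOptions(baseline_order=-1))
        assert np.allclose(fits[0].free_params, fits[1].free_params)

    def test_baseline_near_zero_at_high_snr(self, two_peak, rng):
        # MC mean of the fitted baseline coefficients is within 3 SE of zero
        n_rep = 20
        noiseless = 2.0 * two_peak.fids.sum(axis=0)
        sd = 0.02 * np.abs(noiseless).max()
        ests = []
        for r in range(n_rep):
            fid = noiseless + sd * (
                rng.standard_normal(len(noiseless)) + 1j * rng.standard_normal(len(noiseless))
            )
            fit = fit_independent(
                FIDSeries(two_peak.grid, fid), two_peak, FitOptions(baseline_order=1)
            )[0]
            ests.append([fit[f"baseline_{p}_{i}"] for p in ("re", "im") for i in range(2)])
        ests = np.array(ests)
        se = ests.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(ests.mean(axis=0)) <= 3.5 * se)


class TestInitSpectral:
    def test_shift_estimate_within_one_bin(self, singlet_basis):
        grid = singlet_basis.grid
        hz_per_bin = grid.bandwidth / grid.n_points
        eps_true = 2 * np.pi * 6.0  # 6 Hz shift
        fid = singlet_basis.fids[0] * np.exp(-grid.tau * 1j * eps_true)
        p0 = init_spectral(fid, singlet_basis, FitOptions(baseline_order=-1))
        assert abs(p0.eps[0] - eps_true) <= 2 * np.pi * hz_per_bin

    def test_zero_signal_gives_zero_conc(self, two_peak):
        p0 = init_spectral(np.zeros(two_peak.grid.n_points, complex), two_peak,
                           FitOptions(baseline_order=-1))
        assert np.allclose(p0.conc, 0.0)
        assert p0.phi0 == 0.0 and p0.phi1 == 0.0

    def test_deterministic(self, two_peak, rng):
        fid = two_peak.fids.sum(axis=0) + 0.05 * rng.standard_normal(two_peak.grid.n_points)
        a = init_spectral(fid, two_peak, FitOptions())
        b = init_spectral(fid, two_peak, FitOptions())
        assert np.array_equal(a.conc, b.conc)
        assert a.gamma[0] == b.gamma[0] and a.eps[0] == b.eps[0]


class TestFitDynamic:
    def test_all_variable_matches_independent_objective(self, rng):
        series, tvar, truth = gen_two_peak(0.08, 15.0, seed=11, n_transients=6)
        basis = truth["basis"]
        opts = FitOptions(baseline_order=-1)
        ind = fit_independent(series, basis, opts)
        obj_ind = sum(f.diagnostics["rss"] for f in ind)
        cfg = parse_config(
            {"behaviors": {c: "variable" for c in ("conc", "gamma", "eps", "phi0", "phi1")}}
        )
        dyn = fit_dynamic(series, basis, cfg, tvar, opts)
        assert dyn.diagnostics["objective"] == pytest.approx(obj_ind, rel=1e-6)

    def test_noiseless_toy_recovers_20_percent_increase(self):
        series, tvar, truth = gen_two_peak(0.1, np.inf, seed=1)
        cfg = parse_config(GLM_CONFIG)
        res = fit_dynamic(series, truth["basis"], cfg, tvar, FitOptions(baseline_order=-1))
        ratio = res["conc_peakB_beta1"] / res["conc_peakB_beta0"]
        assert ratio == pytest.approx(0.2, rel=1e-4)

    def test_single_transient_all_fixed_equals_independent(self, two_peak, rng):
        fid = two_peak.fids.sum(axis=0) + 0.02 * (
            rng.standard_normal(two_peak.grid.n_points)
            + 1j * rng.standard_normal(two_peak.grid.n_points)
        )
        series = FIDSeries(two_peak.grid, fid)
        opts = FitOptions(baseline_order=-1)
        ind = fit_independent(series, two_peak, opts)[0]
        dyn = fit_dynamic(series, two_peak, parse_config({"behaviors": {}}), None, opts)
        assert dyn.param_names == ind.param_names
        assert np.allclose(dyn.free_params, ind.free_params, atol=1e-6)

    def test_dynamic_has_fewer_parameters_than_independent(self):
        series, tvar, truth = gen_two_peak(0.1, 20.0, seed=2, n_transients=8)
        basis = truth["basis"]
        opts = FitOptions(baseline_order=-1)
        ind = fit_independent(series, basis, opts)
        n_ind = sum(len(f.param_names) for f in ind)
        dyn = fit_dynamic(series, basis, parse_config(GLM_CONFIG), tvar, opts)
        assert len(dyn.param_names) < n_ind

    def test_mapped_params_per_transient(self):
        series, tvar, truth = gen_two_peak(0.1, np.inf, seed=1, n_transients=8)
        res = fit_dynamic(series, truth["basis"], parse_config(GLM_CONFIG), tvar,
                          FitOptions(baseline_order=-1))
        assert len(res.mapped_params) == 8
        assert res.mapped_params[4].conc[1] == pytest.approx(1.2, rel=1e-4)

    def test_time_variable_length_mismatch(self, two_peak):
        from dynmrs.io import TimeVariable

        series = FIDSeries(two_peak.grid, np.zeros((4, two_peak.grid.n_points), complex))
        tvar = TimeVariable({"const": np.ones(5), "stim": np.zeros(5)})
        with pytest.raises(ValueError):
            fit_dynamic(series, two_peak, parse_config(GLM_CONFIG), tvar)


class TestInitializeDynamic:
    def _mapping(self, truth, tvar, T):
        return ParameterMapping(
            parse_config(GLM_CONFIG), truth["basis"], tvar, T, baseline_order=-1
        )

    def test_glm_inversion_exact_on_noiseless_series(self):
        series, tvar, truth = gen_two_peak(0.1, np.inf, seed=1, n_transients=16)
        basis = truth["basis"]
        opts = FitOptions(baseline_order=-1)
        ind = fit_independent(series, basis, opts)
        mapping = self._mapping(truth, tvar, 16)
        theta0 = initialize_dynamic("invert", mapping, independent_fits=ind)
        names = mapping.theta_names
        assert theta0[names.index("conc_peakB_beta0")] == pytest.approx(1.0, abs=1e-6)
        assert theta0[names.index("conc_peakB_beta1")] == pytest.approx(0.2, abs=1e-6)

    def test_values_strategy_echoes_input(self):
        series, tvar, truth = gen_two_peak(0.1, 10.0, seed=1, n_transients=4)
        mapping = self._mapping(truth, tvar, 4)
        v = np.arange(mapping.n_free, dtype=float)
        assert np.array_equal(
            initialize_dynamic("values", mapping, user_values=v), v
        )
        with pytest.raises(ValueError):
            initialize_dynamic("values", mapping, user_values=v[:-1])

    def test_unknown_strategy(self):
        series, tvar, truth = gen_two_peak(0.1, 10.0, seed=1, n_transients=4)
        mapping = self._mapping(truth, tvar, 4)
        with pytest.raises(ValueError):
            initialize_dynamic("bogus", mapping)


class TestEstimateCovariance:
    def test_orthonormal_jacobian_identity(self, rng):
        # orthonormal columns, residuals scaled for sigma-hat = 1
        q, _ = np.linalg.qr(rng.standard_normal((50, 3)))
        r = rng.standard_normal(50)
        r *= np.sqrt((50 - 3) / (r @ r))
        cov, sd, diag = estimate_covariance(q, r)
        assert np.allclose(cov, np.eye(3), atol=1e-10)
        assert sd == pytest.approx(1.0)
        assert not diag["degenerate"]

    def test_rank_deficient_flagged(self, rng):
        col = rng.standard_normal(30)
        J = np.stack([col, 2 * col], axis=1)
        cov, _, diag = estimate_covariance(J, rng.standard_normal(30))
        assert diag["degenerate"]
        assert np.all(np.isfinite(cov))

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_covariance(rng.standard_normal((3, 5)), rng.standard_normal(3))


class TestNonConvergenceFlag:
    def test_flagged_not_raised(self, two_peak, rng):
        fid = two_peak.fids.sum(axis=0) + 0.5 * (
            rng.standard_normal(two_peak.grid.n_points)
            + 1j * rng.standard_normal(two_peak.grid.n_points)
        )
        series = FIDSeries(two_peak.grid, fid)
        # one iteration cannot converge; must return a flagged result
        fits = fit_independent(series, two_peak, FitOptions(baseline_order=-1, max_iter=1))
        assert len(fits) == 1  # no exception
        assert "n_iter" in fits[0].diagnostics
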