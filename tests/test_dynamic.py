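import math

import numpy as np
import pytest

from dynmrs.dynamic import (
    Behavior,
    DesignMatrix,
    DynamicConfig,
    DynamicParams,
    ParameterMapping,
    convolve_design,
    get_model,
    glover_hrf,
    map_gradient,
    map_parameters,
    model_ball_two_sticks,
    model_biexp,
    model_exp,
    model_exp_offset,
    model_glm,
    parse_config,
    register_model,
    spherical_to_cartesian,
)
from dynmrs.io import FormatError, TimeVariable


@pytest.fixture
def glm_tvar():
    stim = np.zeros(64)
    stim[16:48] = 1.0
    return TimeVariable({"const": np.ones(64), "stim": stim}, kind="design_matrix")


@pytest.fixture
def glm_config():
    return parse_config(
        {"behaviors": {"conc": {"model": "glm", "covariates": ["const", "stim"]}}}
    )


class TestParseConfig:
    def test_toml_and_json_dialects(self):
        toml_text = """
[behaviors]
gamma = "fixed"
phi0 = "variable"
[behaviors.conc]
model = "glm"
covariates = ["const", "stim"]
[bounds]
gamma_0 = [0.0, 50.0]
"""
        cfg = parse_config(toml_text)
        assert cfg.behaviors["phi0"].kind == "variable"
        assert cfg.behaviors["conc"].model == "glm"
        assert cfg.bounds["gamma_0"] == (0.0, 50.0)
        cfg2 = parse_config(
            '{"behaviors": {"phi0": "variable"}, "bounds": {"x": [null, 1]}}'
        )
        assert cfg2.behaviors["phi0"].kind == "variable"
        assert cfg2.bounds["x"] == (-np.inf, 1.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError):
            parse_config({"behaviors": {"conc": {"model": "nope", "covariates": []}}})

    def test_malformed_bounds_rejected(self):
        with pytest.raises(FormatError):
            parse_config({"behaviors": {}, "bounds": {"a": [1.0, 0.0]}})

    def test_plugin_registration_hook(self, glm_tvar, two_peak):
        class Quadratic(get_model("exp").__class__.__base__):
            name = "quad"

            def param_suffixes(self, cov):
                return ["a"]

            def evaluate(self, theta, cov):
                t = np.asarray(cov["const"])
                return np.asarray(theta)[..., 0, None] * t**2

            def gradient(self, theta, cov):
                t = np.asarray(cov["const"])
                return (t**2)[:, None]

        register_model(Quadratic())
        cfg = parse_config(
            {"behaviors": {"phi0": {"model": "quad", "covariates": ["const"]}}}
        )
        mapping = ParameterMapping(cfg, two_peak, glm_tvar, 64, baseline_order=-1)
        assert "phi0_a" in mapping.theta_names

    def test_free_parameter_count_formula(self, glm_config, glm_tvar, two_peak):
        # conc bound to a 2-covariate GLM, nuisances fixed:
        # 2K + (gamma, eps per group) + phi0 + phi1
        mapping = ParameterMapping(glm_config, two_peak, glm_tvar, 64, baseline_order=-1)
        K, G = two_peak.n_metabolites, two_peak.n_groups
        assert mapping.n_free == 2 * K + 2 * G + 2

    def test_variable_phi0_gives_T_parameters(self, glm_tvar, two_peak):
        cfg = parse_config({"behaviors": {"phi0": "variable"}})
        mapping = ParameterMapping(cfg, two_peak, glm_tvar, 64, baseline_order=-1)
        assert sum(n.startswith("phi0_t") for n in mapping.theta_names) == 64

    @pytest.mark.parametrize(
        "behaviors,expected",
        [
            ({}, "fixed"),
            ({"conc": "variable"}, "variable"),
            ({"conc": "variable", "conc_A": "fixed"}, "fixed"),
        ],
    )
    def test_most_specific_behavior_wins(self, behaviors, expected):
        cfg = DynamicConfig({k: Behavior(v) if isinstance(v, str) else v
                             for k, v in behaviors.items()})
        assert cfg.resolve("conc_A", "conc").kind == expected


class TestMapping:
    def test_fixed_constant_across_time(self, glm_tvar, two_peak):
        cfg = parse_config({"behaviors": {}})
        mapping = ParameterMapping(cfg, two_peak, glm_tvar, 64, baseline_order=-1)
        theta = np.arange(mapping.n_free, dtype=float) + 1.0
        p0 = mapping.map_parameters(theta, 0)
        p63 = mapping.map_parameters(theta, 63)
        assert np.allclose(p0.conc, p63.conc)
        assert p0.conc[0] == pytest.approx(theta[mapping.theta_names.index("conc_A")])

    def test_glm_dot_product(self, glm_config, glm_tvar, two_peak):
        mapping = ParameterMapping(glm_config, two_peak, glm_tvar, 64, baseline_order=-1)
        theta = np.zeros(mapping.n_free)
        theta[mapping.theta_names.index("conc_A_beta0")] = 1.0
        theta[mapping.theta_names.index("conc_A_beta1")] = 0.2
        assert mapping.map_parameters(theta, 0).conc[0] == pytest.approx(1.0)
        assert mapping.map_parameters(theta, 32).conc[0] == pytest.approx(1.2)

    def test_exp_model_at_b_zero(self, two_peak):
        tvar = TimeVariable({"b": np.array([0.0, 1.0, 3.0])}, kind="custom")
        cfg = parse_config({"behaviors": {"conc": {"model": "exp", "covariates": ["b"]}}})
        mapping = ParameterMapping(cfg, two_peak, tvar, 3, baseline_order=-1)
        theta = np.zeros(mapping.n_free)
        theta[mapping.theta_names.index("conc_A_amp")] = 2.0
        theta[mapping.theta_names.index("conc_A_adc")] = 0.5
        assert mapping.map_parameters(theta, 0).conc[0] == pytest.approx(2.0)
        assert mapping.map_parameters(theta, 1).conc[0] == pytest.approx(2 * math.exp(-0.5))

    def test_index_out_of_range(self, glm_config, glm_tvar, two_peak):
        mapping = ParameterMapping(glm_config, two_peak, glm_tvar, 64, baseline_order=-1)
        with pytest.raises(IndexError):
            mapping.map_parameters(np.zeros(mapping.n_free), 64)

    def test_map_gradient_finite_difference(self, glm_config, glm_tvar, two_peak, rng):
        mapping = ParameterMapping(glm_config, two_peak, glm_tvar, 64, baseline_order=-1)
        theta = rng.uniform(0.5, 2.0, mapping.n_free)
        t = 20
        J = mapping.map_gradient(theta, t)

        def spectral_vector(th):
            p = mapping.map_parameters(th, t)
            return np.concatenate([p.conc, p.gamma, p.eps, [p.phi0, p.phi1], p.baseline])

        for j in range(mapping.n_free):
            h = 1e-6 * max(abs(theta[j]), 1.0)
            d = np.zeros(mapping.n_free)
            d[j] = h
            fd = (spectral_vector(theta + d) - spectral_vector(theta - d)) / (2 * h)
            assert np.abs(J[:, j] - fd).max() <= 1e-6 * max(np.abs(fd).max(), 1.0)

    def test_all_fixed_jacobian_is_selection_pattern(self, glm_tvar, two_peak):
        cfg = parse_config({"behaviors": {}})
        mapping = ParameterMapping(cfg, two_peak, glm_tvar, 4, baseline_order=-1)
        J = mapping.map_gradient(np.ones(mapping.n_free), 2)
        assert np.array_equal(J, np.eye(mapping.n_free))

    def test_glm_gradient_is_design_row(self, glm_config, glm_tvar, two_peak, rng):
        mapping = ParameterMapping(glm_config, two_peak, glm_tvar, 64, baseline_order=-1)
        t = 30
        J1 = mapping.map_gradient(rng.uniform(1, 2, mapping.n_free), t)
        J2 = mapping.map_gradient(rng.uniform(1, 2, mapping.n_free), t)
        sl = next(b.sl for b in mapping.blocks if b.sparam == "conc_A")
        row = [1.0, glm_tvar["stim"][t]]
        assert np.allclose(J1[0, sl], row)
        assert np.allclose(J2[0, sl], row)  # independent of beta

    def test_variable_behavior_reproduces_any_trajectory(self, glm_tvar, two_peak, rng):
        cfg = parse_config({"behaviors": {"conc": "variable"}})
        mapping = ParameterMapping(cfg, two_peak, glm_tvar, 64, baseline_order=-1)
        target = rng.uniform(0.5, 3.0, (64, 2))
        theta = np.zeros(mapping.n_free)
        for k, name in enumerate(two_peak.names):
            for t in range(64):
                theta[mapping.theta_names.index(f"conc_{name}_t{t}")] = target[t, k]
        for t in (0, 17, 63):
            assert np.allclose(mapping.map_parameters(theta, t).conc, target[t])

    def test_module_level_wrappers(self, glm_config, glm_tvar, two_peak):
        theta = np.zeros(
            ParameterMapping(glm_config, two_peak, glm_tvar, 64, -1).n_free
        )
        p = map_parameters(glm_config, theta, glm_tvar, 0, two_peak, 64, -1)
        assert np.allclose(p.conc, 0.0)
        J = map_gradient(glm_config, theta, glm_tvar, 0, two_peak, 64, -1)
        assert J.shape[1] == len(theta)

    def test_dynamic_params_container(self, glm_config, glm_tvar, two_peak):
        mapping = ParameterMapping(glm_config, two_peak, glm_tvar, 64, -1)
        dp = DynamicParams(np.arange(mapping.n_free, dtype=float), mapping)
        assert dp["conc_A_beta0"] == 0.0
        with pytest.raises(ValueError):
            DynamicParams(np.zeros(mapping.n_free + 1), mapping)


class TestModelLibrary:
    def test_glm_examples(self):
        assert model_glm([3.0, 0.0], [1.0, 0.7]) == pytest.approx(3.0)
        assert model_glm([1.0, 0.2], [1.0, 1.0]) == pytest.approx(1.2)

    def test_glm_recovery_by_least_squares(self, rng):
        X = np.column_stack([np.ones(40), rng.standard_normal(40)])
        beta = np.array([2.0, -0.7])
        cov = {"c0": X[:, 0], "c1": X[:, 1]}
        vals = get_model("glm").evaluate(beta, cov)
        # normal-equations oracle
        expected = np.linalg.solve(X.T @ X, X.T @ vals)
        recovered = get_model("glm").invert(vals, cov)
        assert np.allclose(recovered, expected)
        assert np.allclose(recovered, beta)

    def test_exp_examples(self):
        assert model_exp(5.0, 1.3, 0.0) == pytest.approx(5.0)
        assert model_exp(1.0, 1.0, 1.0) == pytest.approx(0.36788, abs=1e-5)

    def test_biexp_with_f_one_equals_exp(self):
        b = np.linspace(0, 10, 11)
        assert np.allclose(model_biexp(2.0, 1.0, 0.4, 7.7, b), model_exp(2.0, 0.4, b))

    def test_exp_offset_limit(self):
        assert model_exp_offset(3.0, 0.5, 1.25, 1e6) == pytest.approx(1.25)

    @pytest.mark.parametrize("name,theta,cov", [
        ("glm", [1.0, -0.5], {"a": np.linspace(0, 1, 7), "b": np.ones(7)}),
        ("exp", [2.0, 0.4], {"b": np.linspace(0, 5, 7)}),
        ("exp_offset", [2.0, 0.4, 0.3], {"b": np.linspace(0, 5, 7)}),
        ("biexp", [2.0, 0.6, 0.5, 0.05], {"b": np.linspace(0, 5, 7)}),
        ("ball2sticks", [2.0, 0.3, 0.25, 0.4, 1.2, 0.5, 2.0, 2.5],
         {"b": np.array([0.0, 1.0, 3.0, 1.0]),
          "gx": np.array([0.0, 1.0, 0.0, 0.577350269]),
          "gy": np.array([0.0, 0.0, 1.0, 0.577350269]),
          "gz": np.array([0.0, 0.0, 0.0, 0.577350269])}),
    ])
    def test_model_gradients_match_central_differences(self, name, theta, cov):
        m = get_model(name)
        theta = np.asarray(theta, dtype=float)
        J = np.asarray(m.gradient(theta, cov))
        if J.ndim == 2 and J.shape[0] != len(next(iter(cov.values()))):
            J = np.broadcast_to(J, (len(next(iter(cov.values()))), len(theta)))
        for j in range(len(theta)):
            h = 1e-6 * max(abs(theta[j]), 1.0)
            d = np.zeros_like(theta)
            d[j] = h
            fd = (m.evaluate(theta + d, cov) - m.evaluate(theta - d, cov)) / (2 * h)
            denom = max(np.abs(fd).max(), 1.0)
            assert np.abs(J[..., j] - fd).max() / denom <= 1e-6, (name, j)


class TestBallTwoSticks:
    def test_pure_ball(self):
        g = np.array([0.3, 0.5, np.sqrt(1 - 0.34)])
        s = model_ball_two_sticks(0.0, 0.0, 0.4, (0.3, 1.0, 2.0, 0.5), 2.0, g)
        assert s == pytest.approx(math.exp(-2.0 * 0.4))

    def test_stick_perpendicular_no_attenuation(self):
        # stick along z, gradient along x
        s = model_ball_two_sticks(1.0, 0.0, 0.4, (0.0, 0.0, 1.0, 0.0), 3.0,
                                  np.array([1.0, 0.0, 0.0]))
        assert s == pytest.approx(1.0)

    def test_stick_parallel_full_attenuation(self):
        s = model_ball_two_sticks(1.0, 0.0, 0.4, (0.0, 0.0, 1.0, 0.0), 3.0,
                                  np.array([0.0, 0.0, 1.0]))
        assert s == pytest.approx(math.exp(-3.0 * 0.4))

    def test_antipodal_symmetry(self):
        g = np.array([0.6, -0.64, 0.48])
        g = g / np.linalg.norm(g)
        t1, p1 = 1.1, 0.4
        s1 = model_ball_two_sticks(0.4, 0.3, 0.5, (t1, p1, 2.0, 2.2), 1.0, g)
        # antipode of (theta, phi) is (pi - theta, phi + pi)
        s2 = model_ball_two_sticks(0.4, 0.3, 0.5,
                                   (math.pi - t1, p1 + math.pi, 2.0, 2.2), 1.0, g)
        assert s1 == pytest.approx(s2)

    def test_fraction_constraint_violation(self):
        with pytest.raises(ValueError):
            model_ball_two_sticks(0.7, 0.5, 0.4, (0, 0, 0, 0), 1.0,
                                  np.array([0.0, 0.0, 1.0]))

    def test_spherical_to_cartesian_unit_norm(self, rng):
        t = rng.uniform(0, np.pi, 20)
        p = rng.uniform(0, 2 * np.pi, 20)
        v = spherical_to_cartesian(t, p)
        assert np.allclose(np.linalg.norm(v, axis=-1), 1.0)


class TestHRFAndDesign:
    def test_hrf_zero_at_zero(self):
        assert glover_hrf(0.0) == 0.0
        assert np.all(glover_hrf(np.array([-1.0, -0.1])) == 0.0)

    def test_hrf_peak_near_5_4s(self):
        t = np.arange(0, 30, 0.01)
        h = glover_hrf(t)
        assert t[np.argmax(h)] == pytest.approx(5.4, abs=0.25)

    def test_hrf_undershoot(self):
        t = np.arange(0, 30, 0.01)
        h = glover_hrf(t)
        assert h.min() < 0  # second gamma lobe produces an undershoot

    def test_design_columns(self):
        d = convolve_design([[(10.0, 20.0)]], n_transients=50, tr=2.0)
        assert d.regressor_names == ["stim0", "drift", "const"]
        assert np.allclose(d.X[:, 2], 1.0)
        assert d.X[:, 1].sum() == pytest.approx(0.0, abs=1e-12)
        assert np.abs(d.X[:, 0]).max() == pytest.approx(1.0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            convolve_design([[(5.0, -1.0)]], n_transients=10, tr=2.0)

    def test_block_outside_run_rejected(self):
        with pytest.raises(ValueError):
            convolve_design([[(95.0, 20.0)]], n_transients=50, tr=2.0)

    def test_design_matrix_validation(self):
        with pytest.raises(ValueError):
            DesignMatrix(np.ones((5, 2)), ["only_one"])
        with pytest.raises(ValueError):
            DesignMatrix(np.array([[np.inf]]), ["x"])
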