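"""Monte Carlo experiment runner and comparison metrics.

Replicates share common random numbers across fitting strategies: the data
of replicate ``r`` is derived from a child seed of the experiment seed, and
every strategy sees the same replicate data.  Replicate fits of identical
structure are batched through the vectorized Levenberg-Marquardt engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from ._optim import lm_batched
from .dynamic import Behavior, DynamicConfig, ParameterMapping, parse_config
from .fitting import DynamicProblem, FitOptions, init_spectral, _params_to_theta
from .io import BasisSet, TimeVariable
from .spectral import SpectralParams
from .synthetic import (
    DMRS_TRUTH,
    ScenarioSpec,
    gen_dmrs_directions,
    gen_dmrs_multib,
    gen_mega,
    gen_two_peak,
    gen_fmrs_spectrum,
    mega_diff_basis,
    two_peak_design,
)

__all__ = [
    "MCResult",
    "run_monte_carlo",
    "run_cohort_replicate",
    "uncertainty_ratio",
    "mean_param_correlation",
    "stick_error",
    "child_seeds",
]


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds from one experiment seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0]) for c in ss.spawn(n)]


@dataclass
class MCResult:
    """Per-replicate estimates and summary metrics per fitting strategy."""

    estimates: dict[str, pd.DataFrame]
    truth: dict[str, float]
    metrics: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    n_reps: int = 0
    seed: int = 0
    n_failed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("need n_reps >= 2")
        for name, df in self.estimates.items():
            ok = df["_converged"].to_numpy(bool) if "_converged" in df else np.ones(len(df), bool)
            self.n_failed.setdefault(name, int((~ok).sum()))
            if not ok.any():
                raise RuntimeError(f"all replicates failed for strategy {name!r}")
            m: dict[str, dict[str, float]] = {}
            for p, tv in self.truth.items():
                if p not in df.columns:
                    continue
                x = df[p].to_numpy(float)[ok]
                bias = float(x.mean() - tv)
                sd = float(x.std(ddof=0))
                rmse = float(np.sqrt(np.mean((x - tv) ** 2)))
                m[p] = {"rmse": rmse, "sd": sd, "bias": bias}
            self.metrics[name] = m


def uncertainty_ratio(mc: MCResult, strategy_a: str, strategy_b: str, parameter: str) -> float:
    """SD ratio between two strategies for one parameter."""
    return mc.metrics[strategy_a][parameter]["sd"] / mc.metrics[strategy_b][parameter]["sd"]


def mean_param_correlation(mc: MCResult, strategy: str, conc_parameter: str) -> float:
    """Mean |Pearson r| between one concentration estimate and every other
    free-parameter estimate, across Monte Carlo replicates."""
    df = mc.estimates[strategy]
    ok = df["_converged"].to_numpy(bool) if "_converged" in df else np.ones(len(df), bool)
    cols = [c for c in df.columns if not c.startswith("_") and c != conc_parameter]
    x = df[conc_parameter].to_numpy(float)[ok]
    rs = []
    for c in cols:
        y = df[c].to_numpy(float)[ok]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        rs.append(abs(np.corrcoef(x, y)[0, 1]))
    return float(np.mean(rs)) if rs else 0.0


def stick_error(estimated: list[tuple[float, np.ndarray]],
                truth: list[tuple[float, np.ndarray]]) -> float:
    """Summed fraction-scaled, sign-rectified stick-vector distance.

    Sticks are matched by the permutation minimizing the total error; each
    estimated direction's sign is rectified to the closer antipode.
    """
    def one(est_f, est_v, tr_f, tr_v):
        ev = est_f * np.asarray(est_v, dtype=float)
        tv = tr_f * np.asarray(tr_v, dtype=float)
        return min(np.linalg.norm(ev - tv), np.linalg.norm(-ev - tv))

    best = np.inf
    for perm in permutations(range(len(estimated)), len(truth)):
        tot = sum(
            one(estimated[j][0], estimated[j][1], truth[i][0], truth[i][1])
            for i, j in enumerate(perm)
        )
        best = min(best, tot)
    return float(best)


# ---------------------------------------------------------------------------
# Shared machinery
# ---------------------------------------------------------------------------


def _noise_stack(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


def _lm_chunked(
    data: np.ndarray,
    basis: BasisSet,
    mapping: ParameterMapping,
    opts: FitOptions,
    theta0: np.ndarray,
    chunk: int,
):
    """Batched LM over leading replicate axis, chunked to bound memory."""
    R = data.shape[0]
    lo, hi = mapping.default_bounds()
    xs, conv = [], []
    for s in range(0, R, chunk):
        prob = DynamicProblem(data[s : s + chunk], basis, mapping, opts)
        res = lm_batched(
            prob.residual,
            prob.jacobian,
            theta0[s : s + chunk],
            lo,
            hi,
            max_iter=opts.max_iter,
            gtol=opts.gradient_tolerance,
        )
        xs.append(res.x)
        conv.append(res.converged)
    return np.concatenate(xs), np.concatenate(conv)


def _cond_basis(basis: BasisSet, c: int) -> BasisSet:
    return BasisSet(
        basis.names, basis.per_timepoint[c].fids, basis.grid, dict(basis.groups)
    )


def _static_mapping(basis: BasisSet, opts: FitOptions) -> ParameterMapping:
    return ParameterMapping(DynamicConfig({}), basis, None, 1, opts.baseline_order)


def _init_thetas(data: np.ndarray, basis: BasisSet, opts: FitOptions,
                 mapping: ParameterMapping) -> np.ndarray:
    return np.stack(
        [_params_to_theta(init_spectral(d, basis, opts), mapping) for d in data]
    )


def _df(theta_names, thetas, converged, extra: dict | None = None) -> pd.DataFrame:
    df = pd.DataFrame(thetas, columns=theta_names)
    if extra:
        for k, v in extra.items():
            df[k] = v
    df["_converged"] = converged
    return df


# ---------------------------------------------------------------------------
# CS1: toy two-peak simulation
# ---------------------------------------------------------------------------

_CS1_CONFIG = {
    "behaviors": {"conc": {"model": "glm", "covariates": ["const", "stim"]}}
}


def _run_cs1_toy(knobs, strategies, n_reps, seed):
    sep = knobs["separation_ppm"]
    snr = knobs["snr"]
    linked = knobs.get("link", "free") == "linked"
    _, tvar, truth = gen_two_peak(sep, snr, seed=0)
    basis = truth["basis"]
    if linked:
        basis = basis.with_groups({"peakA": 0, "peakB": 0})
    noiseless, sd = truth["noiseless"], truth["noise_sd"]
    T, n = noiseless.shape
    # window +/-0.5 ppm around the peak pair: no baseline, nothing outside
    centre = basis.grid.ppm_reference
    opts = FitOptions(baseline_order=-1,
                      ppm_range=(centre - sep / 2 - 0.5, centre + sep / 2 + 0.5))
    design = truth["design"]
    X = design.X

    data = np.empty((n_reps, T, n), dtype=complex)
    for r, s in enumerate(child_seeds(seed, n_reps)):
        rng = np.random.default_rng(s)
        data[r] = noiseless + sd * _noise_stack(rng, (T, n))

    # --- independent fits (always run: they are the dynamic initializer) ---
    smap = _static_mapping(basis, opts)
    flat = data.reshape(n_reps * T, n)
    # concentration init: linear projection onto the basis spectra
    grid = basis.grid
    bspec = grid.fid_to_spec(basis.fids)
    A = np.concatenate([bspec.real, bspec.imag], axis=1)  # (K, 2n)
    pinvA = np.linalg.pinv(A)
    dspec = grid.fid_to_spec(flat)
    y = np.concatenate([dspec.real, dspec.imag], axis=1)
    conc0 = np.clip(y @ pinvA, 0.0, None)  # (R*T, K)
    theta0 = np.zeros((n_reps * T, smap.n_free))
    for k, name in enumerate(basis.names):
        theta0[:, smap.theta_names.index(f"conc_{name}")] = conc0[:, k]
    th_ind, conv_ind = _lm_chunked(
        flat[:, None, :], basis, smap, opts, theta0, chunk=1600
    )
    th_ind = th_ind.reshape(n_reps, T, smap.n_free)
    conv_ind = conv_ind.reshape(n_reps, T).all(axis=1)
    iconc = {
        name: th_ind[..., smap.theta_names.index(f"conc_{name}")]
        for name in basis.names
    }
    pinvX = np.linalg.pinv(X)  # (2, T)
    beta_ind = {name: iconc[name] @ pinvX.T for name in basis.names}  # (R, 2)

    estimates = {}
    config = parse_config(_CS1_CONFIG)
    dmap = ParameterMapping(config, basis, tvar, T, opts.baseline_order)
    if "independent" in strategies:
        cols = {}
        for name in basis.names:
            cols[f"conc_{name}_beta0"] = beta_ind[name][:, 0]
            cols[f"conc_{name}_beta1"] = beta_ind[name][:, 1]
        estimates["independent"] = _df([], np.zeros((n_reps, 0)), conv_ind, cols)

    if "dynamic" in strategies:
        theta0d = np.zeros((n_reps, dmap.n_free))
        for b in dmap.blocks:
            if b.sparam.startswith("conc_"):
                theta0d[:, b.sl] = beta_ind[b.sparam[5:]]
            else:  # fixed nuisances start at the mean independent estimate
                j = smap.theta_names.index(b.sparam)
                theta0d[:, b.sl] = th_ind[:, :, j].mean(axis=1, keepdims=True)
        th_dyn, conv_dyn = _lm_chunked(data, basis, dmap, opts, theta0d, chunk=25)
        estimates["dynamic"] = _df(dmap.theta_names, th_dyn, conv_dyn)

    truth_vals = {}
    for name in basis.names:
        b0, b1 = truth["beta"][name]
        truth_vals[f"conc_{name}_beta0"] = b0
        truth_vals[f"conc_{name}_beta1"] = b1
    return MCResult(estimates, truth_vals, n_reps=n_reps, seed=seed)


def _run_cs1_full(knobs, strategies, n_reps, seed):
    target = knobs["target_metabolite"]
    lw = knobs["linewidth_hz"]
    snr = knobs.get("snr", 40.0)
    _, tvar, truth = gen_fmrs_spectrum(target, lw, seed=0, snr=snr)
    basis = truth["basis"]
    noiseless, sd = truth["noiseless"], truth["noise_sd"]
    T, n = noiseless.shape
    opts = FitOptions(ppm_range=(0.5, 4.2), baseline_order=-1)

    data = np.empty((n_reps, T, n), dtype=complex)
    for r, s in enumerate(child_seeds(seed, n_reps)):
        rng = np.random.default_rng(s)
        data[r] = noiseless + sd * _noise_stack(rng, (T, n))

    smap = _static_mapping(basis, opts)
    flat = data.reshape(n_reps * T, n)
    theta0 = np.zeros((n_reps * T, smap.n_free))
    p0 = init_spectral(noiseless[0], basis, opts)
    base = _params_to_theta(p0, smap)
    theta0[:] = base
    th_ind, conv_ind = _lm_chunked(flat[:, None, :], basis, smap, opts, theta0, chunk=200)
    th_ind = th_ind.reshape(n_reps, T, smap.n_free)
    conv_ind = conv_ind.reshape(n_reps, T).all(axis=1)
    X = truth["design"].X
    pinvX = np.linalg.pinv(X)
    estimates = {}
    if "independent" in strategies:
        cols = {}
        for name in basis.names:
            series = th_ind[..., smap.theta_names.index(f"conc_{name}")]
            beta = series @ pinvX.T
            cols[f"conc_{name}_beta0"] = beta[:, 0]
            cols[f"conc_{name}_beta1"] = beta[:, 1]
        cols["gamma_0"] = th_ind[..., smap.theta_names.index("gamma_0")].mean(axis=1)
        estimates["independent"] = _df([], np.zeros((n_reps, 0)), conv_ind, cols)
    if "dynamic" in strategies:
        config = parse_config(_CS1_CONFIG)
        dmap = ParameterMapping(config, basis, tvar, T, opts.baseline_order)
        theta0d = np.zeros((n_reps, dmap.n_free))
        for b in dmap.blocks:
            if b.sparam.startswith("conc_"):
                series = th_ind[..., smap.theta_names.index(b.sparam)]
                theta0d[:, b.sl] = series @ pinvX.T
            else:
                j = smap.theta_names.index(b.sparam)
                theta0d[:, b.sl] = th_ind[:, :, j].mean(axis=1, keepdims=True)
        th_dyn, conv_dyn = _lm_chunked(data, basis, dmap, opts, theta0d, chunk=4)
        estimates["dynamic"] = _df(dmap.theta_names, th_dyn, conv_dyn)
    truth_vals = {}
    for name in basis.names:
        b0, b1 = truth["betas"][name]
        truth_vals[f"conc_{name}_beta0"] = b0
        truth_vals[f"conc_{name}_beta1"] = b1
    truth_vals["gamma_0"] = truth["gamma"]
    return MCResult(estimates, truth_vals, n_reps=n_reps, seed=seed)


# ---------------------------------------------------------------------------
# CS2: MEGA editing strategies
# ---------------------------------------------------------------------------

_DERIVED_SUMS = {"tCr": ("Cr", "PCr"), "tNAA": ("NAA", "NAAG"), "Glx": ("Glu", "Gln")}


def _add_derived(cols: dict, names: list[str], get) -> None:
    for combo, parts in _DERIVED_SUMS.items():
        if all(p in names for p in parts):
            cols[f"conc_{combo}"] = sum(get(p) for p in parts)


def _run_cs2(knobs, strategies, n_reps, seed):
    lw = knobs["linewidth_hz"]
    snr = knobs["snr"]
    _, _, _, truth = gen_mega(lw, snr, seed=0)
    basis = truth["basis"]
    grid = basis.grid
    sd = truth["noise_sd"]
    n = grid.n_points
    opts = FitOptions(ppm_range=(0.5, 4.2), baseline_order=2)

    noise = np.empty((n_reps, 3, n), dtype=complex)
    for r, s in enumerate(child_seeds(seed, n_reps)):
        rng = np.random.default_rng(s)
        noise[r] = _noise_stack(rng, (3, n))
    on_data = truth["noiseless_on"] + sd * noise[:, 0]
    off_data = truth["noiseless_off"] + sd * noise[:, 1]
    offh_data = truth["noiseless_off"] + (sd / math.sqrt(2)) * noise[:, 2]

    estimates = {}
    off_basis = _cond_basis(basis, 0)
    on_basis = _cond_basis(basis, 1)

    def fit_static(data, fit_basis, chunk=50):
        smap = _static_mapping(fit_basis, opts)
        th0 = _init_thetas(data, fit_basis, opts, smap)
        th, conv = _lm_chunked(data[:, None, :], fit_basis, smap, opts, th0, chunk)
        return smap, th, conv

    if "OFF" in strategies:
        smap, th, conv = fit_static(offh_data, off_basis)
        cols = {
            f"conc_{m}": th[:, smap.theta_names.index(f"conc_{m}")]
            for m in basis.names
        }
        _add_derived(cols, basis.names,
                     lambda p: th[:, smap.theta_names.index(f"conc_{p}")])
        estimates["OFF"] = _df([], np.zeros((n_reps, 0)), conv, cols)

    if "DIFF" in strategies:
        dbasis = mega_diff_basis(basis)
        smap, th, conv = fit_static(on_data - off_data, dbasis)
        cols = {
            f"conc_{m}": th[:, smap.theta_names.index(f"conc_{m}")]
            for m in dbasis.names
        }
        _add_derived(cols, dbasis.names,
                     lambda p: th[:, smap.theta_names.index(f"conc_{p}")])
        estimates["DIFF"] = _df([], np.zeros((n_reps, 0)), conv, cols)

    if "DYN" in strategies:
        # Initialize from independent static fits of each condition (model
        # inversion of the shared-parameter model = their mean).
        _, th_off, cv1 = fit_static(off_data, off_basis)
        _, th_on, cv2 = fit_static(on_data, on_basis)
        theta0 = 0.5 * (th_off + th_on)
        dmap = ParameterMapping(DynamicConfig({}), basis, None, 2, opts.baseline_order)
        dyn_data = np.stack([off_data, on_data], axis=1)
        th, conv = _lm_chunked(dyn_data, basis, dmap, opts, theta0, chunk=40)
        cols = {
            f"conc_{m}": th[:, dmap.theta_names.index(f"conc_{m}")]
            for m in basis.names
        }
        _add_derived(cols, basis.names,
                     lambda p: th[:, dmap.theta_names.index(f"conc_{p}")])
        estimates["DYN"] = _df([], np.zeros((n_reps, 0)), conv, cols)

    truth_vals = {f"conc_{m}": c for m, c in truth["conc"].items()}
    for combo, parts in _DERIVED_SUMS.items():
        truth_vals[f"conc_{combo}"] = sum(truth["conc"][p] for p in parts)
    return MCResult(estimates, truth_vals, n_reps=n_reps, seed=seed)


# ---------------------------------------------------------------------------
# CS5: multi-direction diffusion
# ---------------------------------------------------------------------------

_CS5_CONFIG = {
    "behaviors": {
        "conc": {"model": "ball2sticks", "covariates": ["b", "gx", "gy", "gz"]}
    }
}


def _truth_theta_cs5(mapping: ParameterMapping, truth: dict) -> np.ndarray:
    theta = np.zeros(mapping.n_free)
    for b in mapping.blocks:
        if b.sparam.startswith("conc_"):
            theta[b.sl] = truth["params"][b.sparam[5:]]
        elif b.sparam.startswith("gamma"):
            theta[b.sl] = truth["gamma"]
    return theta


def _stick_estimates(theta: np.ndarray, mapping: ParameterMapping, name: str):
    from .dynamic import spherical_to_cartesian

    def get(suffix):
        return theta[..., mapping.theta_names.index(f"conc_{name}_{suffix}")]

    out = []
    for i in (1, 2):
        v = spherical_to_cartesian(get(f"theta{i}"), get(f"phi{i}"))
        out.append((get(f"f{i}"), v))
    return out


def _run_cs5(knobs, strategies, n_reps, seed):
    n_dir = knobs["n_dir"]
    init = knobs.get("init", "truth")
    snr = knobs.get("snr", 40.0)
    _, tvar, truth = gen_dmrs_directions(n_dir, seed=0, snr=snr)
    basis = truth["basis"]
    noiseless, sd = truth["noiseless"], truth["noise_sd"]
    T, n = noiseless.shape
    opts = FitOptions(ppm_range=(1.5, 4.3), baseline_order=-1)
    config = parse_config(_CS5_CONFIG)
    mapping = ParameterMapping(config, basis, tvar, T, opts.baseline_order)

    data = np.empty((n_reps, T, n), dtype=complex)
    for r, s in enumerate(child_seeds(seed, n_reps)):
        rng = np.random.default_rng(s)
        data[r] = noiseless + sd * _noise_stack(rng, (T, n))

    theta_truth = _truth_theta_cs5(mapping, truth)
    if init == "truth":
        theta0 = np.tile(theta_truth, (n_reps, 1))
    elif init == "invert":
        from .fitting import fit_independent, initialize_dynamic
        from .io import FIDSeries

        theta0 = np.empty((n_reps, mapping.n_free))
        for r in range(n_reps):
            indep = fit_independent(FIDSeries(basis.grid, data[r]), basis, opts)
            theta0[r] = initialize_dynamic("invert", mapping, independent_fits=indep)
    else:
        raise ValueError(f"unknown init strategy {init!r}")

    chunk = max(1, int(2e8 / (T * 2 * 400 * mapping.n_free * 8)))
    th, conv = _lm_chunked(data, basis, mapping, opts, theta0, chunk=chunk)

    truth_sticks = {}
    for name in basis.names:
        c0, f1, f2, d, t1, p1, t2, p2 = truth["params"][name]
        from .dynamic import spherical_to_cartesian

        truth_sticks[name] = [
            (f1, spherical_to_cartesian(np.asarray(t1), np.asarray(p1))),
            (f2, spherical_to_cartesian(np.asarray(t2), np.asarray(p2))),
        ]
    cols = {}
    errs = {name: np.empty(n_reps) for name in basis.names}
    for r in range(n_reps):
        for name in basis.names:
            est = _stick_estimates(th[r], mapping, name)
            errs[name][r] = stick_error(est, truth_sticks[name])
    total = np.zeros(n_reps)
    for name in basis.names:
        cols[f"stick_err_{name}"] = errs[name]
        total += errs[name]
    cols["stick_err_total"] = total
    estimates = {"dynamic": _df(mapping.theta_names, th, conv, cols)}
    truth_vals = {f"stick_err_{name}": 0.0 for name in basis.names}
    truth_vals["stick_err_total"] = 0.0
    for b in mapping.blocks:
        for j, nm in enumerate(b.names):
            truth_vals.setdefault(nm, float(theta_truth[b.sl][j]))
    return MCResult(estimates, truth_vals, n_reps=n_reps, seed=seed)


# ---------------------------------------------------------------------------
# CS6: multi-b biexponential fitting
# ---------------------------------------------------------------------------

_CS6_CONFIG = {
    "behaviors": {
        "conc_NAA": {"model": "biexp", "covariates": ["b"]},
        "conc_Ins": {"model": "biexp", "covariates": ["b"]},
        "conc_MM": {"model": "exp", "covariates": ["b"]},
        "baseline_re_0": {"model": "exp_offset", "covariates": ["b"]},
    }
}


def _run_cs6(knobs, strategies, n_reps, seed):
    snr = knobs.get("snr", 60.0)
    _, tvar, truth = gen_dmrs_multib(seed=0, snr=snr)
    basis = truth["basis"]
    noiseless, sd = truth["noiseless"], truth["noise_sd"]
    T, n = noiseless.shape
    opts = FitOptions(baseline_order=0)
    config = parse_config(_CS6_CONFIG)
    mapping = ParameterMapping(config, basis, tvar, T, opts.baseline_order)

    theta_truth = np.zeros(mapping.n_free)
    for b in mapping.blocks:
        if b.sparam.startswith("conc_"):
            theta_truth[b.sl] = truth["params"][b.sparam[5:]][1]
        elif b.sparam == "baseline_re_0":
            theta_truth[b.sl] = truth["baseline"]
        elif b.sparam.startswith("gamma"):
            theta_truth[b.sl] = truth["gamma"]

    data = np.empty((n_reps, T, n), dtype=complex)
    for r, s in enumerate(child_seeds(seed, n_reps)):
        rng = np.random.default_rng(s)
        data[r] = noiseless + sd * _noise_stack(rng, (T, n))

    theta0 = np.tile(theta_truth, (n_reps, 1))
    th, conv = _lm_chunked(data, basis, mapping, opts, theta0, chunk=10)
    estimates = {"dynamic": _df(mapping.theta_names, th, conv)}
    truth_vals = {nm: float(v) for nm, v in zip(mapping.theta_names, theta_truth)}
    return MCResult(estimates, truth_vals, n_reps=n_reps, seed=seed)


# ---------------------------------------------------------------------------
# CS3: group fMRS cohort pipeline
# ---------------------------------------------------------------------------


def run_cohort_replicate(
    n_subjects: int = 10,
    seed: int = 0,
    snr: float = 150.0,
    n_transients: int = 60,
) -> dict:
    """End-to-end group fMRS analysis of one simulated cohort.

    Fits every scan with a GLM-bound dynamic model (concentrations and
    line-broadening share the stimulus design), forms the stimulation
    contrast per metabolite, and runs the variance-weighted paired GLM
    across the stimulation and control conditions.

    Returns per-metabolite group statistics plus per-scan recovered and
    true concentration betas.
    """
    from .fitting import estimate_covariance
    from .group import group_glm, paired_design
    from .synthetic import gen_fmrs_cohort

    scans, design, truth = gen_fmrs_cohort(
        n_subjects, seed, snr=snr, n_transients=n_transients
    )
    basis = truth["basis"]
    tvar = design.to_time_variable()
    cols = design.regressor_names
    config = DynamicConfig(
        behaviors={
            "conc": Behavior("model", "glm", tuple(cols)),
            "gamma": Behavior("model", "glm", tuple(cols)),
        }
    )
    opts = FitOptions(ppm_range=(0.5, 4.2), baseline_order=-1)
    T = n_transients
    mapping = ParameterMapping(config, basis, tvar, T, opts.baseline_order)

    flat = np.stack(
        [scan.transients for pair in scans for scan in pair]
    )  # (2S, T, n)
    S = flat.shape[0]

    # heuristic initialization from each scan's mean FID
    theta0 = np.zeros((S, mapping.n_free))
    i_const = cols.index("const")
    for s in range(S):
        p0 = init_spectral(flat[s].mean(axis=0), basis, opts)
        for b in mapping.blocks:
            if b.sparam.startswith("conc_"):
                k = basis.names.index(b.sparam[5:])
                theta0[s, b.sl.start + i_const] = p0.conc[k]
            elif b.sparam.startswith("gamma"):
                theta0[s, b.sl.start + i_const] = p0.gamma[0]
            elif b.sparam.startswith("eps"):
                theta0[s, b.sl] = p0.eps[0]

    th, conv = _lm_chunked(flat, basis, mapping, opts, theta0, chunk=4)

    # first-level: summed stimulation betas per metabolite, with variance
    stim_idx = [cols.index(c) for c in cols if c.startswith("stim")]
    copes = np.zeros((S, basis.n_metabolites))
    varcopes = np.zeros((S, basis.n_metabolites))
    prob = DynamicProblem(flat, basis, mapping, opts)
    for s in range(S):
        J = prob.jacobian(th[s][None], np.array([s]))[0]
        r = prob.residual(th[s][None], np.array([s]))[0]
        cov, _, _ = estimate_covariance(J, r)
        for k, name in enumerate(basis.names):
            blk = next(b for b in mapping.blocks if b.sparam == f"conc_{name}")
            w = np.zeros(mapping.n_free)
            for j in stim_idx:
                w[blk.sl.start + j] = 1.0
            copes[s, k] = w @ th[s]
            varcopes[s, k] = max(w @ cov @ w, 1e-12)

    # group paired GLM: scans ordered (stim, control) per subject
    gdesign = paired_design(n_subjects)
    contrast = np.zeros(gdesign.X.shape[1])
    contrast[0] = 1.0
    group = {}
    for k, name in enumerate(basis.names):
        res = group_glm(copes[:, k], varcopes[:, k], gdesign, contrast)
        group[name] = {"beta": res.cope, "z": res.z, "p": res.p}

    # recovered vs true concentration betas (stim scans, const + stim cols)
    rec, tru = [], []
    for s in range(S):
        scan_truth = truth["per_scan"][s]
        for k, name in enumerate(basis.names):
            blk = next(b for b in mapping.blocks if b.sparam == f"conc_{name}")
            for j in [i_const] + stim_idx:
                rec.append(th[s, blk.sl.start + j])
                tru.append(scan_truth["betas"][k, j])
    rec, tru = np.array(rec), np.array(tru)
    return {
        "group": group,
        "recovered_betas": rec,
        "true_betas": tru,
        "beta_correlation": float(np.corrcoef(rec, tru)[0, 1]),
        "modulated": truth["modulated"],
        "converged": conv,
        "theta": th,
        "param_names": mapping.theta_names,
        "basis_names": list(basis.names),
    }


_RUNNERS = {
    "cs1_toy": _run_cs1_toy,
    "cs1_full": _run_cs1_full,
    "cs2_mega": _run_cs2,
    "cs5_dir": _run_cs5,
    "cs6_multib": _run_cs6,
}

_DEFAULT_STRATEGIES = {
    "cs1_toy": ("independent", "dynamic"),
    "cs1_full": ("independent", "dynamic"),
    "cs2_mega": ("OFF", "DIFF", "DYN"),
    "cs5_dir": ("dynamic",),
    "cs6_multib": ("dynamic",),
}


def run_monte_carlo(
    scenario: ScenarioSpec,
    strategies: list[str] | None = None,
    n_reps: int = 100,
    seed: int | None = None,
) -> MCResult:
    """Run a Monte Carlo study of one simulation scenario.

    Within each replicate every strategy sees the same data (common random
    numbers); replicates with non-converged fits are flagged and excluded
    from the metrics.
    """
    if scenario.case not in _RUNNERS:
        raise NotImplementedError(
            f"case {scenario.case!r} has no Monte Carlo runner; use the "
            "cohort pipeline for group fMRS"
        )
    strategies = list(strategies or _DEFAULT_STRATEGIES[scenario.case])
    seed = scenario.seed if seed is None else seed
    return _RUNNERS[scenario.case](scenario.knobs, strategies, n_reps, seed)
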