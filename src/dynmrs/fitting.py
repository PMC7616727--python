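"""Independent and joint dynamic fitting of transient series.

Residuals are evaluated in the frequency domain (real and imaginary parts
concatenated) over a configurable ppm window.  Both fitting routes share
one vectorized forward/Jacobian evaluation; independent fitting batches the
per-transient problems through the same Levenberg-Marquardt engine used for
the joint fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._optim import lm_batched
from .dynamic import DynamicConfig, ParameterMapping
from .io import AcquisitionGrid, BasisSet, FIDSeries, ResultsTable, TimeVariable
from .spectral import SpectralParams, aic, baseline_regressors, model_spectra

__all__ = [
    "FitOptions",
    "DynamicProblem",
    "fit_independent",
    "fit_dynamic",
    "init_spectral",
    "initialize_dynamic",
    "estimate_covariance",
]


@dataclass
class FitOptions:
    """Knobs of the nonlinear fit."""

    ppm_range: tuple[float, float] | None = None
    baseline_order: int = 2
    max_iter: int = 200
    gradient_tolerance: float = 1e-10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ppm_range is not None and not self.ppm_range[0] < self.ppm_range[1]:
            raise ValueError("ppm_range must satisfy low < high")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.baseline_order < -1:
            raise ValueError("baseline_order must be >= -1")


class DynamicProblem:
    """Windowed frequency-domain residual/Jacobian of a joint dynamic fit.

    ``data`` may carry leading batch dimensions (e.g. Monte Carlo
    replicates): shape (..., T, n_points).
    """

    def __init__(
        self,
        data: np.ndarray,
        basis: BasisSet,
        mapping: ParameterMapping,
        opts: FitOptions,
    ):
        self.basis = basis
        self.mapping = mapping
        self.opts = opts
        grid = basis.grid
        self.mask = grid.ppm_window_mask(opts.ppm_range)
        self.M = int(self.mask.sum())
        self.breg = baseline_regressors(grid, opts.baseline_order, self.mask)
        data = np.asarray(data, dtype=complex)
        if data.ndim == 1:
            data = data[None, :]
        if data.ndim == 2:  # (T, n) single problem -> explicit batch axis
            data = data[None, :, :]
        self.T = data.shape[-2]
        if self.T != mapping.T:
            raise ValueError("data transient count != mapping transient count")
        spectra = grid.fid_to_spec(data)[..., self.mask]
        self.y = spectra  # (..., T, M)
        if basis.per_timepoint is not None:
            self.fids = np.stack(
                [basis.basis_for_timepoint(t).fids for t in range(self.T)]
            )  # (T, K, n)
        else:
            self.fids = basis.fids  # (K, n)
        self.n_data = 2 * self.M * self.T

    # -- forward -----------------------------------------------------------
    def _model(self, theta: np.ndarray, want_grad: bool):
        conc, gamma, eps, phi0, phi1, bcoef = self.mapping.spectral_arrays(theta)
        return model_spectra(
            conc,
            gamma,
            eps,
            phi0,
            phi1,
            bcoef,
            self.basis,
            self.fids,
            self.mask,
            self.breg,
            want_grad=want_grad,
        )

    def residual(self, theta: np.ndarray, idx=None) -> np.ndarray:
        model, _ = self._model(theta, want_grad=False)
        y = self.y if idx is None else self.y[idx]
        r = model - y
        rr = np.concatenate([r.real, r.imag], axis=-1)  # (..., T, 2M)
        return rr.reshape(rr.shape[:-2] + (self.T * 2 * self.M,))

    def jacobian(self, theta: np.ndarray, idx=None) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        model, grads = self._model(theta, want_grad=True)
        bj = self.mapping.block_jacobians(theta)
        lead = theta.shape[:-1]
        P = self.mapping.n_free
        Jc = np.zeros(lead + (self.T, self.M, P), dtype=complex)
        basis = self.basis
        G = basis.n_groups
        nb = self.mapping.baseline_order + 1

        def add(sname: str, gs: np.ndarray):
            """gs: model gradient w.r.t. spectral param ``sname``, (..., T, M)."""
            blk = self._block_by_name[sname]
            if blk.behavior.kind == "fixed":  # Jb is all ones: skip the product
                Jc[..., :, :, blk.sl.start] += gs
                return
            Jb = np.asarray(bj[sname])  # (T, Pb) or (..., T, Pb)
            Jc[..., :, :, blk.sl] += gs[..., :, :, None] * Jb[..., :, None, :]

        if not hasattr(self, "_block_by_name"):
            self._block_by_name = {b.sparam: b for b in self.mapping.blocks}
        for k, name in enumerate(basis.names):
            add(f"conc_{name}", grads["conc"][..., k, :])
        for g in range(G):
            add(f"gamma_{g}", grads["gamma"][..., g, :])
            add(f"eps_{g}", grads["eps"][..., g, :])
        add("phi0", grads["phi0"])
        add("phi1", grads["phi1"])
        for i in range(nb):
            bl_re = np.broadcast_to(grads["baseline"][i], model.shape)
            bl_im = np.broadcast_to(grads["baseline"][nb + i], model.shape)
            add(f"baseline_re_{i}", bl_re)
            add(f"baseline_im_{i}", bl_im)
        Jr = np.concatenate([Jc.real, Jc.imag], axis=-2)  # (..., T, 2M, P)
        return Jr.reshape(lead + (self.T * 2 * self.M, P))


def estimate_covariance(
    jacobian_at_optimum: np.ndarray, residuals: np.ndarray
) -> tuple[np.ndarray, float, dict]:
    """Gauss-Newton covariance: sigma^2 (J^T J)^+ with dof-corrected noise.

    Returns (covariance, noise_sd, diagnostics); degenerate directions of a
    rank-deficient Jacobian are flagged in the diagnostics.
    """
    J = np.asarray(jacobian_at_optimum, dtype=float)
    r = np.asarray(residuals, dtype=float)
    n, P = J.shape
    if P >= n:
        raise ValueError(f"need more data points ({n}) than parameters ({P})")
    rss = float(r @ r)
    sigma2 = rss / (n - P)
    JtJ = J.T @ J
    scale = np.max(np.abs(np.diag(JtJ)))
    rank = np.linalg.matrix_rank(JtJ, tol=scale * 1e-12) if scale > 0 else 0
    cov = sigma2 * np.linalg.pinv(JtJ, rcond=1e-12)
    diagnostics = {"rank": int(rank), "degenerate": bool(rank < P), "rss": rss}
    return cov, float(np.sqrt(sigma2)), diagnostics


# ---------------------------------------------------------------------------
# Spectral initialization heuristics
# ---------------------------------------------------------------------------


def init_spectral(
    data_t: np.ndarray,
    basis: BasisSet,
    opts: FitOptions,
    fids: np.ndarray | None = None,
) -> SpectralParams:
    """Deterministic starting point for a single-transient fit.

    Phases start at zero; the global shift comes from the cross-correlation
    of the data spectrum with a unit-concentration model; broadening from a
    peak-width comparison (floored at zero); concentrations from
    non-negative least squares at those nuisances.
    """
    from scipy.optimize import nnls

    grid = basis.grid
    if fids is None:
        fids = basis.fids
    mask = grid.ppm_window_mask(opts.ppm_range)
    dspec = grid.fid_to_spec(np.asarray(data_t, dtype=complex))
    mspec = grid.fid_to_spec(fids.sum(axis=0))
    # Shift: cross-correlate magnitude spectra over +/- 0.15 ppm.
    max_bins = max(int(0.15 * grid.spectrometer_freq / (grid.bandwidth / grid.n_points)), 1)
    dm, mm = np.abs(dspec), np.abs(mspec)
    shifts = np.arange(-max_bins, max_bins + 1)
    scores = [np.dot(dm, np.roll(mm, s)) for s in shifts]
    shift_bins = shifts[int(np.argmax(scores))]
    hz_per_bin = grid.bandwidth / grid.n_points
    # Data peak sits shift_bins above the model peak; e^{-j eps tau} moves the
    # model by -eps/(2 pi) Hz, so eps = -2 pi * shift.
    eps0 = -2.0 * np.pi * shift_bins * hz_per_bin

    def peak_width_bins(spec_mag: np.ndarray) -> float:
        i = int(np.argmax(spec_mag))
        half = spec_mag[i] / 2.0
        left, right = i, i
        while left > 0 and spec_mag[left] > half:
            left -= 1
        while right < len(spec_mag) - 1 and spec_mag[right] > half:
            right += 1
        return max(right - left, 1)

    w_data = peak_width_bins(dm)
    w_model = peak_width_bins(mm)
    gamma0 = max((w_data - w_model) * hz_per_bin * np.pi, 0.0)

    G = basis.n_groups
    params0 = SpectralParams(
        conc=np.zeros(basis.n_metabolites),
        gamma=np.full(G, gamma0),
        eps=np.full(G, eps0),
        baseline=np.zeros(2 * (opts.baseline_order + 1) if opts.baseline_order >= 0 else 0),
    )
    # NNLS for concentrations at the estimated nuisances.
    tau = grid.tau
    shifted = fids * np.exp(-tau * (gamma0 + 1j * eps0))
    bspec = grid.fid_to_spec(shifted)[:, mask]
    A = np.concatenate([bspec.real, bspec.imag], axis=1).T
    y = np.concatenate([dspec[mask].real, dspec[mask].imag])
    if np.any(np.abs(y) > 0):
        conc, _ = nnls(A, y)
        params0.conc = conc
    return params0


# ---------------------------------------------------------------------------
# Independent (per-transient) fitting
# ---------------------------------------------------------------------------


def _static_mapping(basis: BasisSet, opts: FitOptions) -> ParameterMapping:
    return ParameterMapping(
        DynamicConfig(behaviors={}),
        basis,
        None,
        n_transients=1,
        baseline_order=opts.baseline_order,
    )


def _params_to_theta(p: SpectralParams, mapping: ParameterMapping) -> np.ndarray:
    theta = np.zeros(mapping.n_free)
    vals = dict(zip(
        mapping.spectral_names,
        np.concatenate([p.conc, p.gamma, p.eps, [p.phi0, p.phi1], p.baseline]),
    ))
    for b in mapping.blocks:
        theta[b.sl] = vals[b.sparam]
    return theta


def fit_independent(
    data: FIDSeries,
    basis: BasisSet,
    opts: FitOptions | None = None,
    theta0: np.ndarray | None = None,
) -> list[ResultsTable]:
    """Fit every transient separately; all per-transient problems run
    through one batched Levenberg-Marquardt call.

    Non-convergence is flagged on the returned tables, not raised.
    """
    opts = opts or FitOptions()
    T = data.n_transients
    mapping = _static_mapping(basis, opts)
    # Treat transients as the batch dimension of T single-transient problems.
    stacked = data.transients[:, None, :]  # (T, 1, n)
    problems = []
    fids_per_t = [
        basis.basis_for_timepoint(t).fids if basis.per_timepoint is not None else basis.fids
        for t in range(T)
    ]
    if theta0 is None:
        theta0 = np.stack(
            [
                _params_to_theta(
                    init_spectral(data.transients[t], basis, opts, fids=fids_per_t[t]),
                    mapping,
                )
                for t in range(T)
            ]
        )
    else:
        theta0 = np.atleast_2d(np.asarray(theta0, dtype=float))
        if theta0.shape[0] == 1:
            theta0 = np.repeat(theta0, T, axis=0)

    if basis.per_timepoint is None:
        prob = DynamicProblem(stacked, basis, mapping, opts)
        probs = [(prob, np.arange(T))]
    else:
        # Group transients sharing one condition basis so each group batches.
        probs = []
        n_cond = len(basis.per_timepoint)
        for c in range(n_cond):
            idx = np.arange(c, T, n_cond)
            sub = BasisSet(
                basis.names,
                basis.per_timepoint[c].fids,
                basis.grid,
                dict(basis.groups),
            )
            probs.append((DynamicProblem(stacked[idx], sub, mapping, opts), idx))

    lo, hi = mapping.default_bounds()
    results: list[ResultsTable | None] = [None] * T
    for prob, idx in probs:
        res = lm_batched(
            prob.residual,
            prob.jacobian,
            theta0[idx],
            lo,
            hi,
            max_iter=opts.max_iter,
            gtol=opts.gradient_tolerance,
        )
        for j, t in enumerate(idx):
            th = res.x[j]
            J = prob.jacobian(th[None, :], np.array([j]))[0]
            r = prob.residual(th[None, :], np.array([j]))[0]
            try:
                cov, sd, diag = estimate_covariance(J, r)
            except ValueError:
                cov, sd, diag = np.zeros((mapping.n_free,) * 2), np.nan, {"degenerate": True}
            rss = float(r @ r)
            results[t] = ResultsTable(
                param_names=list(mapping.theta_names),
                free_params=th,
                covariance=cov,
                aic=aic(max(rss, 1e-300), prob.n_data, mapping.n_free),
                mapped_params=[mapping.map_parameters(th, 0)],
                init_record={"strategy": "spectral_heuristic", "theta0": theta0[t]},
                converged=bool(res.converged[j]),
                diagnostics={**diag, "n_iter": int(res.n_iter[j]), "noise_sd": sd},
            )
    return results  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Dynamic (joint) fitting
# ---------------------------------------------------------------------------


def initialize_dynamic(
    strategy: str,
    mapping: ParameterMapping,
    independent_fits: list[ResultsTable] | None = None,
    user_values: np.ndarray | None = None,
) -> np.ndarray:
    """Starting free-parameter vector for a joint fit.

    ``invert``: least-squares inversion of every bound dynamic model against
    the per-transient independent estimates (fixed parameters start at the
    mean, variable parameters at the per-transient values).
    ``values``: ``user_values`` verbatim.
    """
    if strategy == "values":
        if user_values is None:
            raise ValueError("strategy 'values' requires user_values")
        th = np.asarray(user_values, dtype=float)
        if th.shape != (mapping.n_free,):
            raise ValueError(
                f"user_values has shape {th.shape}, expected ({mapping.n_free},)"
            )
        return th
    if strategy != "invert":
        raise ValueError(f"unknown initialization strategy {strategy!r}")
    if independent_fits is None:
        raise ValueError("strategy 'invert' requires independent fits")
    if len(independent_fits) != mapping.T:
        raise ValueError("need one independent fit per transient")
    theta0 = np.zeros(mapping.n_free)
    for b in mapping.blocks:
        series = np.array([fit[b.sparam] for fit in independent_fits])
        if b.behavior.kind == "fixed":
            theta0[b.sl] = series.mean()
        elif b.behavior.kind == "variable":
            theta0[b.sl] = series
        else:
            try:
                theta0[b.sl] = b.model.invert(series, b.cov)
            except Exception as e:  # noqa: BLE001
                raise RuntimeError(
                    f"inversion failed for parameter block {b.sparam!r}: {e}"
                ) from e
    return theta0


def fit_dynamic(
    data: FIDSeries,
    basis: BasisSet,
    config: DynamicConfig,
    tvar: TimeVariable | None,
    opts: FitOptions | None = None,
    init_strategy: str = "invert",
    init_values: np.ndarray | None = None,
) -> ResultsTable:
    """Joint fit of all transients under the dynamic configuration."""
    opts = opts or FitOptions()
    T = data.n_transients
    if tvar is not None and tvar.n_transients != T:
        raise ValueError("time variable length != number of transients")
    mapping = ParameterMapping(config, basis, tvar, T, baseline_order=opts.baseline_order)
    if init_strategy == "values":
        theta0 = initialize_dynamic("values", mapping, user_values=init_values)
        init_record = {"strategy": "values"}
    else:
        indep = fit_independent(data, basis, opts)
        theta0 = initialize_dynamic("invert", mapping, independent_fits=indep)
        init_record = {"strategy": "invert"}
    init_record["theta0"] = theta0.copy()

    prob = DynamicProblem(data.transients, basis, mapping, opts)
    lo, hi = mapping.default_bounds()
    res = lm_batched(
        prob.residual,
        prob.jacobian,
        theta0[None, :],
        lo,
        hi,
        max_iter=opts.max_iter,
        gtol=opts.gradient_tolerance,
    )
    th = res.x[0]
    J = prob.jacobian(th[None, :])[0]
    r = prob.residual(th[None, :])[0]
    cov, noise_sd, diag = estimate_covariance(J, r)
    rss = float(r @ r)
    return ResultsTable(
        param_names=list(mapping.theta_names),
        free_params=th,
        covariance=cov,
        aic=aic(max(rss, 1e-300), prob.n_data, mapping.n_free),
        mapped_params=[mapping.map_parameters(th, t) for t in range(T)],
        init_record=init_record,
        converged=bool(res.converged[0]),
        diagnostics={**diag, "n_iter": int(res.n_iter[0]), "noise_sd": noise_sd,
                     "objective": rss},
    )
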