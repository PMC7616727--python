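"""Forward linear-combination spectral model and its analytic gradients.

The model of one spectrum is

    s(nu) = B(nu) + exp(-j(phi0 + nu*phi1)) * sum_k c_k F[m_k(tau) * exp(-tau*(gamma_g(k) + j*eps_g(k)))]

with a complex polynomial baseline B in the frequency axis rescaled to
[-1, 1] over the fit window.  ``nu`` is in Hz, ``gamma`` in 1/s, ``eps`` in
rad/s and ``phi1`` in s.  All primitives broadcast over arbitrary leading
dimensions so that many transients (or Monte Carlo replicates) can be
evaluated in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AcquisitionGrid, BasisSet

__all__ = [
    "SpectralParams",
    "forward_spectrum",
    "spectral_gradient",
    "baseline_regressors",
    "aic",
    "gamma_to_fwhm_hz",
    "eps_to_hz",
]


@dataclass
class SpectralParams:
    """Spectral parameters of a single transient.

    ``baseline`` stores the real coefficients followed by the imaginary
    coefficients of the complex polynomial, i.e. length ``2*(order+1)``.
    """

    conc: np.ndarray
    gamma: np.ndarray
    eps: np.ndarray
    phi0: float = 0.0
    phi1: float = 0.0
    baseline: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.conc = np.atleast_1d(np.asarray(self.conc, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.eps = np.atleast_1d(np.asarray(self.eps, dtype=float))
        self.baseline = np.atleast_1d(np.asarray(self.baseline, dtype=float))
        if self.gamma.shape != self.eps.shape:
            raise ValueError("gamma and eps must have one entry per metabolite group")

    @property
    def baseline_order(self) -> int:
        return len(self.baseline) // 2 - 1

    def validate_against(self, basis: BasisSet) -> None:
        if len(self.conc) != basis.n_metabolites:
            raise ValueError(
                f"{len(self.conc)} concentrations for {basis.n_metabolites} metabolites"
            )
        if len(self.gamma) != basis.n_groups:
            raise ValueError(
                f"{len(self.gamma)} gamma values for {basis.n_groups} metabolite groups"
            )


def gamma_to_fwhm_hz(gamma: float) -> float:
    """Extra Lorentzian FWHM (Hz) contributed by broadening ``gamma`` (1/s)."""
    return gamma / np.pi


def eps_to_hz(eps: float) -> float:
    """Frequency shift in Hz corresponding to ``eps`` (rad/s)."""
    return eps / (2.0 * np.pi)


def baseline_regressors(
    grid: AcquisitionGrid, order: int, mask: np.ndarray | None = None
) -> np.ndarray:
    """(order+1, M) real polynomial regressors in nu scaled to [-1, 1].

    The scaling interval is the fit window (``mask``) so that baseline
    coefficients stay comparable across window choices.
    """
    if order < 0:
        M = int(mask.sum()) if mask is not None else grid.n_points
        return np.zeros((0, M))
    nu = grid.nu_hz if mask is None else grid.nu_hz[mask]
    lo, hi = nu[0], nu[-1]
    x = 2.0 * (nu - lo) / (hi - lo) - 1.0 if hi > lo else np.zeros_like(nu)
    return np.stack([x**p for p in range(order + 1)])


def _group_onehot(basis: BasisSet) -> np.ndarray:
    """(G, K) indicator matrix mapping metabolites to groups."""
    gidx = basis.group_index
    G = basis.n_groups
    onehot = np.zeros((G, basis.n_metabolites))
    onehot[gidx, np.arange(basis.n_metabolites)] = 1.0
    return onehot


def model_spectra(
    conc: np.ndarray,
    gamma: np.ndarray,
    eps: np.ndarray,
    phi0: np.ndarray,
    phi1: np.ndarray,
    bcoef: np.ndarray,
    basis: BasisSet,
    fids: np.ndarray,
    mask: np.ndarray,
    breg: np.ndarray,
    want_grad: bool = False,
):
    """Vectorized forward model (and gradients) over the fit window.

    Parameters broadcast over leading dimensions: ``conc`` (..., K),
    ``gamma``/``eps`` (..., G), ``phi0``/``phi1`` (...,), ``bcoef``
    (..., 2B).  A second-to-last "time" axis of length 1 broadcasts against
    full-length time axes of the other blocks (time-constant parameters).
    ``fids`` is the (possibly per-transient) basis FID stack broadcastable
    to (..., K, n).  Returns the masked complex model (..., M) and, if
    requested, a dict of gradient stacks.
    """
    grid = basis.grid
    tau = grid.tau
    gidx = basis.group_index
    gamma = np.asarray(gamma)
    eps = np.asarray(eps)
    idx = np.fft.fftshift(np.arange(grid.n_points))[mask]
    # decay is shared within a metabolite group: exponentiate per group,
    # then gather per metabolite (cheap when G << K)
    decay_g = np.exp(-tau * (gamma[..., None] + 1j * eps[..., None]))
    base = fids * decay_g[..., gidx, :]
    spec = np.fft.fft(base, axis=-1, norm="ortho")[..., idx]
    tspec = (
        np.fft.fft(tau * base, axis=-1, norm="ortho")[..., idx] if want_grad else None
    )
    conc = np.asarray(conc)
    if conc.ndim >= 2 and spec.ndim >= 3 and spec.shape[-3] == 1 < conc.shape[-2]:
        # time-constant basis spectra: plain matmul over the metabolite axis
        msum = conc @ spec[..., 0, :, :]
    else:
        lead = np.broadcast_shapes(conc.shape[:-1], spec.shape[:-2])
        msum = np.einsum(
            "...k,...km->...m",
            np.broadcast_to(conc, lead + conc.shape[-1:]),
            np.broadcast_to(spec, lead + spec.shape[-2:]),
        )
    nu = grid.nu_hz[mask]
    phase = np.exp(
        -1j * (np.asarray(phi0)[..., None] + nu * np.asarray(phi1)[..., None])
    )
    B = breg.shape[0]
    bcoef = np.asarray(bcoef)
    if B:
        bl = (
            np.einsum("...b,bm->...m", bcoef[..., :B], breg)
            + 1j * np.einsum("...b,bm->...m", bcoef[..., B:], breg)
        )
    else:
        bl = 0.0
    model = bl + phase * msum
    if not want_grad:
        return model, None

    onehot = _group_onehot(basis)
    # d/d gamma_g: phase * sum_{k in g} c_k * (-tspec_k)
    wt = conc[..., None] * (-tspec)
    ggrad = phase[..., None, :] * np.einsum("gk,...km->...gm", onehot, wt)
    grads = {
        "conc": phase[..., None, :] * spec,
        "gamma": ggrad,
        "eps": 1j * ggrad,
        "phi0": -1j * phase * msum,
        "phi1": -1j * nu * phase * msum,
        "baseline": np.concatenate([breg.astype(complex), 1j * breg]) if B else np.zeros((0, mask.sum())),
    }
    return model, grads


def forward_spectrum(
    params: SpectralParams,
    basis: BasisSet,
    grid: AcquisitionGrid | None = None,
    ppm_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Complex model spectrum of a single transient on the full axis."""
    grid = grid or basis.grid
    params.validate_against(basis)
    mask = grid.ppm_window_mask(ppm_range)
    breg = baseline_regressors(grid, params.baseline_order, mask)
    model, _ = model_spectra(
        params.conc,
        params.gamma,
        params.eps,
        np.asarray(params.phi0),
        np.asarray(params.phi1),
        params.baseline,
        basis,
        basis.fids,
        mask,
        breg,
    )
    if ppm_range is None:
        return model
    out = np.zeros(grid.n_points, dtype=complex)
    out[mask] = model
    return out


def spectral_gradient(
    params: SpectralParams,
    basis: BasisSet,
    grid: AcquisitionGrid | None = None,
    ppm_range: tuple[float, float] | None = None,
) -> dict[str, np.ndarray]:
    """Analytic gradient of the model spectrum w.r.t. every parameter block.

    Returns a dict with complex arrays: ``conc`` (K, M), ``gamma``/``eps``
    (G, M), ``phi0``/``phi1`` (M,), ``baseline`` (2B, M).
    """
    grid = grid or basis.grid
    params.validate_against(basis)
    mask = grid.ppm_window_mask(ppm_range)
    breg = baseline_regressors(grid, params.baseline_order, mask)
    _, grads = model_spectra(
        params.conc,
        params.gamma,
        params.eps,
        np.asarray(params.phi0),
        np.asarray(params.phi1),
        params.baseline,
        basis,
        basis.fids,
        mask,
        breg,
        want_grad=True,
    )
    return grads


def aic(residual_sum_squares: float, n_data: int, n_free: int) -> float:
    """Akaike information criterion under Gaussian residuals.

    ``n_data`` counts real and imaginary points separately.
    """
    if residual_sum_squares <= 0:
        raise ValueError("residual sum of squares must be > 0")
    if not (n_data > n_free >= 1):
        raise ValueError("need n_data > n_free >= 1")
    return n_data * np.log(residual_sum_squares / n_data) + 2.0 * n_free
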