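"""Batched bound-constrained Levenberg-Marquardt.

Solves many independent nonlinear least-squares problems of identical
structure in one vectorized loop (e.g. one problem per transient, or per
Monte Carlo replicate).  Box bounds are handled with an active-set
reduction (coordinates pinned at a bound with an outward gradient are
frozen out of the step); damping uses Marquardt scaling by the diagonal of
J^T J so steps are invariant to per-parameter rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LMResult", "lm_batched"]


@dataclass
class LMResult:
    x: np.ndarray  # (B, P)
    cost: np.ndarray  # (B,) sum of squared residuals
    converged: np.ndarray  # (B,) bool
    n_iter: np.ndarray  # (B,) iterations used
    message: str = ""


def lm_batched(
    residual_fn,
    jac_fn,
    x0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    max_iter: int = 200,
    ftol: float = 1e-9,
    gtol: float = 1e-10,
    lam0: float = 1e-3,
    max_trial: int = 12,
) -> LMResult:
    """Minimize ||residual_fn(x_b)||^2 for every batch item b.

    ``residual_fn(x, idx)`` maps (Ba, P) parameters (for batch items
    ``idx``) to (Ba, M) residuals; ``jac_fn(x, idx)`` to (Ba, M, P)
    Jacobians.  Residuals and Jacobians are cached so each accepted step
    triggers exactly one Jacobian evaluation.
    """
    x = np.clip(np.atleast_2d(np.asarray(x0, dtype=float)).copy(), lower, upper)
    B, P = x.shape
    all_idx = np.arange(B)
    r = residual_fn(x, all_idx)  # cached residual at current x
    M = r.shape[-1]
    cost = np.einsum("bm,bm->b", r, r)
    J = np.zeros((B, M, P))
    dirty = np.ones(B, dtype=bool)  # Jacobian stale for these items
    lam = np.full(B, lam0)
    converged = np.zeros(B, dtype=bool)
    n_iter = np.zeros(B, dtype=int)
    eyeP = np.eye(P)

    for _ in range(max_iter):
        act = np.flatnonzero(~converged)
        if act.size == 0:
            break
        n_iter[act] += 1
        upd = act[dirty[act]]
        if upd.size:
            J[upd] = jac_fn(x[upd], upd)
            dirty[upd] = False
        Ja, ra, xa = J[act], r[act], x[act]
        ca = cost[act]
        g = np.einsum("bmp,bm->bp", Ja, ra)

        # projected-gradient convergence test
        pg = g.copy()
        pg[(xa <= lower + 1e-14) & (pg > 0)] = 0.0
        pg[(xa >= upper - 1e-14) & (pg < 0)] = 0.0
        gsmall = np.max(np.abs(pg), axis=1) <= gtol * (1.0 + ca)
        if np.any(gsmall):
            converged[act[gsmall]] = True
            keep = ~gsmall
            if not np.any(keep):
                continue
            act = act[keep]
            Ja, ra, xa, ca, g = Ja[keep], ra[keep], xa[keep], ca[keep], g[keep]

        JtJ = np.einsum("bmp,bmq->bpq", Ja, Ja)
        D = np.einsum("bpp->bp", JtJ).copy()
        D = np.maximum(D, 1e-12 * np.maximum(D.max(axis=1, keepdims=True), 1e-30))
        # Freeze coordinates pinned at a bound whose gradient points outward.
        free = ~(((xa <= lower + 1e-14) & (g > 0)) | ((xa >= upper - 1e-14) & (g < 0)))
        pending = np.ones(act.size, dtype=bool)
        for _trial in range(max_trial):
            pidx = np.flatnonzero(pending)
            if pidx.size == 0:
                break
            fm = free[pidx]
            A = JtJ[pidx] + lam[act[pidx], None, None] * (D[pidx, :, None] * eyeP)
            A = A * (fm[:, :, None] & fm[:, None, :])
            A[:, np.arange(P), np.arange(P)] += ~fm
            rhs = np.where(fm, g[pidx], 0.0)
            try:
                step = -np.linalg.solve(A, rhs[..., None])[..., 0]
            except np.linalg.LinAlgError:
                A += 1e-8 * eyeP
                step = -np.linalg.solve(A, rhs[..., None])[..., 0]
            x_new = np.clip(xa[pidx] + step, lower, upper)
            r_new = residual_fn(x_new, act[pidx])
            c_new = np.einsum("bm,bm->b", r_new, r_new)
            better = c_new < ca[pidx]
            acc = pidx[better]
            if acc.size:
                gidxs = act[acc]
                x[gidxs] = x_new[better]
                r[gidxs] = r_new[better]
                rel_drop = (ca[acc] - c_new[better]) / np.maximum(ca[acc], 1e-300)
                cost[gidxs] = c_new[better]
                lam[gidxs] = np.maximum(lam[gidxs] * 0.33, 1e-12)
                converged[gidxs] |= rel_drop <= ftol
                dirty[gidxs] = True
            rej = pidx[~better]
            if rej.size:
                lam[act[rej]] = np.minimum(lam[act[rej]] * 4.0, 1e12)
                # damping saturated: accept the local minimum in place
                converged[act[rej]] |= lam[act[rej]] >= 1e12
            pending[acc] = False
            pending[rej] = ~converged[act[rej]]

    return LMResult(x=x, cost=cost, converged=converged, n_iter=n_iter)
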