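"""First-level contrasts, metabolite combination, and group-level inference.

Group inference is a closed-form variance-weighted GLM: copes are
regressed on the group design with weights 1/varcope, the residual scale is
estimated from the weighted residuals (so the equal-weight paired design
reduces exactly to the classical paired t-test), and z statistics are
obtained from the t statistic through the normal quantile map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import ResultsTable

__all__ = [
    "Contrast",
    "GroupDesign",
    "GroupResult",
    "first_level_cope",
    "percent_change_cope",
    "combine_metabolites",
    "group_glm",
    "paired_design",
]


@dataclass
class Contrast:
    """Named linear contrast over first-level free parameters."""

    name: str
    weights: dict[str, float]

    def vector(self, param_names: list[str]) -> np.ndarray:
        missing = set(self.weights) - set(param_names)
        if missing:
            raise KeyError(f"contrast references absent parameters: {sorted(missing)}")
        w = np.zeros(len(param_names))
        for k, v in self.weights.items():
            w[param_names.index(k)] = v
        return w


@dataclass
class GroupDesign:
    """One row per scan; columns are group-level explanatory variables."""

    X: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("design columns != column names")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("group design is rank deficient")


@dataclass
class GroupResult:
    beta: np.ndarray
    cope: float
    varcope: float
    t: float
    z: float
    p: float
    dof: int


def first_level_cope(fit: ResultsTable, contrast: Contrast) -> tuple[float, float]:
    """(cope, varcope) = (w' beta, w' Cov w) from a fit's free parameters."""
    w = contrast.vector(fit.param_names)
    cope = float(w @ fit.free_params)
    varcope = float(w @ fit.covariance @ w)
    return cope, varcope


def percent_change_cope(
    fit: ResultsTable, stim_param: str, const_param: str
) -> tuple[float, float]:
    """Percent change stim/baseline with delta-method variance."""
    i = fit.param_names.index(stim_param)
    j = fit.param_names.index(const_param)
    b1, b0 = fit.free_params[i], fit.free_params[j]
    if b0 == 0:
        raise ZeroDivisionError("baseline parameter is zero")
    grad = np.zeros(len(fit.param_names))
    grad[i] = 100.0 / b0
    grad[j] = -100.0 * b1 / b0**2
    return 100.0 * b1 / b0, float(grad @ fit.covariance @ grad)


def _conc_suffixes(fit: ResultsTable, met: str) -> list[str]:
    prefix = f"conc_{met}"
    out = []
    for n in fit.param_names:
        if n == prefix:
            out.append("")
        elif n.startswith(prefix + "_"):
            out.append(n[len(prefix):])
    return out


_LINEAR = {("fixed", None), ("variable", None), ("model", "glm")}


def combine_metabolites(fit: ResultsTable, names_to_sum: list[str]) -> ResultsTable:
    """Sum the concentration parameter blocks of several metabolites.

    Only defined when every named metabolite is bound to a linear dynamic
    behavior (fixed, variable, or GLM); covariances between the summed
    blocks are propagated.  Returns a reduced ResultsTable holding only the
    combined block.
    """
    behaviors = fit.diagnostics.get("behaviors", {})
    for m in names_to_sum:
        beh = behaviors.get(f"conc_{m}")
        if beh is not None and tuple(beh) not in _LINEAR:
            raise ValueError(
                f"metabolite {m!r} is bound to nonlinear model {beh[1]!r}; "
                "combination undefined"
            )
    suffixes = _conc_suffixes(fit, names_to_sum[0])
    if not suffixes:
        raise KeyError(f"no concentration parameters for {names_to_sum[0]!r}")
    for m in names_to_sum[1:]:
        if _conc_suffixes(fit, m) != suffixes:
            raise ValueError("metabolites have mismatched parameter blocks")
    combo = "+".join(names_to_sum)
    W = np.zeros((len(suffixes), len(fit.param_names)))
    for r, suf in enumerate(suffixes):
        for m in names_to_sum:
            W[r, fit.param_names.index(f"conc_{m}{suf}")] = 1.0
    beta = W @ fit.free_params
    cov = W @ fit.covariance @ W.T
    return ResultsTable(
        param_names=[f"conc_{combo}{suf}" for suf in suffixes],
        free_params=beta,
        covariance=cov,
        aic=fit.aic,
        init_record={"combined_from": list(names_to_sum)},
        converged=fit.converged,
        diagnostics={"behaviors": {f"conc_{combo}": behaviors.get(
            f"conc_{names_to_sum[0]}", ("fixed", None))}},
    )


def paired_design(n_subjects: int) -> GroupDesign:
    """Paired t-test design: condition column (+1/-1) plus subject means.

    Rows are ordered [subject0-condA, subject0-condB, subject1-condA, ...].
    """
    N = 2 * n_subjects
    X = np.zeros((N, n_subjects + 1))
    X[0::2, 0] = 1.0
    X[1::2, 0] = -1.0
    for s in range(n_subjects):
        X[2 * s : 2 * s + 2, 1 + s] = 1.0
    return GroupDesign(X, ["condition"] + [f"subject{s}" for s in range(n_subjects)])


def group_glm(
    copes: np.ndarray,
    varcopes: np.ndarray,
    design: GroupDesign,
    contrast: np.ndarray,
) -> GroupResult:
    """Variance-weighted least squares of copes on the group design."""
    y = np.asarray(copes, dtype=float)
    v = np.asarray(varcopes, dtype=float)
    if np.any(v <= 0):
        raise ValueError("varcopes must be strictly positive")
    X = design.X
    if len(y) != X.shape[0]:
        raise ValueError("number of copes != design rows")
    w = 1.0 / v
    XtW = X.T * w
    A = XtW @ X
    beta = np.linalg.solve(A, XtW @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(resid @ (w * resid)) / dof
    c = np.asarray(contrast, dtype=float)
    cov_beta = sigma2 * np.linalg.inv(A)
    cope = float(c @ beta)
    varcope = float(c @ cov_beta @ c)
    t = cope / np.sqrt(varcope) if varcope > 0 else 0.0
    p = float(2.0 * sps.t.sf(abs(t), dof))
    z = float(np.sign(t) * sps.norm.isf(max(p / 2.0, 1e-300)))
    return GroupResult(beta=beta, cope=cope, varcope=varcope, t=t, z=z, p=p, dof=dof)
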