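"""Dynamic-model library and the mapping from free dynamic parameters to
per-transient spectral parameters.

Every spectral parameter is resolved to one of three behaviors:

* ``fixed``    -- one free parameter shared by all transients,
* ``variable`` -- one free parameter per transient,
* ``model``    -- a named dynamic model of the experimental time variable,
  contributing that model's parameters to the free vector.

Behaviors are declared in a small declarative configuration (TOML or JSON)
rather than executable code; additional models can be registered through
:func:`register_model` before parsing.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import BasisSet, FormatError, TimeVariable
from .spectral import SpectralParams

__all__ = [
    "DynamicModel",
    "DynamicConfig",
    "DynamicParams",
    "DesignMatrix",
    "ParameterMapping",
    "parse_config",
    "register_model",
    "get_model",
    "model_glm",
    "model_exp",
    "model_exp_offset",
    "model_biexp",
    "model_ball_two_sticks",
    "glover_hrf",
    "convolve_design",
    "spherical_to_cartesian",
]

_UNBOUNDED = (-np.inf, np.inf)


# ---------------------------------------------------------------------------
# Model library
# ---------------------------------------------------------------------------


class DynamicModel:
    """Base class: a parametric map (theta, covariates) -> per-transient value."""

    name: str = ""

    def param_suffixes(self, cov: dict[str, np.ndarray]) -> list[str]:
        raise NotImplementedError

    def default_bounds(self, cov: dict[str, np.ndarray]) -> list[tuple[float, float]]:
        return [_UNBOUNDED] * len(self.param_suffixes(cov))

    def evaluate(self, theta: np.ndarray, cov: dict[str, np.ndarray]) -> np.ndarray:
        """theta (..., P) -> values (..., T)."""
        raise NotImplementedError

    def gradient(self, theta: np.ndarray, cov: dict[str, np.ndarray]) -> np.ndarray:
        """theta (..., P) -> Jacobian broadcastable to (..., T, P)."""
        raise NotImplementedError

    def invert(self, values: np.ndarray, cov: dict[str, np.ndarray]) -> np.ndarray:
        """Least-squares fit of the model to a per-transient value series."""
        from scipy.optimize import least_squares

        x0 = np.asarray(self._coarse_start(values, cov), dtype=float)
        lo, hi = zip(*self.default_bounds(cov))
        x0 = np.clip(x0, np.nextafter(lo, np.inf), np.nextafter(hi, -np.inf))
        res = least_squares(
            lambda th: self.evaluate(th, cov) - values,
            x0,
            jac=lambda th: self.gradient(th, cov),
            bounds=(list(lo), list(hi)),
            method="trf",
        )
        if not res.success:
            raise RuntimeError(f"inversion of model {self.name!r} failed: {res.message}")
        return res.x

    def _coarse_start(self, values, cov):  # pragma: no cover - overridden
        raise NotImplementedError


class GLMModel(DynamicModel):
    """value(t) = x_t . beta for design-matrix rows x_t."""

    name = "glm"

    @staticmethod
    def _design(cov: dict[str, np.ndarray]) -> np.ndarray:
        return np.stack([np.asarray(v, dtype=float) for v in cov.values()], axis=1)

    def param_suffixes(self, cov):
        return [f"beta{i}" for i in range(len(cov))]

    def evaluate(self, theta, cov):
        X = self._design(cov)
        return np.einsum("tr,...r->...t", X, np.asarray(theta))

    def gradient(self, theta, cov):
        return self._design(cov)

    def invert(self, values, cov):
        X = self._design(cov)
        beta, *_ = np.linalg.lstsq(X, np.asarray(values, dtype=float), rcond=None)
        return beta


class ExpModel(DynamicModel):
    """value(b) = amp * exp(-b * adc); covariate ``b``."""

    name = "exp"
    suffixes = ["amp", "adc"]

    def param_suffixes(self, cov):
        return list(self.suffixes)

    def default_bounds(self, cov):
        return [(0.0, np.inf), (0.0, np.inf)]

    @staticmethod
    def _b(cov):
        return np.asarray(cov["b"], dtype=float)

    def evaluate(self, theta, cov):
        b = self._b(cov)
        amp, adc = np.asarray(theta)[..., 0, None], np.asarray(theta)[..., 1, None]
        return amp * np.exp(-b * adc)

    def gradient(self, theta, cov):
        b = self._b(cov)
        amp, adc = np.asarray(theta)[..., 0, None], np.asarray(theta)[..., 1, None]
        e = np.exp(-b * adc)
        return np.stack([e, -amp * b * e], axis=-1)

    def _coarse_start(self, values, cov):
        b = self._b(cov)
        v = np.clip(np.asarray(values, dtype=float), 1e-12, None)
        slope, icept = np.polyfit(b, np.log(v), 1)
        return [math.exp(icept), max(-slope, 1e-6)]


class ExpOffsetModel(DynamicModel):
    """value(b) = amp * exp(-b * adc) + offset."""

    name = "exp_offset"
    suffixes = ["amp", "adc", "offset"]

    def param_suffixes(self, cov):
        return list(self.suffixes)

    def default_bounds(self, cov):
        return [_UNBOUNDED, (0.0, np.inf), _UNBOUNDED]

    def evaluate(self, theta, cov):
        b = np.asarray(cov["b"], dtype=float)
        th = np.asarray(theta)
        amp, adc, off = th[..., 0, None], th[..., 1, None], th[..., 2, None]
        return amp * np.exp(-b * adc) + off

    def gradient(self, theta, cov):
        b = np.asarray(cov["b"], dtype=float)
        th = np.asarray(theta)
        amp, adc = th[..., 0, None], th[..., 1, None]
        e = np.exp(-b * adc)
        return np.stack([e, -amp * b * e, np.broadcast_to(1.0, e.shape).copy()], axis=-1)

    def _coarse_start(self, values, cov):
        v = np.asarray(values, dtype=float)
        off = v.min()
        amp = v.max() - off
        b = np.asarray(cov["b"], dtype=float)
        return [amp if amp > 0 else 1e-6, 1.0 / max(b.max(), 1e-6), off]


class BiexpModel(DynamicModel):
    """value(b) = amp * (frac*exp(-b*adc1) + (1-frac)*exp(-b*adc2))."""

    name = "biexp"
    suffixes = ["amp", "frac", "adc1", "adc2"]

    def param_suffixes(self, cov):
        return list(self.suffixes)

    def default_bounds(self, cov):
        return [(0.0, np.inf), (0.0, 1.0), (0.0, np.inf), (0.0, np.inf)]

    def evaluate(self, theta, cov):
        b = np.asarray(cov["b"], dtype=float)
        th = np.asarray(theta)
        amp, f = th[..., 0, None], th[..., 1, None]
        d1, d2 = th[..., 2, None], th[..., 3, None]
        return amp * (f * np.exp(-b * d1) + (1 - f) * np.exp(-b * d2))

    def gradient(self, theta, cov):
        b = np.asarray(cov["b"], dtype=float)
        th = np.asarray(theta)
        amp, f = th[..., 0, None], th[..., 1, None]
        d1, d2 = th[..., 2, None], th[..., 3, None]
        e1, e2 = np.exp(-b * d1), np.exp(-b * d2)
        return np.stack(
            [
                f * e1 + (1 - f) * e2,
                amp * (e1 - e2),
                -amp * f * b * e1,
                -amp * (1 - f) * b * e2,
            ],
            axis=-1,
        )

    def _coarse_start(self, values, cov):
        amp, adc = ExpModel()._coarse_start(values, cov)
        return [amp, 0.7, adc, adc / 5.0]


def spherical_to_cartesian(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Unit vectors (..., 3) from polar angle theta and azimuth phi."""
    st, ct = np.sin(theta), np.cos(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), ct], axis=-1)


class BallTwoSticksModel(DynamicModel):
    """Ball-and-two-sticks diffusion attenuation scaling a base amplitude.

    value(b, g) = amp * [(1-f1-f2) exp(-b d)
                         + f1 exp(-b d (g.v1)^2) + f2 exp(-b d (g.v2)^2)]

    with shared diffusivity ``d`` and stick directions from spherical
    angles.  Covariates: ``b``, ``gx``, ``gy``, ``gz``.
    """

    name = "ball2sticks"
    suffixes = ["amp", "f1", "f2", "d", "theta1", "phi1", "theta2", "phi2"]

    def param_suffixes(self, cov):
        return list(self.suffixes)

    def default_bounds(self, cov):
        return [
            (0.0, np.inf),
            (0.0, 1.0),
            (0.0, 1.0),
            (0.0, np.inf),
            _UNBOUNDED,
            _UNBOUNDED,
            _UNBOUNDED,
            _UNBOUNDED,
        ]

    @staticmethod
    def _bg(cov):
        b = np.asarray(cov["b"], dtype=float)
        g = np.stack([np.asarray(cov[c], dtype=float) for c in ("gx", "gy", "gz")], axis=1)
        return b, g

    def evaluate(self, theta, cov):
        b, g = self._bg(cov)
        th = np.asarray(theta)
        amp, f1, f2, d = (th[..., i, None] for i in range(4))
        a1 = np.einsum("tj,...j->...t", g, spherical_to_cartesian(th[..., 4], th[..., 5]))
        a2 = np.einsum("tj,...j->...t", g, spherical_to_cartesian(th[..., 6], th[..., 7]))
        S = (
            (1 - f1 - f2) * np.exp(-b * d)
            + f1 * np.exp(-b * d * a1**2)
            + f2 * np.exp(-b * d * a2**2)
        )
        return amp * S

    def gradient(self, theta, cov):
        b, g = self._bg(cov)
        th = np.asarray(theta)
        amp, f1, f2, d = (th[..., i, None] for i in range(4))
        t1, p1, t2, p2 = (th[..., i] for i in range(4, 8))

        def dots(tt, pp):
            tt, pp = np.asarray(tt), np.asarray(pp)
            v = spherical_to_cartesian(tt, pp)
            dv_dt = spherical_to_cartesian(tt + np.pi / 2, pp)  # d v / d theta
            dv_dp = np.stack(
                [-np.sin(tt) * np.sin(pp), np.sin(tt) * np.cos(pp), np.zeros_like(tt)],
                axis=-1,
            )
            a = np.einsum("tj,...j->...t", g, v)
            da_dt = np.einsum("tj,...j->...t", g, dv_dt)
            da_dp = np.einsum("tj,...j->...t", g, dv_dp)
            return a, da_dt, da_dp

        a1, da1_dt, da1_dp = dots(t1, p1)
        a2, da2_dt, da2_dp = dots(t2, p2)
        eb = np.exp(-b * d)
        e1 = np.exp(-b * d * a1**2)
        e2 = np.exp(-b * d * a2**2)
        S = (1 - f1 - f2) * eb + f1 * e1 + f2 * e2
        dS_dd = -b * ((1 - f1 - f2) * eb + f1 * a1**2 * e1 + f2 * a2**2 * e2)
        c1 = -2.0 * f1 * b * d * a1 * e1
        c2 = -2.0 * f2 * b * d * a2 * e2
        return np.stack(
            [
                S,
                amp * (e1 - eb),
                amp * (e2 - eb),
                amp * dS_dd,
                amp * c1 * da1_dt,
                amp * c1 * da1_dp,
                amp * c2 * da2_dt,
                amp * c2 * da2_dp,
            ],
            axis=-1,
        )

    def invert(self, values, cov):
        """Grid search over stick angles and fractions, then bounded refinement."""
        from scipy.optimize import least_squares

        b, g = self._bg(cov)
        v = np.asarray(values, dtype=float)
        amp0 = float(np.mean(v[b == 0])) if np.any(b == 0) else float(v.max())
        if amp0 <= 0:
            raise RuntimeError("ball2sticks inversion: non-positive b=0 amplitude")
        att = np.clip(v / amp0, 1e-6, None)
        bmax = b.max()
        d0 = max(-math.log(float(np.mean(att[b == bmax]))) / bmax, 1e-4) if bmax > 0 else 0.1

        # Fibonacci hemisphere of candidate stick directions.
        n_cand = 40
        idx = np.arange(n_cand)
        z = (idx + 0.5) / n_cand
        az = idx * np.pi * (3 - np.sqrt(5))
        tt = np.arccos(z)
        cand = np.stack([tt, az % (2 * np.pi)], axis=1)
        best, best_rss = None, np.inf
        fgrid = [0.15, 0.3, 0.45]
        for i in range(n_cand):
            for jj in range(i, n_cand):
                for f1 in fgrid:
                    for f2 in fgrid:
                        if f1 + f2 > 0.95:
                            continue
                        th = np.array(
                            [amp0, f1, f2, d0, cand[i, 0], cand[i, 1], cand[jj, 0], cand[jj, 1]]
                        )
                        r = self.evaluate(th, cov) - v
                        rss = float(r @ r)
                        if rss < best_rss:
                            best_rss, best = rss, th
        lo, hi = zip(*self.default_bounds(cov))
        res = least_squares(
            lambda th: self.evaluate(th, cov) - v,
            best,
            jac=lambda th: self.gradient(th, cov),
            bounds=(list(lo), list(hi)),
            method="trf",
        )
        return res.x


MODEL_REGISTRY: dict[str, DynamicModel] = {}


def register_model(model: DynamicModel) -> None:
    """Register a custom dynamic model before config parsing."""
    MODEL_REGISTRY[model.name] = model


def get_model(name: str) -> DynamicModel:
    if name not in MODEL_REGISTRY:
        raise KeyError(f"unknown dynamic model {name!r}; registered: {sorted(MODEL_REGISTRY)}")
    return MODEL_REGISTRY[name]


for _m in (GLMModel(), ExpModel(), ExpOffsetModel(), BiexpModel(), BallTwoSticksModel()):
    register_model(_m)


# ---------------------------------------------------------------------------
# Functional model API
# ---------------------------------------------------------------------------


def model_glm(beta, x_t):
    """GLM value at one design row; gradient w.r.t. beta is ``x_t``."""
    return float(np.dot(np.asarray(beta, dtype=float), np.asarray(x_t, dtype=float)))


def model_exp(amp, adc, b):
    return amp * np.exp(-np.asarray(b, dtype=float) * adc)


def model_exp_offset(amp, adc, offset, b):
    return amp * np.exp(-np.asarray(b, dtype=float) * adc) + offset


def model_biexp(amp, frac, adc1, adc2, b):
    b = np.asarray(b, dtype=float)
    return amp * (frac * np.exp(-b * adc1) + (1 - frac) * np.exp(-b * adc2))


def model_ball_two_sticks(f1, f2, d, angles, b, g):
    """Ball-and-two-sticks attenuation (no amplitude factor).

    ``angles`` = (theta1, phi1, theta2, phi2); ``g`` is a unit direction (or
    an array of them).  Raises if the compartment fractions are infeasible.
    """
    if f1 < 0 or f2 < 0 or f1 + f2 > 1 + 1e-12 or d < 0:
        raise ValueError("require f1, f2 >= 0, f1 + f2 <= 1 and d >= 0")
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    t1, p1, t2, p2 = angles
    v1 = spherical_to_cartesian(np.asarray(t1), np.asarray(p1))
    v2 = spherical_to_cartesian(np.asarray(t2), np.asarray(p2))
    a1 = g @ v1
    a2 = g @ v2
    return (
        (1 - f1 - f2) * np.exp(-b * d)
        + f1 * np.exp(-b * d * a1**2)
        + f2 * np.exp(-b * d * a2**2)
    )


# ---------------------------------------------------------------------------
# Hemodynamic response and fMRS design construction
# ---------------------------------------------------------------------------

_GLOVER = dict(n1=6.0, t1=0.9, n2=12.0, t2=0.9, a2=0.35)


def glover_hrf(t_seconds) -> np.ndarray:
    """Double-gamma hemodynamic response, each lobe peak-normalized.

    h(t) = g1(t) - a2 * g2(t) with g_i(t) = (t / (n_i tau_i))^{n_i}
    exp(n_i - t/tau_i); peaks at 5.4 s and 10.8 s.
    """
    t = np.asarray(t_seconds, dtype=float)
    c = _GLOVER

    def lobe(n, tau):
        with np.errstate(invalid="ignore"):
            g = (t / (n * tau)) ** n * np.exp(n - t / tau)
        return np.where(t > 0, g, 0.0)

    return lobe(c["n1"], c["t1"]) - c["a2"] * lobe(c["n2"], c["t2"])


@dataclass
class DesignMatrix:
    """T x R design with named regressors."""

    X: np.ndarray
    regressor_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] != len(self.regressor_names):
            raise ValueError("design column count != number of regressor names")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design matrix entries must be finite")

    @property
    def n_transients(self) -> int:
        return self.X.shape[0]

    def to_time_variable(self) -> TimeVariable:
        return TimeVariable(
            {n: self.X[:, i] for i, n in enumerate(self.regressor_names)},
            kind="design_matrix",
        )


def convolve_design(
    stimulus_blocks: list[list[tuple[float, float]]],
    n_transients: int,
    tr: float,
    drift: bool = True,
    constant: bool = True,
    stimulus_names: list[str] | None = None,
) -> DesignMatrix:
    """HRF-convolved design: one column per stimulus boxcar train.

    ``stimulus_blocks`` holds, per stimulus regressor, (onset, duration)
    pairs in seconds.  Convolved columns are peak-normalized; the drift
    column is linear and zero-mean; the constant column is 1.
    """
    if tr <= 0:
        raise ValueError("TR must be > 0")
    run_len = n_transients * tr
    dt = min(tr, 0.1)
    n_fine = int(round(run_len / dt))
    t_fine = np.arange(n_fine) * dt
    hrf = glover_hrf(np.arange(0, 32.0, dt))
    cols, names = [], []
    for i, blocks in enumerate(stimulus_blocks):
        box = np.zeros(n_fine)
        for onset, dur in blocks:
            if dur < 0:
                raise ValueError("stimulus duration must be >= 0")
            if onset < 0 or onset + dur > run_len + 1e-9:
                raise ValueError("stimulus block outside the run")
            box[(t_fine >= onset) & (t_fine < onset + dur)] = 1.0
        conv = np.convolve(box, hrf)[:n_fine]
        sample = conv[np.round(np.arange(n_transients) * tr / dt).astype(int)]
        peak = np.abs(sample).max()
        cols.append(sample / peak if peak > 0 else sample)
        names.append(
            stimulus_names[i] if stimulus_names is not None else f"stim{i}"
        )
    if drift:
        d = np.arange(n_transients, dtype=float)
        d -= d.mean()
        d /= np.abs(d).max()
        cols.append(d)
        names.append("drift")
    if constant:
        cols.append(np.ones(n_transients))
        names.append("const")
    return DesignMatrix(np.stack(cols, axis=1), names)


# ---------------------------------------------------------------------------
# Declarative configuration
# ---------------------------------------------------------------------------

_CLASS_KEYS = ("conc", "gamma", "eps", "phi0", "phi1", "baseline")


@dataclass(frozen=True)
class Behavior:
    kind: str  # fixed | variable | model
    model: str | None = None
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in {"fixed", "variable", "model"}:
            raise FormatError(f"unknown behavior kind {self.kind!r}")
        if self.kind == "model" and not self.model:
            raise FormatError("model behavior requires a model name")


@dataclass
class DynamicConfig:
    """Per-parameter behaviors, bounds and dynamic-model bindings."""

    behaviors: dict[str, Behavior]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise FormatError(f"bounds for {name!r}: lower {lo} > upper {hi}")
        for key, beh in self.behaviors.items():
            if beh.kind == "model":
                get_model(beh.model)  # raises on unknown model

    def resolve(self, param_name: str, class_key: str) -> Behavior:
        """Most specific behavior wins: exact name > parameter class."""
        if param_name in self.behaviors:
            return self.behaviors[param_name]
        if class_key in self.behaviors:
            return self.behaviors[class_key]
        return Behavior("fixed")


def _parse_behavior(value) -> Behavior:
    if isinstance(value, str):
        return Behavior(value)
    if isinstance(value, dict):
        return Behavior(
            "model", model=value.get("model"), covariates=tuple(value.get("covariates", ()))
        )
    raise FormatError(f"cannot interpret behavior spec {value!r}")


def parse_config(path_or_text: str | Path | dict) -> DynamicConfig:
    """Parse a declarative dynamic-fit configuration (TOML, JSON or dict)."""
    if isinstance(path_or_text, dict):
        raw = path_or_text
    else:
        text = None
        p = Path(str(path_or_text))
        try:
            if p.exists():
                text = p.read_text()
        except OSError:
            pass
        if text is None:
            text = str(path_or_text)
        stripped = text.lstrip()
        if stripped.startswith("{"):
            raw = json.loads(text)
        else:
            raw = tomllib.loads(text)
    behaviors = {k: _parse_behavior(v) for k, v in raw.get("behaviors", {}).items()}
    bounds = {}
    for k, v in raw.get("bounds", {}).items():
        lo = -np.inf if v[0] is None else float(v[0])
        hi = np.inf if v[1] is None else float(v[1])
        bounds[k] = (lo, hi)
    return DynamicConfig(behaviors=behaviors, bounds=bounds)


# ---------------------------------------------------------------------------
# Free-parameter mapping
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    """One spectral parameter's binding into the free-parameter vector."""

    sparam: str  # spectral parameter name
    class_key: str
    behavior: Behavior
    sl: slice
    names: list[str]
    model: DynamicModel | None = None
    cov: dict[str, np.ndarray] | None = None


class ParameterMapping:
    """Resolved mapping free theta -> per-transient spectral parameters."""

    def __init__(
        self,
        config: DynamicConfig,
        basis: BasisSet,
        tvar: TimeVariable | None,
        n_transients: int,
        baseline_order: int = 2,
    ):
        self.config = config
        self.basis = basis
        self.tvar = tvar
        self.T = int(n_transients)
        self.baseline_order = baseline_order
        G = basis.n_groups
        sparams: list[tuple[str, str]] = []
        sparams += [(f"conc_{n}", "conc") for n in basis.names]
        sparams += [(f"gamma_{g}", "gamma") for g in range(G)]
        sparams += [(f"eps_{g}", "eps") for g in range(G)]
        sparams += [("phi0", "phi0"), ("phi1", "phi1")]
        for part in ("re", "im"):
            sparams += [
                (f"baseline_{part}_{i}", "baseline") for i in range(baseline_order + 1)
            ]
        self.spectral_names = [s for s, _ in sparams]
        self.blocks: list[_Block] = []
        pos = 0
        for sname, ckey in sparams:
            beh = config.resolve(sname, ckey)
            if beh.kind == "fixed":
                names = [sname]
                model, cov = None, None
            elif beh.kind == "variable":
                names = [f"{sname}_t{t}" for t in range(self.T)]
                model, cov = None, None
            else:
                model = get_model(beh.model)
                if tvar is None:
                    raise FormatError("model-bound parameters require a time variable")
                missing = [c for c in beh.covariates if c not in tvar.columns]
                if missing:
                    raise FormatError(f"covariates {missing} not in time variable")
                cov = {c: tvar[c] for c in beh.covariates}
                names = [f"{sname}_{s}" for s in model.param_suffixes(cov)]
            sl = slice(pos, pos + len(names))
            pos += len(names)
            self.blocks.append(_Block(sname, ckey, beh, sl, names, model, cov))
        self.n_free = pos
        self.theta_names = [n for b in self.blocks for n in b.names]
        self._index = {n: i for i, n in enumerate(self.theta_names)}

    # -- bounds ------------------------------------------------------------
    _CLASS_DEFAULT_BOUNDS = {
        "conc": (0.0, np.inf),
        "gamma": (0.0, np.inf),
    }

    def default_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.full(self.n_free, -np.inf)
        hi = np.full(self.n_free, np.inf)
        for b in self.blocks:
            if b.model is not None:
                mb = b.model.default_bounds(b.cov)
                lo[b.sl] = [x[0] for x in mb]
                hi[b.sl] = [x[1] for x in mb]
                if b.class_key == "conc" and b.model.name == "glm":
                    lo[b.sl] = -np.inf  # GLM betas of concentrations unbounded
            elif b.class_key in self._CLASS_DEFAULT_BOUNDS:
                l, h = self._CLASS_DEFAULT_BOUNDS[b.class_key]
                lo[b.sl], hi[b.sl] = l, h
        for name, (l, h) in self.config.bounds.items():
            if name in self._index:
                i = self._index[name]
                lo[i], hi[i] = l, h
        return lo, hi

    # -- evaluation --------------------------------------------------------
    def trajectories(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Per-spectral-parameter trajectories, each (..., T) or (..., 1).

        Time-constant (fixed) parameters keep a length-1 time axis so that
        downstream model evaluation can avoid redundant per-transient work.
        """
        theta = np.asarray(theta, dtype=float)
        out = {}
        for b in self.blocks:
            block = theta[..., b.sl]
            if b.behavior.kind == "fixed":
                out[b.sparam] = block  # (..., 1): broadcasts over transients
            elif b.behavior.kind == "variable":
                out[b.sparam] = block
            else:
                out[b.sparam] = b.model.evaluate(block, b.cov)
        return out

    @staticmethod
    def _stack(trajs: list[np.ndarray]) -> np.ndarray:
        """Stack per-parameter trajectories along a trailing axis.

        Trajectories of one kind may mix length-1 (time-constant) and
        length-T time axes; all are broadcast to the longest before
        stacking, so the result is (..., T_kind, n_params) with T_kind in
        {1, T}.
        """
        tmax = max(t.shape[-1] for t in trajs)
        trajs = [
            np.broadcast_to(t, t.shape[:-1] + (tmax,)) if t.shape[-1] != tmax else t
            for t in trajs
        ]
        return np.stack(trajs, axis=-1)

    def spectral_arrays(self, theta: np.ndarray):
        """Assembled (conc, gamma, eps, phi0, phi1, baseline) arrays.

        Shapes: conc (..., T', K), gamma/eps (..., T', G), phi0/phi1
        (..., T'), baseline (..., T', 2*(order+1)) where each T' is the
        full transient count, or 1 when that block is time-constant.
        """
        traj = self.trajectories(theta)
        G = self.basis.n_groups
        conc = self._stack([traj[f"conc_{n}"] for n in self.basis.names])
        gamma = self._stack([traj[f"gamma_{g}"] for g in range(G)])
        eps = self._stack([traj[f"eps_{g}"] for g in range(G)])
        phi0 = traj["phi0"]
        phi1 = traj["phi1"]
        bnames = [
            f"baseline_{part}_{i}"
            for part in ("re", "im")
            for i in range(self.baseline_order + 1)
        ]
        if bnames:
            baseline = self._stack([traj[n] for n in bnames])
        else:
            baseline = np.zeros(conc.shape[:-1] + (0,))
        return conc, gamma, eps, phi0, phi1, baseline

    def block_jacobians(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """d trajectory(t) / d theta_block, each broadcastable to (..., T, P_b)."""
        theta = np.asarray(theta, dtype=float)
        out = {}
        for b in self.blocks:
            if b.behavior.kind == "fixed":
                out[b.sparam] = np.ones((self.T, 1))
            elif b.behavior.kind == "variable":
                out[b.sparam] = np.eye(self.T)
            else:
                out[b.sparam] = b.model.gradient(theta[..., b.sl], b.cov)
        return out

    def map_parameters(self, theta: np.ndarray, t: int) -> SpectralParams:
        """SpectralParams at transient ``t`` implied by the free vector."""
        if not 0 <= t < self.T:
            raise IndexError(f"transient index {t} out of range [0, {self.T})")
        conc, gamma, eps, phi0, phi1, baseline = self.spectral_arrays(theta)

        def at(arr, vector=True):
            ax = -2 if vector else -1
            i = t if arr.shape[ax] > 1 else 0
            return arr[..., i, :] if vector else arr[..., i]

        return SpectralParams(
            conc=at(conc),
            gamma=at(gamma),
            eps=at(eps),
            phi0=float(at(phi0, vector=False)),
            phi1=float(at(phi1, vector=False)),
            baseline=at(baseline),
        )

    def map_gradient(self, theta: np.ndarray, t: int) -> np.ndarray:
        """Dense Jacobian d spectral-params(t) / d theta, (n_spectral, n_free)."""
        if not 0 <= t < self.T:
            raise IndexError(f"transient index {t} out of range [0, {self.T})")
        theta = np.asarray(theta, dtype=float)
        J = np.zeros((len(self.spectral_names), self.n_free))
        jac = self.block_jacobians(theta)
        for row, b in zip(range(len(self.blocks)), self.blocks):
            Jb = np.asarray(jac[b.sparam])
            if Jb.ndim == 2 and Jb.shape == (self.T, b.sl.stop - b.sl.start):
                J[row, b.sl] = Jb[t]
            else:
                J[row, b.sl] = np.broadcast_to(
                    Jb, (self.T, b.sl.stop - b.sl.start)
                )[t]
        return J


@dataclass
class DynamicParams:
    """A flat free-parameter vector tied to its mapping."""

    theta: np.ndarray
    mapping: ParameterMapping

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape[-1] != self.mapping.n_free:
            raise ValueError(
                f"theta length {self.theta.shape[-1]} != mapping free count "
                f"{self.mapping.n_free}"
            )

    @property
    def names(self) -> list[str]:
        return self.mapping.theta_names

    def __getitem__(self, name: str) -> float:
        return float(self.theta[..., self.mapping._index[name]])


def map_parameters(
    config: DynamicConfig,
    theta: np.ndarray,
    tvar: TimeVariable | None,
    t: int,
    basis: BasisSet,
    n_transients: int,
    baseline_order: int = 2,
) -> SpectralParams:
    """Spec-level convenience wrapper around :class:`ParameterMapping`."""
    mapping = ParameterMapping(config, basis, tvar, n_transients, baseline_order)
    return mapping.map_parameters(theta, t)


def map_gradient(
    config: DynamicConfig,
    theta: np.ndarray,
    tvar: TimeVariable | None,
    t: int,
    basis: BasisSet,
    n_transients: int,
    baseline_order: int = 2,
) -> np.ndarray:
    mapping = ParameterMapping(config, basis, tvar, n_transients, baseline_order)
    return mapping.map_gradient(theta, t)
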