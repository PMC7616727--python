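"""Synthetic dynamic MRS generators.

Each generator reproduces the statistical structure of one simulation case
study: a toy two-peak functional series, a realistic multi-metabolite brain
spectrum with stimulus-driven concentration changes, MEGA edited ON/OFF
pairs, multi-direction diffusion series, and a multi-b diffusion series
with biexponential decays.  Metabolite spectra are parametric Lorentzian
line lists (a pseudo-basis) rather than density-matrix simulations.

All generators are deterministic given their arguments and a seed; noise is
complex white Gaussian in the time domain (white per frequency bin under
the unitary transform).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamic import (
    DesignMatrix,
    convolve_design,
    model_ball_two_sticks,
    spherical_to_cartesian,
)
from .io import AcquisitionGrid, BasisSet, FIDSeries, TimeVariable

__all__ = [
    "PseudoBasisSpec",
    "ScenarioSpec",
    "gen_two_peak",
    "gen_fmrs_spectrum",
    "gen_mega",
    "gen_fmrs_cohort",
    "gen_dmrs_directions",
    "gen_dmrs_multib",
    "matched_filter_noise_sd",
    "measure_snr",
    "fibonacci_directions",
    "BRAIN_METABOLITES",
]

# ---------------------------------------------------------------------------
# Pseudo-basis construction
# ---------------------------------------------------------------------------


@dataclass
class PseudoBasisSpec:
    """Parametric stand-in for a simulated basis set.

    ``lines`` maps metabolite name -> list of (ppm, amplitude, phase)
    Lorentzian lines; amplitudes are non-negative (anti-phase lines use a
    phase of pi).  ``conditions``, when given, provides per-condition line
    lists (e.g. editing OFF/ON) with identical metabolite names.
    """

    lines: dict[str, list[tuple[float, float, float]]]
    linewidth_hz: float = 1.0
    conditions: list[dict[str, list[tuple[float, float, float]]]] | None = None

    def __post_init__(self) -> None:
        all_lists = [self.lines] + (self.conditions or [])
        for d in all_lists:
            for name, ls in d.items():
                for ppm, amp, _ in ls:
                    if amp < 0:
                        raise ValueError(
                            f"negative line amplitude for {name}; encode anti-phase "
                            "lines with phase=pi"
                        )

    def _fid(self, grid: AcquisitionGrid, ls) -> np.ndarray:
        tau = grid.tau
        decay = math.pi * self.linewidth_hz
        fid = np.zeros(grid.n_points, dtype=complex)
        for ppm, amp, phase in ls:
            nu = grid.ppm_to_hz(ppm)
            fid += amp * np.exp(1j * phase) * np.exp((2j * math.pi * nu - decay) * tau)
        return fid

    def build(self, grid: AcquisitionGrid, groups: dict[str, int] | None = None) -> BasisSet:
        names = sorted(self.lines)
        base = BasisSet(
            names,
            np.array([self._fid(grid, self.lines[n]) for n in names]),
            grid,
            dict(groups) if groups else {},
        )
        if self.conditions is None:
            return base
        per = [
            BasisSet(
                names,
                np.array([self._fid(grid, cond[n]) for n in names]),
                grid,
                dict(base.groups),
            )
            for cond in self.conditions
        ]
        return BasisSet(names, per[0].fids, grid, dict(base.groups), per)


@dataclass
class ScenarioSpec:
    """A named simulation scenario with its knobs and mandatory seed."""

    case: str
    seed: int
    knobs: dict = field(default_factory=dict)

    _CASES = ("cs1_toy", "cs1_full", "cs2_mega", "cs3_fmrs", "cs5_dir", "cs6_multib")

    def __post_init__(self) -> None:
        if self.case not in self._CASES:
            raise ValueError(f"unknown case {self.case!r}; one of {self._CASES}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


# ---------------------------------------------------------------------------
# Metabolite tables (documented stand-in values)
# ---------------------------------------------------------------------------

# name: (concentration / mM, [(ppm, amplitude)...]); amplitudes are rough
# proton-count weights of the main resonances within the 0.5-4.3 ppm window.
BRAIN_METABOLITES: dict[str, tuple[float, list[tuple[float, float]]]] = {
    "Ala": (1.2, [(1.47, 3.0), (3.78, 1.0)]),
    "Asc": (1.2, [(3.73, 1.0), (4.01, 1.0)]),
    "Asp": (2.5, [(2.65, 1.0), (2.80, 1.0), (3.89, 1.0)]),
    "Cr": (4.5, [(3.027, 3.0), (3.913, 2.0)]),
    "PCr": (4.0, [(3.029, 3.0), (3.930, 2.0)]),
    "GABA": (1.5, [(1.83, 0.5), (1.889, 1.0), (1.95, 0.5),
                   (2.22, 0.5), (2.284, 1.0), (2.35, 0.5),
                   (3.012, 2.0)]),
    "Glc": (1.5, [(3.43, 2.0), (3.80, 2.0)]),
    "Gln": (3.0, [(2.05, 0.4), (2.11, 0.6), (2.17, 0.4), (2.39, 0.7), (2.45, 1.0), (2.51, 0.7), (3.77, 1.0)]),
    "Glu": (10.0, [(1.98, 0.3), (2.04, 0.7), (2.12, 0.7), (2.19, 0.3), (2.29, 0.7), (2.35, 1.0), (2.41, 0.7), (3.75, 1.0)]),
    "GPC": (1.0, [(3.21, 9.0), (3.68, 2.0)]),
    "PCh": (0.6, [(3.22, 9.0), (3.61, 2.0)]),
    "GSH": (2.0, [(2.15, 1.0), (2.55, 1.0), (2.915, 1.0), (2.975, 1.0), (3.78, 1.0)]),
    "Ins": (6.5, [(3.27, 1.0), (3.52, 2.0), (3.61, 2.0), (4.05, 1.0)]),
    "Lac": (1.0, [(1.31, 3.0), (4.10, 1.0)]),
    "NAA": (12.0, [(2.008, 3.0), (2.49, 1.0), (2.67, 1.0)]),
    "NAAG": (1.5, [(2.04, 3.0), (2.52, 1.0), (2.72, 1.0)]),
    "PE": (1.8, [(3.22, 1.0), (3.98, 1.0)]),
    "Scyllo": (0.4, [(3.35, 6.0)]),
    "Tau": (1.5, [(3.25, 2.0), (3.42, 2.0)]),
    "Gly": (1.0, [(3.55, 2.0)]),
}

MEGA_METABOLITES = [n for n in BRAIN_METABOLITES if n != "Gly"]  # 19 entries

_BASIS_LW_HZ = 1.0  # intrinsic pseudo-basis linewidth


def _plain_lines(names) -> dict[str, list[tuple[float, float, float]]]:
    return {n: [(p, a, 0.0) for p, a in BRAIN_METABOLITES[n][1]] for n in names}


def _concs(names) -> np.ndarray:
    return np.array([BRAIN_METABOLITES[n][0] for n in names])


def gamma_for_linewidth(linewidth_hz: float) -> float:
    """Broadening (1/s) taking the intrinsic basis linewidth to a target FWHM."""
    if linewidth_hz < _BASIS_LW_HZ:
        raise ValueError(f"target linewidth must be >= {_BASIS_LW_HZ} Hz")
    return math.pi * (linewidth_hz - _BASIS_LW_HZ)


# ---------------------------------------------------------------------------
# Noise calibration (exponential matched-filter SNR)
# ---------------------------------------------------------------------------


def _matched_filter(grid: AcquisitionGrid, lw_hz: float) -> np.ndarray:
    return np.exp(-math.pi * lw_hz * grid.tau)


def matched_filter_noise_sd(
    ref_fid: np.ndarray,
    grid: AcquisitionGrid,
    lw_hz: float,
    snr: float,
    peak_ppm: tuple[float, float] = (1.8, 2.2),
) -> float:
    """Time-domain complex noise SD realizing a target matched-filter SNR.

    SNR is defined as the peak height of the matched-filtered reference
    singlet over the filtered per-bin noise SD.
    """
    filt = _matched_filter(grid, lw_hz)
    spec = np.abs(grid.fid_to_spec(ref_fid * filt))
    m = grid.ppm_window_mask(peak_ppm)
    peak = float(spec[m].max())
    gain = math.sqrt(float(np.mean(filt**2)))
    return peak / (snr * gain)


def measure_snr(
    fid: np.ndarray,
    grid: AcquisitionGrid,
    lw_hz: float,
    peak_ppm: tuple[float, float] = (1.8, 2.2),
    noise_ppm: tuple[float, float] | None = None,
) -> float:
    """Matched-filter SNR measured from a noisy FID.

    The per-sample noise SD is estimated from the tail of the time-domain
    FID (where the signal has decayed) and converted to the filtered
    per-bin spectral noise SD through the filter's noise gain.
    """
    fid = np.asarray(fid, dtype=complex)
    filt = _matched_filter(grid, lw_hz)
    spec = grid.fid_to_spec(fid * filt)
    m = grid.ppm_window_mask(peak_ppm)
    peak = float(np.abs(spec[m]).max())
    tail = fid[-grid.n_points // 4:]
    sd_time = float(np.std(np.concatenate([tail.real, tail.imag])))
    gain = math.sqrt(float(np.mean(filt**2)))
    return peak / (sd_time * gain)


def _complex_noise(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    return sd * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))


# ---------------------------------------------------------------------------
# CS1: toy two-peak functional series
# ---------------------------------------------------------------------------

TWO_PEAK_GRID = AcquisitionGrid(
    dwell_time=4e-3, n_points=128, spectrometer_freq=123.2, ppm_reference=3.0
)
TWO_PEAK_LW_HZ = 2.0


def two_peak_basis(separation_ppm: float, linked: bool = False) -> BasisSet:
    """Two Lorentzian singlets at +/- separation/2 around the centre."""
    grid = TWO_PEAK_GRID
    c = grid.ppm_reference
    spec = PseudoBasisSpec(
        {
            "peakA": [(c - separation_ppm / 2, 1.0, 0.0)],
            "peakB": [(c + separation_ppm / 2, 1.0, 0.0)],
        },
        linewidth_hz=TWO_PEAK_LW_HZ,
    )
    groups = {"peakA": 0, "peakB": 0} if linked else None
    return spec.build(grid, groups)


def two_peak_design(n_transients: int = 64) -> DesignMatrix:
    """Baseline + rectangular stimulation covering the central half."""
    stim = np.zeros(n_transients)
    q = n_transients // 4
    stim[q : n_transients - q] = 1.0
    return DesignMatrix(
        np.stack([np.ones(n_transients), stim], axis=1), ["const", "stim"]
    )


def gen_two_peak(
    separation_ppm: float,
    snr: float,
    seed: int,
    n_transients: int = 64,
    amp_increase: float = 0.2,
):
    """Toy fMRS series: peak A constant, peak B +20% in the central half."""
    grid = TWO_PEAK_GRID
    basis = two_peak_basis(separation_ppm)
    if not (grid.ppm.min() < grid.ppm_reference - separation_ppm / 2
            and grid.ppm_reference + separation_ppm / 2 < grid.ppm.max()):
        raise ValueError("peak separation outside the spectral window")
    design = two_peak_design(n_transients)
    cA = np.ones(n_transients)
    cB = design.X @ np.array([1.0, amp_increase])
    conc = np.stack([cA, cB], axis=1)  # (T, K); names sorted: peakA, peakB
    noiseless = conc @ basis.fids  # (T, n)
    sd = 0.0
    if np.isfinite(snr):
        sd = matched_filter_noise_sd(
            basis.fids[basis.names.index("peakA")],
            grid,
            TWO_PEAK_LW_HZ,
            snr,
            peak_ppm=(grid.ppm.min(), grid.ppm.max()),
        )
    rng = np.random.default_rng(seed)
    series = FIDSeries(grid, noiseless + _complex_noise(rng, noiseless.shape, sd))
    tvar = design.to_time_variable()
    truth = {
        "basis": basis,
        "noiseless": noiseless,
        "noise_sd": sd,
        "conc": conc,
        "beta": {"peakA": (1.0, 0.0), "peakB": (1.0, amp_increase)},
        "design": design,
    }
    return series, tvar, truth


# ---------------------------------------------------------------------------
# CS1 full / CS3: realistic brain spectrum with functional modulation
# ---------------------------------------------------------------------------

FMRS_GRID_3T = AcquisitionGrid(
    dwell_time=5e-4, n_points=1024, spectrometer_freq=123.2, ppm_reference=2.3
)


def brain_basis(
    grid: AcquisitionGrid, names=None, single_group: bool = True
) -> BasisSet:
    names = list(names) if names is not None else sorted(BRAIN_METABOLITES)
    spec = PseudoBasisSpec(_plain_lines(names), linewidth_hz=_BASIS_LW_HZ)
    groups = {n: 0 for n in names} if single_group else None
    return spec.build(grid, groups)


def gen_fmrs_spectrum(
    target_metabolite: str,
    linewidth_hz: float,
    seed: int,
    snr: float = 40.0,
    n_transients: int = 60,
    amp_increase: float = 0.2,
):
    """Realistic fMRS series: one metabolite +20% for the central half."""
    grid = FMRS_GRID_3T
    basis = brain_basis(grid)
    if target_metabolite not in basis.names:
        raise ValueError(f"unknown metabolite {target_metabolite!r}")
    design = two_peak_design(n_transients)
    conc0 = _concs(basis.names)
    betas = np.zeros((basis.n_metabolites, 2))
    betas[:, 0] = conc0
    k = basis.names.index(target_metabolite)
    betas[k, 1] = amp_increase * conc0[k]
    conc = design.X @ betas.T  # (T, K)
    gamma = gamma_for_linewidth(linewidth_hz)
    decayed = basis.fids * np.exp(-gamma * grid.tau)
    noiseless = conc @ decayed
    sd = 0.0
    if np.isfinite(snr):
        naa = decayed[basis.names.index("NAA")] * conc0[basis.names.index("NAA")]
        sd = matched_filter_noise_sd(naa, grid, linewidth_hz, snr)
    rng = np.random.default_rng(seed)
    series = FIDSeries(grid, noiseless + _complex_noise(rng, noiseless.shape, sd))
    truth = {
        "basis": basis,
        "noiseless": noiseless,
        "noise_sd": sd,
        "gamma": gamma,
        "betas": {n: tuple(betas[i]) for i, n in enumerate(basis.names)},
        "design": design,
    }
    return series, design.to_time_variable(), truth


# ---------------------------------------------------------------------------
# CS2: MEGA edited ON/OFF pairs
# ---------------------------------------------------------------------------

MEGA_GRID = AcquisitionGrid(
    dwell_time=1e-3, n_points=1024, spectrometer_freq=123.2, ppm_reference=2.3
)

# GABA multiplets.  In the OFF condition the 3.01 ppm triplet is in-phase
# but merges with the Cr/PCr 3.03 ppm singlets as the linewidth grows
# (strong signal, strong collinearity).  The 1.9 ppm edit-ON pulse
# refocuses it into a distinct pseudo-doublet and saturates the 1.89 ppm
# resonance, so the ON-OFF difference mode carries clean, decorrelated
# GABA information.
_GABA_3PPM_OFF = [(3.012, 0.0, 0.0)]
_GABA_3PPM_ON = [(2.952, 1.0, 0.0), (3.072, 1.0, 0.0)]
_GABA_2PPM = [(2.16, 0.2, 0.0), (2.22, 0.3, 0.0), (2.284, 0.4, 0.0),
              (2.34, 0.3, 0.0), (2.40, 0.2, 0.0)]
_GABA_19PPM = [(1.83, 0.2, 0.0), (1.89, 0.3, 0.0), (1.95, 0.4, 0.0),
               (2.01, 0.3, 0.0), (2.07, 0.2, 0.0)]


def mega_lines() -> tuple[dict, dict]:
    """Per-condition (OFF, ON) line lists for the 19 MEGA metabolites.

    The 1.9 ppm editing pulse: refocuses the GABA 3.01 ppm multiplet,
    saturates the GABA 1.89 ppm resonance, refocuses the Glx 3.75 ppm
    region (half amplitude in OFF) and partially saturates the NAA
    2.008 ppm singlet.  All other lines are condition-independent, so
    their difference spectrum vanishes.
    """
    off = _plain_lines(MEGA_METABOLITES)
    on = _plain_lines(MEGA_METABOLITES)
    off["GABA"] = _GABA_19PPM + _GABA_2PPM + _GABA_3PPM_OFF
    on["GABA"] = _GABA_2PPM + _GABA_3PPM_ON
    for met, ppm in (("Glu", 3.75), ("Gln", 3.77)):
        off[met] = [
            (p, a * (0.5 if p == ppm else 1.0), 0.0) for p, a in BRAIN_METABOLITES[met][1]
        ]
    on["NAA"] = [
        (p, a * (0.7 if p == 2.008 else 1.0), 0.0) for p, a in BRAIN_METABOLITES["NAA"][1]
    ]
    return off, on


def mega_basis() -> BasisSet:
    """Per-condition basis [OFF, ON] for the MEGA simulation."""
    off, on = mega_lines()
    spec = PseudoBasisSpec(off, linewidth_hz=_BASIS_LW_HZ, conditions=[off, on])
    groups = {n: 0 for n in MEGA_METABOLITES}
    return spec.build(MEGA_GRID, groups)


def mega_diff_basis(basis: BasisSet | None = None, min_rel_norm: float = 1e-3) -> BasisSet:
    """ON - OFF difference basis restricted to metabolites that survive it."""
    basis = basis or mega_basis()
    off, on = basis.per_timepoint
    diff = on.fids - off.fids
    norms = np.linalg.norm(diff, axis=1)
    keep = norms > min_rel_norm * np.linalg.norm(off.fids, axis=1).max()
    names = [n for n, k in zip(basis.names, keep) if k]
    return BasisSet(names, diff[keep], basis.grid, {n: 0 for n in names})


def gen_mega(linewidth_hz: float, snr: float, seed: int):
    """Paired MEGA ON/OFF transients plus a half-variance OFF-only series.

    Noise: the paired ON and OFF spectra each carry variance sigma^2; the
    OFF-only series (time-matched single-condition acquisition) carries
    sigma^2 / 2.  ``snr`` is the NAA singlet matched-filter SNR of the
    paired OFF condition.
    """
    grid = MEGA_GRID
    basis = mega_basis()
    off_b, on_b = basis.per_timepoint
    conc = _concs(basis.names)
    gamma = gamma_for_linewidth(linewidth_hz)
    decay = np.exp(-gamma * grid.tau)
    noiseless_off = conc @ (off_b.fids * decay)
    noiseless_on = conc @ (on_b.fids * decay)
    sd = 0.0
    if np.isfinite(snr):
        k = basis.names.index("NAA")
        sd = matched_filter_noise_sd(
            off_b.fids[k] * decay * conc[k], grid, linewidth_hz, snr
        )
    rng = np.random.default_rng(seed)
    on_series = FIDSeries(grid, noiseless_on + _complex_noise(rng, (grid.n_points,), sd))
    off_series = FIDSeries(grid, noiseless_off + _complex_noise(rng, (grid.n_points,), sd))
    off_half = FIDSeries(
        grid, noiseless_off + _complex_noise(rng, (grid.n_points,), sd / math.sqrt(2))
    )
    truth = {
        "basis": basis,
        "conc": dict(zip(basis.names, conc)),
        "gamma": gamma,
        "noise_sd": sd,
        "noiseless_on": noiseless_on,
        "noiseless_off": noiseless_off,
    }
    return on_series, off_series, off_half, truth


# ---------------------------------------------------------------------------
# CS3: group fMRS cohort at 7T
# ---------------------------------------------------------------------------

FMRS_GRID_7T = AcquisitionGrid(
    dwell_time=2.5e-4, n_points=512, spectrometer_freq=297.2, ppm_reference=2.3
)

COHORT_EFFECTS = {"Glu": 0.02, "Lac": 0.04, "Glc": -0.03, "Asp": -0.03}
COHORT_TR = 4.0
COHORT_BETWEEN_SUBJECT_CV = 0.1  # SD of subject effects as fraction of the mean
COHORT_GAMMA_NARROWING = -math.pi * 0.5  # BOLD narrowing: -0.5 Hz FWHM
# desk-scale metabolite subset for the cohort simulation (4 modulated + 8 null)
COHORT_METABOLITES = [
    "Asp", "Cr", "GABA", "Glc", "Gln", "Glu", "GPC", "Ins", "Lac", "NAA", "PCr", "Scyllo",
]


def cohort_design(n_transients: int = 60, tr: float = COHORT_TR) -> DesignMatrix:
    """Two HRF-convolved stimulation regressors + linear drift + constant."""
    run = n_transients * tr
    blocks_a = [(run * f, run / 8) for f in (0.125, 0.5)]
    blocks_b = [(run * f, run / 8) for f in (0.3125, 0.6875)]
    return convolve_design([blocks_a, blocks_b], n_transients, tr,
                           stimulus_names=["stimA", "stimB"])


def gen_fmrs_cohort(
    n_subjects: int,
    seed: int,
    snr: float = 1200.0,
    n_transients: int = 60,
    linewidth_hz: float = 9.0,
):
    """Per-subject (stimulation, control) scans with HRF-driven changes.

    Returns (scans, design, truth) where ``scans`` is a list of
    (stim FIDSeries, control FIDSeries) pairs.  Modulated metabolites carry
    inter-subject Gaussian variation on their effect sizes; control scans
    have no stimulation effects and no BOLD line narrowing.
    """
    grid = FMRS_GRID_7T
    basis = brain_basis(grid, names=sorted(COHORT_METABOLITES))
    design = cohort_design(n_transients)
    X = design.X
    stim_cols = [design.regressor_names.index(c) for c in ("stimA", "stimB")]
    conc0 = _concs(basis.names)
    gamma0 = gamma_for_linewidth(linewidth_hz)
    rng = np.random.default_rng(seed)
    k_naa = basis.names.index("NAA")
    sd = matched_filter_noise_sd(
        basis.fids[k_naa] * np.exp(-gamma0 * grid.tau) * conc0[k_naa],
        grid,
        linewidth_hz,
        snr,
    )
    scans, subject_truths = [], []
    for _s in range(n_subjects):
        eff = {
            m: e * (1.0 + COHORT_BETWEEN_SUBJECT_CV * rng.standard_normal())
            for m, e in COHORT_EFFECTS.items()
        }
        per_cond = []
        for condition in ("stim", "control"):
            betas = np.zeros((basis.n_metabolites, X.shape[1]))
            betas[:, design.regressor_names.index("const")] = conc0
            gamma_beta = np.zeros(X.shape[1])
            gamma_beta[design.regressor_names.index("const")] = gamma0
            if condition == "stim":
                for m, e in eff.items():
                    kk = basis.names.index(m)
                    betas[kk, stim_cols] = e * conc0[kk]
                gamma_beta[stim_cols] = COHORT_GAMMA_NARROWING
            conc_t = X @ betas.T  # (T, K)
            gamma_t = X @ gamma_beta  # (T,)
            fid = np.einsum(
                "tk,kn->tn", conc_t, basis.fids
            ) * np.exp(-gamma_t[:, None] * grid.tau)
            series = FIDSeries(grid, fid + _complex_noise(rng, fid.shape, sd))
            per_cond.append(series)
            subject_truths.append(
                {"condition": condition, "betas": betas.copy(), "gamma_beta": gamma_beta}
            )
        scans.append(tuple(per_cond))
    truth = {
        "basis": basis,
        "noise_sd": sd,
        "conc0": dict(zip(basis.names, conc0)),
        "effects": COHORT_EFFECTS,
        "gamma0": gamma0,
        "per_scan": subject_truths,
        "modulated": sorted(COHORT_EFFECTS),
    }
    return scans, design, truth


# ---------------------------------------------------------------------------
# CS5: multi-direction diffusion series
# ---------------------------------------------------------------------------

DMRS_GRID = AcquisitionGrid(
    dwell_time=1e-3, n_points=512, spectrometer_freq=123.2, ppm_reference=2.8
)
DMRS_LW_HZ = 6.0
DMRS_BVALS = (1.0, 3.0)  # ms/um^2

# name -> (concentration, f1, f2, d, theta1, phi1, theta2, phi2)
DMRS_TRUTH = {
    "NAA": (12.0, 0.40, 0.35, 0.35, math.pi / 2, 0.0, math.pi / 2, math.pi / 3),
    "Ins": (6.5, 0.06, 0.04, 0.22, math.pi / 2, 0.0, math.pi / 2, math.pi / 3),
    "Cr": (8.5, 0.22, 0.18, 0.28, math.pi / 2, 0.0, math.pi / 2, math.pi / 3),
}
DMRS_METABOLITES = ["Cr", "Ins", "NAA"]  # sorted order used by the basis


def fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic, roughly uniform unit directions on the hemisphere."""
    i = np.arange(n)
    z = (i + 0.5) / n
    az = i * math.pi * (3.0 - math.sqrt(5.0))
    st = np.sqrt(1.0 - z**2)
    return np.stack([st * np.cos(az), st * np.sin(az), z], axis=1)


def dmrs_basis() -> BasisSet:
    spec = PseudoBasisSpec(_plain_lines(DMRS_METABOLITES), linewidth_hz=_BASIS_LW_HZ)
    return spec.build(DMRS_GRID, {n: 0 for n in DMRS_METABOLITES})


def dmrs_scheme(n_dir: int) -> TimeVariable:
    """b = 0 plus two shells of ``n_dir`` directions each."""
    dirs = fibonacci_directions(n_dir)
    b = np.concatenate([[0.0], *[[bv] * n_dir for bv in DMRS_BVALS]])
    g = np.concatenate([[[0.0, 0.0, 0.0]], dirs, dirs])
    return TimeVariable(
        {"b": b, "gx": g[:, 0], "gy": g[:, 1], "gz": g[:, 2]}, kind="custom"
    )


def gen_dmrs_directions(n_dir: int, seed: int, snr: float = 40.0):
    """Diffusion series with ball-and-two-sticks truths per metabolite.

    The 60-direction scheme carries 10x the noise variance of the
    6-direction scheme (time-matched acquisitions).
    """
    if n_dir not in (6, 60):
        raise ValueError("n_dir must be 6 or 60")
    grid = DMRS_GRID
    basis = dmrs_basis()
    tvar = dmrs_scheme(n_dir)
    b = tvar["b"]
    g = np.stack([tvar["gx"], tvar["gy"], tvar["gz"]], axis=1)
    T = len(b)
    gamma = gamma_for_linewidth(DMRS_LW_HZ)
    conc_t = np.zeros((T, basis.n_metabolites))
    for k, name in enumerate(basis.names):
        c0, f1, f2, d, t1, p1, t2, p2 = DMRS_TRUTH[name]
        att = np.array(
            [
                model_ball_two_sticks(f1, f2, d, (t1, p1, t2, p2), b[i], g[i])
                if b[i] > 0
                else 1.0
                for i in range(T)
            ]
        )
        conc_t[:, k] = c0 * att
    noiseless = (conc_t @ basis.fids) * np.exp(-gamma * grid.tau)
    k = basis.names.index("NAA")
    sd = matched_filter_noise_sd(
        basis.fids[k] * np.exp(-gamma * grid.tau) * DMRS_TRUTH["NAA"][0],
        grid,
        DMRS_LW_HZ,
        snr,
        peak_ppm=(1.8, 2.2),
    )
    if n_dir == 60:
        sd *= math.sqrt(10.0)
    rng = np.random.default_rng(seed)
    series = FIDSeries(grid, noiseless + _complex_noise(rng, noiseless.shape, sd))
    truth = {
        "basis": basis,
        "noiseless": noiseless,
        "noise_sd": sd,
        "gamma": gamma,
        "params": {n: DMRS_TRUTH[n] for n in basis.names},
    }
    return series, tvar, truth


# ---------------------------------------------------------------------------
# CS6: multi-b diffusion with biexponential decays
# ---------------------------------------------------------------------------

MULTIB_BVALS = np.geomspace(0.02, 50.0, 7)

# metabolites: biexponential (amp-fraction frac at adc1, rest at adc2);
# macromolecules: mono-exponential; baseline: exponential + offset.
MULTIB_TRUTH = {
    "NAA": ("biexp", (12.0, 0.6, 0.45, 0.05)),
    "Ins": ("biexp", (6.5, 0.5, 0.30, 0.04)),
    "MM": ("exp", (8.0, 0.004)),
}
MULTIB_BASELINE = (0.5, 0.3, 0.1)  # amp, adc, offset of the re_0 coefficient


def multib_basis() -> BasisSet:
    lines = _plain_lines(["NAA", "Ins"])
    lines["MM"] = [(0.93, 6.0, 0.0), (1.24, 4.0, 0.0), (1.7, 4.0, 0.0)]
    spec = PseudoBasisSpec(lines, linewidth_hz=_BASIS_LW_HZ)
    names = sorted(lines)
    return spec.build(DMRS_GRID, {n: 0 for n in names})


def gen_dmrs_multib(seed: int, snr: float = 60.0, linewidth_hz: float = 8.0):
    """Multi-b series: biexponential metabolites, mono-exponential MM,
    exponential-plus-offset baseline trajectory."""
    from .dynamic import get_model
    from .spectral import baseline_regressors

    grid = DMRS_GRID
    basis = multib_basis()
    b = MULTIB_BVALS
    tvar = TimeVariable({"b": b}, kind="custom")
    T = len(b)
    gamma = gamma_for_linewidth(linewidth_hz)
    conc_t = np.zeros((T, basis.n_metabolites))
    for k, name in enumerate(basis.names):
        kind, theta = MULTIB_TRUTH[name]
        conc_t[:, k] = get_model(kind).evaluate(np.asarray(theta), {"b": b})
    fid = (conc_t @ basis.fids) * np.exp(-gamma * grid.tau)
    # Baseline trajectory enters the zeroth real polynomial coefficient.
    bl_coef = get_model("exp_offset").evaluate(np.asarray(MULTIB_BASELINE), {"b": b})
    mask = np.ones(grid.n_points, dtype=bool)
    breg = baseline_regressors(grid, 0, mask)
    bl_spec = bl_coef[:, None] * breg[0]
    noiseless = fid + grid.spec_to_fid(bl_spec)
    k = basis.names.index("NAA")
    sd = matched_filter_noise_sd(
        basis.fids[k] * np.exp(-gamma * grid.tau) * 12.0, grid, linewidth_hz, snr
    )
    rng = np.random.default_rng(seed)
    series = FIDSeries(grid, noiseless + _complex_noise(rng, noiseless.shape, sd))
    truth = {
        "basis": basis,
        "noiseless": noiseless,
        "noise_sd": sd,
        "gamma": gamma,
        "params": dict(MULTIB_TRUTH),
        "baseline": MULTIB_BASELINE,
    }
    return series, tvar, truth
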