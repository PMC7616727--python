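"""Desk-scale replication studies behind the acceptance report.

Each function regenerates its scenario from scratch, runs the Monte Carlo
comparison, and returns summary quantities.  Scales are reduced relative to
the original 500-replicate studies (100 replicates, a 4-level subset of the
8-level SNR grid) to fit a single-CPU time budget; seeds control all
randomness.
"""

from __future__ import annotations

import numpy as np

from .mc import MCResult, run_monte_carlo, uncertainty_ratio
from .synthetic import ScenarioSpec

__all__ = [
    "SNR_GRID_FULL",
    "SNR_GRID_DESK",
    "MEGA_LINEWIDTHS",
    "cs2_study",
    "cs5_study",
    "cs1_study",
]

# NAA-singlet SNR 30..330 in eight steps; every other level for desk scale.
SNR_GRID_FULL = tuple(np.linspace(30.0, 330.0, 8))
SNR_GRID_DESK = SNR_GRID_FULL[::2]
MEGA_LINEWIDTHS = (5.0, 6.33, 7.67, 9.0)


def _gaba_rmse(mc: MCResult, strategy: str) -> float:
    return mc.metrics[strategy]["conc_GABA"]["rmse"]


def cs2_study(
    seed: int,
    n_reps: int = 100,
    snr_levels: tuple = SNR_GRID_DESK,
    linewidths: tuple = MEGA_LINEWIDTHS,
) -> dict:
    """MEGA editing strategy comparison (OFF / DIFF / DYN).

    OFF runs only at the narrowest and widest linewidths (the two RMSE-ratio
    targets); DIFF and DYN run everywhere.  Ratios are averaged over the SNR
    grid per linewidth (each condition's RMSE ratio is scale-free, so
    averaging ratios pools the grid without letting the lowest SNR dominate).
    """
    results: dict = {"conditions": {}}
    ss = np.random.SeedSequence(seed)
    dyn_off = {lw: [] for lw in linewidths}
    dyn_diff = {lw: [] for lw in linewidths}
    rmses = {}
    for lw in linewidths:
        # the two RMSE-ratio targets (narrowest/widest linewidth) pool the
        # full 8-level SNR grid for a stabler ratio estimate; the pooled
        # DYN-vs-DIFF target uses the 4-level desk subset at all linewidths
        with_off = lw in (min(linewidths), max(linewidths))
        levels = SNR_GRID_FULL if with_off else snr_levels
        strategies = ["OFF", "DIFF", "DYN"] if with_off else ["DIFF", "DYN"]
        for snr in levels:
            mc = run_monte_carlo(
                ScenarioSpec("cs2_mega", int(ss.spawn(1)[0].generate_state(1)[0]),
                             {"linewidth_hz": lw, "snr": snr}),
                strategies=strategies,
                n_reps=n_reps,
            )
            entry = {s: _gaba_rmse(mc, s) for s in strategies}
            rmses[(lw, snr)] = entry
            if snr in snr_levels:
                dyn_diff[lw].append(entry["DYN"] / entry["DIFF"])
            if with_off:
                dyn_off[lw].append(entry["DYN"] / entry["OFF"])
    lw_lo, lw_hi = min(linewidths), max(linewidths)
    all_dyn_diff = [r for lw in linewidths for r in dyn_diff[lw]]
    results["conditions"] = rmses
    results["dyn_off_ratio_widest"] = float(np.mean(dyn_off[lw_hi]))
    results["dyn_off_ratio_narrowest"] = float(np.mean(dyn_off[lw_lo]))
    results["dyn_diff_reduction_pct"] = float(100.0 * (1.0 - np.mean(all_dyn_diff)))
    results["dyn_diff_ratios"] = all_dyn_diff
    results["n_reps"] = n_reps
    return results


def cs5_study(seed: int, n_reps: int = 100, init: str = "truth") -> dict:
    """Direction-count benefit of joint spectral-diffusion fitting.

    Simulates the 6- and 60-direction schemes (the latter with 10x noise
    variance), fits the ball-and-two-sticks model from the requested
    initialization, and reports the percent reduction in summed
    fraction-scaled stick-vector error.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0]) for c in ss.spawn(2)]
    errs = {}
    for s, n_dir in zip(seeds, (6, 60)):
        mc = run_monte_carlo(
            ScenarioSpec("cs5_dir", s, {"n_dir": n_dir, "init": init}),
            n_reps=n_reps,
        )
        df = mc.estimates["dynamic"]
        ok = df["_converged"].to_numpy(bool)
        errs[n_dir] = float(df["stick_err_total"].to_numpy()[ok].mean())
    return {
        "err_6": errs[6],
        "err_60": errs[60],
        "reduction_pct": float(100.0 * (1.0 - errs[60] / errs[6])),
        "n_reps": n_reps,
    }


def cs1_study(
    seed: int,
    separations: tuple = tuple(np.linspace(0.02, 0.2, 10)),
    snr_levels: tuple = (10.0, 20.0, 50.0),
    n_reps: int = 100,
) -> dict:
    """Toy two-peak uncertainty-ratio study over a separation x SNR grid.

    For each condition and each nuisance configuration (per-peak "free"
    groups vs one "linked" group) the Monte Carlo SD ratio and RMSEs of the
    stimulation beta are computed with common random numbers between the
    independent and dynamic routes.
    """
    param = "conc_peakB_beta1"
    ss = np.random.SeedSequence(seed)
    out = {}
    for sep in separations:
        for snr in snr_levels:
            cond_seed = int(ss.spawn(1)[0].generate_state(1)[0])
            for link in ("free", "linked"):
                mc = run_monte_carlo(
                    ScenarioSpec(
                        "cs1_toy", cond_seed,
                        {"separation_ppm": float(sep), "snr": float(snr), "link": link},
                    ),
                    n_reps=n_reps,
                )
                out[(round(float(sep), 4), snr, link)] = {
                    "ratio": uncertainty_ratio(mc, "independent", "dynamic", param),
                    "rmse_independent": mc.metrics["independent"][param]["rmse"],
                    "rmse_dynamic": mc.metrics["dynamic"][param]["rmse"],
                }
    return out
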