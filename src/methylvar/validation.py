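"""Ground-truth recovery benchmarks on canonical synthetic designs.

Each function generates a cohort under the package's canonical study
conditions (documented in docs/methods.md), runs the corresponding
analysis stage, and reports how well the generating truth is recovered.
They are used both by the acceptance test suite and by
``scripts/acceptance.py``.
"""
from __future__ import annotations

import numpy as np

from . import nonlinearity as nl
from .snr import snr_profile
from .synthetic import (CohortConfig, NoiseSpec, TrendSpec,
                        cross_sectional_config, generate_cohort,
                        longitudinal_config)
from .trends import infer_noise_scaling

_LONG_TREND = TrendSpec("linear", {"k": 0.003, "b": 0.3})


def ds_recovery(seed: int = 0, n_each: int = 200, n_individuals: int = 150,
                visits: int = 4) -> dict:
    """Deterministic/stochastic classification on known mechanisms.

    Generates divergence-mechanism and random-walk probes on one
    longitudinal design and classifies each by its SNR profile.
    """
    probes = [(f"div{i:04d}", _LONG_TREND, NoiseSpec.divergent())
              for i in range(n_each)]
    probes += [(f"rw{i:04d}", _LONG_TREND, NoiseSpec.stochastic())
               for i in range(n_each)]
    cohort = generate_cohort(longitudinal_config(
        probes, n_individuals=n_individuals, visits=visits, seed=seed))
    prof = snr_profile(cohort)
    div = prof.loc[[p for p in prof.index if p.startswith("div")]]
    rw = prof.loc[[p for p in prof.index if p.startswith("rw")]]
    return {
        "divergence_deterministic_pct":
            100.0 * (div["call"] == "deterministic").mean(),
        "random_walk_stochastic_pct":
            100.0 * (rw["call"] == "stochastic").mean(),
        "random_walk_median_log10_snr_ratio":
            float(np.median(rw["log10_ratio"])),
        "n": 2 * n_each,
    }


def snr_ordering(seed: int = 0, n_probes: int = 100, n_individuals: int = 150,
                 n_twin_pairs: int = 40) -> dict:
    """Median SNR of trajectories vs twin pairs vs clouds on divergence probes."""
    probes = [(f"div{i:04d}", _LONG_TREND, NoiseSpec.divergent())
              for i in range(n_probes)]
    cohort = generate_cohort(longitudinal_config(
        probes, n_individuals=n_individuals, seed=seed,
        twin_fraction=2 * n_twin_pairs / n_individuals))
    prof = snr_profile(cohort)
    return {
        "median_snr_trajectories": float(np.median(prof["snr_trajectories"])),
        "median_snr_twin_pairs": float(np.median(prof["snr_twin_pairs"])),
        "median_snr_cloud": float(np.median(prof["snr_cloud"])),
        "n": n_probes,
    }


def scaling_recovery(seed: int = 0, n_each: int = 100,
                     n_individuals: int = 700) -> dict:
    """Variance-mean scaling law inference on constructed noise laws."""
    trend = TrendSpec("linear", {"k": 0.005, "b": 0.2})
    probes = [(f"cv{i:04d}", trend, NoiseSpec(scaling="cv_constant",
                                              magnitude=0.1))
              for i in range(n_each)]
    probes += [(f"fa{i:04d}", trend, NoiseSpec(scaling="fano_constant",
                                               magnitude=0.0025))
               for i in range(n_each)]
    probes += [(f"cu{i:04d}", trend, NoiseSpec(scaling="cubic",
                                               magnitude=0.01))
               for i in range(n_each)]
    cohort = generate_cohort(cross_sectional_config(
        probes, n_individuals=n_individuals, seed=seed, sex_ratio=1.0))
    table = infer_noise_scaling(cohort, cohort.probe_ids)
    law = table["law"]
    pref = lambda s: law[[p for p in law.index if p.startswith(s)]]
    return {
        "cv_constant_quadratic_pct": 100.0 * (pref("cv") == "quadratic").mean(),
        "fano_constant_linear_pct": 100.0 * (pref("fa") == "linear").mean(),
        "cubic_na_pct": 100.0 * (pref("cu") == "NA").mean(),
        "n": 3 * n_each,
    }


def nonlinearity_recovery(seed: int = 0, n_each: int = 100,
                          n_individuals: int = 700,
                          true_alpha: float = 0.3) -> dict:
    """Power-law exponent and class recovery on a lifespan cohort.

    Uses ages 1-94 so that a pure power law is geometrically separable
    from a straight line (over adult-only spans the two are within the
    classification margin of each other by construction).
    """
    probes = [(f"pw{i:04d}",
               TrendSpec("power", {"scale": 0.15, "exponent": true_alpha}),
               NoiseSpec(scaling="cv_constant", magnitude=0.01))
              for i in range(n_each)]
    probes += [(f"ln{i:04d}", TrendSpec("linear", {"k": 0.002, "b": 0.3}),
                NoiseSpec(scaling="cv_constant", magnitude=0.01))
               for i in range(n_each)]
    cohort = generate_cohort(CohortConfig(
        n_individuals=n_individuals, probes=probes, seed=seed,
        age_range=(1.0, 94.0), sex_ratio=1.0, dataset="synthetic-lifespan"))
    table = nl.trend_table(cohort)
    pw = table.loc[[p for p in table.index if p.startswith("pw")]]
    ln = table.loc[[p for p in table.index if p.startswith("ln")]]
    ok = ((pw["alpha"] - true_alpha).abs() < 0.05) \
        & (pw["trend_class"] == "nonlinear_power")
    strong = ("nonlinear_power", "nonlinear_exponential")
    return {
        "power_recovery_pct": 100.0 * ok.mean(),
        "alpha_mean": float(pw["alpha"].mean()),
        "linear_false_nonlinear_pct":
            100.0 * ln["trend_class"].isin(strong).mean(),
        "n": 2 * n_each,
    }


def hand_worked_snr() -> dict:
    """The two fully hand-checkable SNR values."""
    from .snr import snr_trajectory, snr_twin_pair
    return {
        "snr_z_hand_worked": snr_trajectory([50, 60, 70], [0.5, 0.7, 0.6]),
        "snr_tp_hand_worked": snr_twin_pair([0.6, 0.7], [0.4, 0.5]),
    }
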