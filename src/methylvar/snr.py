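"""Signal-to-noise ratios separating deterministic from stochastic variability.

Three SNR statistics are computed per probe on a longitudinal cohort:

``SNR_trajectories``
    Fit each individual's measurements by a line in age; per point, the
    ratio of the fitted level to the absolute deviation |beta - fit|;
    average along the trajectory (SNR_z) and then across individuals.
    Only individuals with at least three measurements at distinct ages
    are eligible.

``SNR_twin_pairs``
    For each same-sex twin pair, synchronize the two series (linear
    interpolation inside the co-twin's observed span, no extrapolation),
    then per time point take the mean of the two values over half their
    absolute difference; average along the pair and across pairs.

``SNR_cloud``
    Pool all points, take the 10-year sliding-window mean as the level
    and |beta - window mean| as the deviation.

A probe is called *deterministic* when SNR_trajectories > SNR_cloud
(log10 ratio > 0): the cross-sectional spread exceeds what single
trajectories wander, so population heterogeneity dominates. Otherwise it
is *stochastic*. Points with deviation below ``epsilon`` are excluded
from the average; an all-excluded (perfect-fit) series maps to the cap.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .variability import DEFAULT_HALF_WIDTH, window_weights

EPSILON = 1e-8
SNR_CAP = 1e6

DETERMINISTIC = "deterministic"
STOCHASTIC = "stochastic"


class IneligibleSeries(ValueError):
    """Trajectory or twin pair with too few usable points."""


def _ratio_mean(level: np.ndarray, dev: np.ndarray,
                epsilon: float, cap: float) -> float:
    keep = dev >= epsilon
    if not keep.any():
        return float(cap)
    return float(min(np.mean(level[keep] / dev[keep]), cap))


# ----------------------------------------------------------------------
# individual trajectories
# ----------------------------------------------------------------------

def snr_trajectory(ages, betas, epsilon: float = EPSILON,
                   snr_cap: float = SNR_CAP) -> float:
    """SNR_z of one individual's trajectory (requires >= 3 distinct ages)."""
    ages = np.asarray(ages, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if ages.size < 3 or np.unique(ages).size < 3:
        raise IneligibleSeries(
            f"need >= 3 measurements at distinct ages, got {ages.size}")
    X = np.column_stack([np.ones_like(ages), ages])
    coef, *_ = np.linalg.lstsq(X, betas, rcond=None)
    fit = X @ coef
    return _ratio_mean(fit, np.abs(betas - fit), epsilon, snr_cap)


def snr_trajectories_probe(cohort, probe_id, epsilon: float = EPSILON,
                           snr_cap: float = SNR_CAP) -> float:
    """Unweighted mean of SNR_z over eligible individuals; NaN if none."""
    series = cohort.beta.loc[probe_id]
    vals = []
    for _, grp in cohort.individuals().items():
        ids = grp["sample_id"]
        try:
            vals.append(snr_trajectory(grp["age"].to_numpy(),
                                       series[ids].to_numpy(),
                                       epsilon, snr_cap))
        except IneligibleSeries:
            continue
    return float(np.mean(vals)) if vals else float("nan")


# ----------------------------------------------------------------------
# twin pairs
# ----------------------------------------------------------------------

def twin_alignment(ages_a, ages_b):
    """Synchronize two visit schedules.

    Returns ``(ages, Wa, Wb)`` where the weight matrices map each twin's
    own measurements onto the synchronized ages: an exact measurement
    keeps weight 1; a missing one is linearly interpolated from the two
    bracketing visits when the age lies strictly inside the twin's span;
    ages outside either span are dropped (no extrapolation).
    """
    ages_a = np.asarray(ages_a, dtype=float)
    ages_b = np.asarray(ages_b, dtype=float)

    def weights_for(own: np.ndarray, at: float):
        exact = np.flatnonzero(own == at)
        w = np.zeros(own.size)
        if exact.size:
            w[exact[0]] = 1.0
            return w
        if not (own.min() < at < own.max()):
            return None
        hi = int(np.searchsorted(own, at))
        lo = hi - 1
        t = (at - own[lo]) / (own[hi] - own[lo])
        w[lo], w[hi] = 1.0 - t, t
        return w

    sync_ages, rows_a, rows_b = [], [], []
    for at in np.unique(np.concatenate([ages_a, ages_b])):
        wa = weights_for(ages_a, at)
        wb = weights_for(ages_b, at)
        if wa is None or wb is None:
            continue
        sync_ages.append(at)
        rows_a.append(wa)
        rows_b.append(wb)
    if not sync_ages:
        return np.empty(0), np.empty((0, ages_a.size)), np.empty((0, ages_b.size))
    return np.asarray(sync_ages), np.vstack(rows_a), np.vstack(rows_b)


def align_twin_points(ages_a, values_a, ages_b, values_b):
    """Synchronized (ages, values_a, values_b) for one probe and pair."""
    order_a = np.argsort(ages_a)
    order_b = np.argsort(ages_b)
    ages, Wa, Wb = twin_alignment(np.asarray(ages_a)[order_a],
                                  np.asarray(ages_b)[order_b])
    va = Wa @ np.asarray(values_a, dtype=float)[order_a]
    vb = Wb @ np.asarray(values_b, dtype=float)[order_b]
    return ages, va, vb


def snr_twin_pair(values_a, values_b, epsilon: float = EPSILON,
                  snr_cap: float = SNR_CAP) -> float:
    """SNR_tp from two synchronized value series (>= 2 points)."""
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    if va.size < 2:
        raise IneligibleSeries("twin pair needs >= 2 synchronized points")
    mean = (va + vb) / 2.0
    return _ratio_mean(mean, np.abs(va - mean), epsilon, snr_cap)


def snr_twin_pairs_probe(cohort, probe_id, epsilon: float = EPSILON,
                         snr_cap: float = SNR_CAP) -> float:
    """Mean SNR_tp over eligible same-sex pairs; NaN when none."""
    series = cohort.beta.loc[probe_id]
    by_ind = cohort.individuals()
    pairs, _ = cohort.twin_pairs()
    vals = []
    for _, ind_a, ind_b in pairs:
        ga, gb = by_ind[ind_a], by_ind[ind_b]
        _, va, vb = align_twin_points(
            ga["age"].to_numpy(), series[ga["sample_id"]].to_numpy(),
            gb["age"].to_numpy(), series[gb["sample_id"]].to_numpy())
        if va.size < 2:
            continue
        vals.append(snr_twin_pair(va, vb, epsilon, snr_cap))
    return float(np.mean(vals)) if vals else float("nan")


# ----------------------------------------------------------------------
# pooled cloud
# ----------------------------------------------------------------------

def snr_cloud(ages, betas, epsilon: float = EPSILON, snr_cap: float = SNR_CAP,
              half_width: float = DEFAULT_HALF_WIDTH) -> float:
    """SNR of the pooled point cloud against 10-year window means."""
    ages = np.asarray(ages, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if ages.size < 2:
        raise IneligibleSeries("cloud needs >= 2 points")
    m = window_weights(ages, half_width) @ betas
    return _ratio_mean(m, np.abs(betas - m), epsilon, snr_cap)


def snr_cloud_probe(cohort, probe_id, epsilon: float = EPSILON,
                    snr_cap: float = SNR_CAP,
                    half_width: float = DEFAULT_HALF_WIDTH) -> float:
    return snr_cloud(cohort.ages, cohort.beta.loc[probe_id].to_numpy(),
                     epsilon, snr_cap, half_width)


# ----------------------------------------------------------------------
# probe-level profile
# ----------------------------------------------------------------------

def classify_determinism(snr_trajectories: float, snr_cloud_value: float) -> str:
    """Deterministic iff SNR_trajectories strictly exceeds SNR_cloud."""
    if np.isnan(snr_trajectories) or np.isnan(snr_cloud_value):
        return "NA"
    return DETERMINISTIC if snr_trajectories > snr_cloud_value else STOCHASTIC


def snr_profile(cohort, probes=None, epsilon: float = EPSILON,
                snr_cap: float = SNR_CAP,
                half_width: float = DEFAULT_HALF_WIDTH) -> pd.DataFrame:
    """All three SNR statistics, their log10 ratio and the D/S call.

    Vectorized across probes: the per-individual hat matrices, twin
    alignment weights and window membership depend only on the visit
    schedule and are shared by every probe.
    """
    if probes is None:
        probes = cohort.probe_ids
    probes = list(probes)
    B = cohort.beta.loc[probes].to_numpy()
    n_probes = len(probes)
    col_of = {s: j for j, s in enumerate(cohort.sample_ids)}
    by_ind = cohort.individuals()

    # --- trajectories ---
    total = np.zeros(n_probes)
    n_elig = 0
    for _, grp in by_ind.items():
        ages = grp["age"].to_numpy()
        if ages.size < 3 or np.unique(ages).size < 3:
            continue
        cols = [col_of[s] for s in grp["sample_id"]]
        X = np.column_stack([np.ones_like(ages), ages])
        H = X @ np.linalg.solve(X.T @ X, X.T)
        sub = B[:, cols]
        fit = sub @ H.T
        dev = np.abs(sub - fit)
        keep = dev >= epsilon
        ratio = np.where(keep, fit / np.where(keep, dev, 1.0), 0.0)
        cnt = keep.sum(axis=1)
        snr_z = np.where(cnt > 0, ratio.sum(axis=1) / np.maximum(cnt, 1), snr_cap)
        total += np.minimum(snr_z, snr_cap)
        n_elig += 1
    snr_traj = total / n_elig if n_elig else np.full(n_probes, np.nan)

    # --- twin pairs ---
    pair_sum = np.zeros(n_probes)
    n_pairs_used = 0
    pairs, _ = cohort.twin_pairs()
    for _, ind_a, ind_b in pairs:
        ga, gb = by_ind[ind_a], by_ind[ind_b]
        ages_a, ages_b = ga["age"].to_numpy(), gb["age"].to_numpy()
        _, Wa, Wb = twin_alignment(ages_a, ages_b)
        if Wa.shape[0] < 2:
            continue
        va = B[:, [col_of[s] for s in ga["sample_id"]]] @ Wa.T
        vb = B[:, [col_of[s] for s in gb["sample_id"]]] @ Wb.T
        mean = (va + vb) / 2.0
        dev = np.abs(va - mean)
        keep = dev >= epsilon
        ratio = np.where(keep, mean / np.where(keep, dev, 1.0), 0.0)
        cnt = keep.sum(axis=1)
        snr_tp = np.where(cnt > 0, ratio.sum(axis=1) / np.maximum(cnt, 1), snr_cap)
        pair_sum += np.minimum(snr_tp, snr_cap)
        n_pairs_used += 1
    snr_tw = pair_sum / n_pairs_used if n_pairs_used else np.full(n_probes, np.nan)

    # --- cloud ---
    W = window_weights(cohort.ages, half_width)
    M = B @ W.T
    dev = np.abs(B - M)
    keep = dev >= epsilon
    ratio = np.where(keep, M / np.where(keep, dev, 1.0), 0.0)
    cnt = keep.sum(axis=1)
    snr_cl = np.where(cnt > 0, ratio.sum(axis=1) / np.maximum(cnt, 1), snr_cap)
    snr_cl = np.minimum(snr_cl, snr_cap)

    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log10(snr_traj / snr_cl)
    calls = [classify_determinism(t, c) for t, c in zip(snr_traj, snr_cl)]
    return pd.DataFrame({
        "snr_trajectories": snr_traj,
        "snr_twin_pairs": snr_tw,
        "snr_cloud": snr_cl,
        "log10_ratio": log_ratio,
        "call": calls,
    }, index=probes)


# ----------------------------------------------------------------------
# distribution comparison
# ----------------------------------------------------------------------

def ks_compare(sample_a, sample_b):
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS comparison needs two non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
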