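"""Sliding-window variability and age-regression machinery.

The population variability of a probe at each methylation point is the
squared deviation from the local mean,

    sigma^2_l = (beta_l - <beta>_l)^2,

where ``<beta>_l`` averages all samples whose age falls inside a centered
sliding window (10 years wide by default, i.e. half-width 5) around the
sample's own age. Probes whose sigma^2 trends with age (OLS slope t-test,
Benjamini-Hochberg adjusted) in both a cross-sectional and a longitudinal
cohort are age-associated variably methylated positions (aVMPs).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_HALF_WIDTH = 5.0


class DegenerateDesignError(ValueError):
    """All ages equal (or too few points): the slope is not identifiable."""


@dataclass(frozen=True)
class AgeRegression:
    """OLS fit of a quantity on age with a two-sided slope t-test."""
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n: int


# ----------------------------------------------------------------------
# sliding windows
# ----------------------------------------------------------------------

def window_weights(ages: np.ndarray, half_width: float = DEFAULT_HALF_WIDTH) -> np.ndarray:
    """Row-normalized window membership matrix W (L x L).

    ``W @ values`` gives, for every sample, the mean of all values whose
    age lies within ``half_width`` years (inclusive) of that sample's age.
    The window always contains the sample itself, so rows never sum to 0.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.ndim != 1 or ages.size == 0:
        raise ValueError("ages must be a non-empty 1-D array")
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    member = np.abs(ages[:, None] - ages[None, :]) <= half_width
    w = member.astype(float)
    return w / w.sum(axis=1, keepdims=True)


def sliding_window_mean(ages, values, half_width: float = DEFAULT_HALF_WIDTH) -> np.ndarray:
    """Per-sample sliding-window mean of ``values`` along age."""
    values = np.asarray(values, dtype=float)
    return window_weights(ages, half_width) @ values


def pointwise_sigma2(ages, values, half_width: float = DEFAULT_HALF_WIDTH) -> pd.DataFrame:
    """Per-sample variability series for a single probe.

    Returns a DataFrame with columns ``age``, ``value``, ``window_mean``
    and ``sigma2`` where ``sigma2 = (value - window_mean)**2``.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    m = sliding_window_mean(ages, values, half_width)
    return pd.DataFrame({
        "age": ages,
        "value": values,
        "window_mean": m,
        "sigma2": (values - m) ** 2,
    })


def sigma2_matrix(ages, B: np.ndarray, weights: np.ndarray | None = None,
                  half_width: float = DEFAULT_HALF_WIDTH):
    """Window means and squared deviations for a probes-x-samples matrix.

    Returns ``(window_means, sigma2)`` with the same shape as ``B``.
    ``weights`` can be passed to reuse a precomputed membership matrix.
    """
    B = np.asarray(B, dtype=float)
    if weights is None:
        weights = window_weights(ages, half_width)
    means = B @ weights.T
    return means, (B - means) ** 2


# ----------------------------------------------------------------------
# regressions
# ----------------------------------------------------------------------

def regress_on_age(ages, y) -> AgeRegression:
    """OLS of ``y`` on age; two-sided t-test for slope = 0."""
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    if ages.size < 3:
        raise DegenerateDesignError(f"need >= 3 points, got {ages.size}")
    if np.ptp(ages) == 0:
        raise DegenerateDesignError("all ages equal; slope not identifiable")
    table = regress_each(ages, y[None, :])
    row = table.iloc[0]
    return AgeRegression(slope=float(row["slope"]), intercept=float(row["intercept"]),
                         p_value=float(row["p_value"]), r_squared=float(row["r_squared"]),
                         n=int(ages.size))


def regress_each(ages, Y: np.ndarray) -> pd.DataFrame:
    """Vectorized per-row OLS on age.

    ``Y`` has shape (n_series, n_samples). Returns a DataFrame with
    columns ``slope``, ``intercept``, ``p_value``, ``r_squared``.
    Constant series get slope 0, R^2 0, p 1; perfect fits get p 0.
    """
    ages = np.asarray(ages, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = ages.size
    if n < 3:
        raise DegenerateDesignError(f"need >= 3 points, got {n}")
    xc = ages - ages.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise DegenerateDesignError("all ages equal; slope not identifiable")

    slope = Y @ xc / sxx
    intercept = Y.mean(axis=1) - slope * ages.mean()
    resid = Y - intercept[:, None] - np.outer(slope, ages)
    rss = np.einsum("ij,ij->i", resid, resid)
    tss = np.einsum("ij,ij->i", Y - Y.mean(axis=1, keepdims=True),
                    Y - Y.mean(axis=1, keepdims=True))

    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        t = np.where(se > 0, slope / se, np.where(slope == 0, 0.0, np.inf))
    # guard tiny negative rss from cancellation
    r2 = np.clip(r2, None, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (slope == 0), 1.0, p)
    return pd.DataFrame({"slope": slope, "intercept": intercept,
                         "p_value": p, "r_squared": r2})


# ----------------------------------------------------------------------
# multiple testing
# ----------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------------
# aVMP selection
# ----------------------------------------------------------------------

def sigma2_age_tests(cohort, half_width: float = DEFAULT_HALF_WIDTH) -> pd.DataFrame:
    """Per-probe regression of sigma^2 on age within one (single-sex) cohort.

    Adds a BH-adjusted p-value over all probes tested.
    """
    ages = cohort.ages
    _, s2 = sigma2_matrix(ages, cohort.values(), half_width=half_width)
    table = regress_each(ages, s2)
    table.index = cohort.probe_ids
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    return table


def select_avmps(primary, secondary, alpha_primary: float = 0.001,
                 alpha_secondary: float = 0.05,
                 half_width: float = DEFAULT_HALF_WIDTH) -> dict:
    """Age-variable probes per sex, requiring support in both cohorts.

    A probe is an aVMP for a sex when its sigma^2-on-age slope is
    significant at ``alpha_primary`` (BH-adjusted within the primary
    cohort and sex) and at ``alpha_secondary`` in the secondary cohort.
    Returns ``{sex: sorted probe list}``.
    """
    shared = [p for p in primary.probe_ids if p in set(secondary.probe_ids)]
    if not shared:
        raise ValueError("primary and secondary cohorts share no probes")
    out = {}
    prim_sex = primary.subset(probes=shared).split_by_sex()
    sec_sex = secondary.subset(probes=shared).split_by_sex()
    for sex in prim_sex:
        if sex not in sec_sex:
            continue
        t1 = sigma2_age_tests(prim_sex[sex], half_width)
        t2 = sigma2_age_tests(sec_sex[sex], half_width)
        hits1 = set(t1.index[t1["p_adjusted"] < alpha_primary])
        hits2 = set(t2.index[t2["p_adjusted"] < alpha_secondary])
        out[sex] = sorted(hits1 & hits2)
    return out
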