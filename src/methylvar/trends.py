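"""aDMP/aDaVMP selection, direction classes, and variance-mean scaling.

Age-associated differentially methylated positions (aDMPs) are probes
whose mean methylation trends with age: |OLS slope| > 0.001 per year
(>= 0.1 beta per century) and R^2 above the 99th percentile of the R^2
distribution over all probes tested in that sex. aDaVMPs are the subset
whose sigma^2 also trends with age (BH-adjusted slope p < 0.001).

For each aDaVMP the variance-mean scaling law is inferred by testing
which normalization of sigma^2 removes the age trend: the squared
coefficient of variation CV^2 = sigma^2 / <beta>^2 (flat CV^2 implies
sigma^2 ~ beta^2) or the Fano factor F = sigma^2 / <beta> (flat F implies
sigma^2 ~ beta). When methylation level and variability trend in opposite
directions, both statistics are normalized to 1 - <beta> instead.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variability import (DEFAULT_HALF_WIDTH, bh_adjust, regress_each,
                          sigma2_matrix)

DIRECTION_CLASSES = ("up_up", "down_down", "down_up", "up_down")
SCALING_LAWS = ("quadratic", "linear", "NA")


class ClassificationError(ValueError):
    """Zero slope reached a sign-based classification (should be gated out)."""


@dataclass(frozen=True)
class AdmpCriteria:
    """Selection thresholds for age-trending probes."""
    min_abs_slope: float = 0.001      # beta per year
    r2_percentile: float = 99.0
    alpha_variability: float = 0.001

    def __post_init__(self):
        if self.min_abs_slope <= 0:
            raise ValueError("min_abs_slope must be positive")
        if not 0.0 < self.r2_percentile < 100.0:
            raise ValueError("r2_percentile must lie in (0, 100)")


def beta_age_fits(cohort) -> pd.DataFrame:
    """Per-probe OLS of beta on age (single-sex cohort)."""
    table = regress_each(cohort.ages, cohort.values())
    table.index = cohort.probe_ids
    return table


def select_admps(cohort, criteria: AdmpCriteria | None = None) -> dict:
    """aDMPs per sex: slope and R^2-percentile gates on the beta trend."""
    criteria = criteria or AdmpCriteria()
    out = {}
    for sex, sub in cohort.split_by_sex().items():
        if sub.n_probes < 10:
            raise ValueError("need >= 10 probes for a meaningful R^2 percentile")
        fits = beta_age_fits(sub)
        cut = np.percentile(fits["r_squared"].to_numpy(), criteria.r2_percentile)
        keep = (fits["slope"].abs() > criteria.min_abs_slope) & (fits["r_squared"] > cut)
        out[sex] = sorted(fits.index[keep])
    return out


def select_adavmps(cohort, admps: dict, alpha: float = 0.001,
                   half_width: float = DEFAULT_HALF_WIDTH) -> dict:
    """aDMPs whose sigma^2 also trends with age (BH within the aDMP set)."""
    out = {}
    for sex, sub in cohort.split_by_sex().items():
        probes = list(admps.get(sex, []))
        if not probes:
            out[sex] = []
            continue
        sel = sub.subset(probes=probes)
        _, s2 = sigma2_matrix(sel.ages, sel.values(), half_width=half_width)
        tests = regress_each(sel.ages, s2)
        tests.index = probes
        p_adj = bh_adjust(tests["p_value"].to_numpy())
        out[sex] = sorted(np.asarray(probes)[p_adj < alpha])
    return out


def classify_direction(beta_slope: float, sigma2_slope: float) -> str:
    """Direction class from the sign pair (methylation, variability)."""
    if beta_slope == 0 or sigma2_slope == 0:
        raise ClassificationError("zero slope cannot be direction-classified")
    if beta_slope > 0:
        return "up_up" if sigma2_slope > 0 else "up_down"
    return "down_up" if sigma2_slope > 0 else "down_down"


def infer_noise_scaling(cohort, adavmps, alpha: float = 0.001,
                        half_width: float = DEFAULT_HALF_WIDTH) -> pd.DataFrame:
    """Scaling law (sigma^2 ~ beta^2, ~ beta, or NA) per aDaVMP.

    ``cohort`` must be single-sex; ``adavmps`` is the probe list forming
    the BH stratum. Returns a table with the direction class, chosen
    orientation, adjusted p-values of the CV^2 and Fano age tests, and
    the inferred ``law`` (quadratic when the CV^2 test fails to reject;
    else linear when the Fano test fails to reject; else NA).
    """
    probes = list(adavmps)
    sub = cohort.subset(probes=probes)
    ages = sub.ages
    B = sub.values()
    M, S2 = sigma2_matrix(ages, B, half_width=half_width)

    beta_fits = regress_each(ages, B)
    s2_fits = regress_each(ages, S2)
    opposite = (np.sign(beta_fits["slope"].to_numpy())
                != np.sign(s2_fits["slope"].to_numpy()))
    denom = np.where(opposite[:, None], 1.0 - M, M)
    # window means sit strictly inside (0,1) for clipped betas; guard anyway
    denom = np.where(denom == 0, np.nan, denom)

    cv2 = S2 / denom ** 2
    fano = S2 / denom
    cv2_p = bh_adjust(regress_each(ages, cv2)["p_value"].to_numpy())
    fano_p = bh_adjust(regress_each(ages, fano)["p_value"].to_numpy())

    law = np.where(cv2_p >= alpha, "quadratic",
                   np.where(fano_p >= alpha, "linear", "NA"))
    direction = [classify_direction(b, s) if b != 0 and s != 0 else "NA"
                 for b, s in zip(beta_fits["slope"], s2_fits["slope"])]
    return pd.DataFrame({
        "beta_slope": beta_fits["slope"].to_numpy(),
        "sigma2_slope": s2_fits["slope"].to_numpy(),
        "direction": direction,
        "orientation": np.where(opposite, "one_minus_beta", "beta"),
        "cv2_p_adjusted": cv2_p,
        "fano_p_adjusted": fano_p,
        "law": law,
    }, index=probes)
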