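"""Linear vs power-law vs exponential age trends of methylation level.

Three regression models are fitted per probe:

    (1) beta = k * age + b                  (linear)
    (2) ln beta = alpha * ln(age) + p       (power law,  beta ~ age**alpha)
    (3) ln beta = gamma * age + q           (exponential, beta ~ e**(gamma*age))

The log-space fits are ordinary least squares in their own axes, but all
three models are scored on the original beta scale via
R^2 = 1 - RSS/TSS with back-transformed fitted values, so the
coefficients of determination are directly comparable (the nonlinear
R^2 may be negative on that scale).

Because many probes are better described on the demethylated fraction,
both beta and 1 - beta are fitted; when the best nonlinear R^2 on
1 - beta is at least 5% higher, the complementary orientation is used.
A probe is strongly nonlinear when the best nonlinear R^2 beats the
linear R^2 by at least 5% (power vs exponential decided by the larger
R^2, ties going to the power law); within +/-5% it is weakly nonlinear;
below that, linear.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BETA_FLOOR = 1e-6
DEFAULT_MARGIN = 0.05

TREND_CLASSES = ("nonlinear_power", "nonlinear_exponential",
                 "weak_nonlinear", "linear")


@dataclass(frozen=True)
class ModelFit:
    """One fitted trend model, scored on the original beta scale."""
    slope: float        # k, alpha or gamma
    intercept: float    # b, p or q
    r_squared: float


@dataclass(frozen=True)
class TrendFits:
    probe_id: str
    orientation: str            # "beta" or "complement"
    linear: ModelFit
    power: ModelFit
    exponential: ModelFit
    trend_class: str


def _ols(x: np.ndarray, y: np.ndarray):
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("degenerate design: all abscissae equal")
    slope = float(y @ xc / sxx)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


def _r2(y: np.ndarray, fitted: np.ndarray) -> float:
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    rss = float(((y - fitted) ** 2).sum())
    return 1.0 - rss / tss


def fit_linear(ages, betas) -> ModelFit:
    ages = np.asarray(ages, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if ages.size < 3:
        raise ValueError("need >= 3 points")
    k, b = _ols(ages, betas)
    return ModelFit(k, b, _r2(betas, k * ages + b))


def fit_power(ages, betas, floor: float = BETA_FLOOR) -> ModelFit:
    """ln beta on ln age; R^2 on the original scale."""
    ages = np.asarray(ages, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if (ages <= 0).any():
        raise ValueError("power-law fit requires strictly positive ages")
    y = np.log(np.maximum(betas, floor))
    alpha, p = _ols(np.log(ages), y)
    fitted = np.exp(p) * ages ** alpha
    return ModelFit(alpha, p, _r2(betas, fitted))


def fit_exponential(ages, betas, floor: float = BETA_FLOOR) -> ModelFit:
    """ln beta on age; R^2 on the original scale."""
    ages = np.asarray(ages, dtype=float)
    betas = np.asarray(betas, dtype=float)
    y = np.log(np.maximum(betas, floor))
    gamma, q = _ols(ages, y)
    fitted = np.exp(q) * np.exp(gamma * ages)
    return ModelFit(gamma, q, _r2(betas, fitted))


def _beats(candidate: float, reference: float, margin: float) -> bool:
    """candidate >= reference 'by at least margin percent'.

    Multiplicative when the reference is positive; absolute fallback when
    it is not (a percentage of a non-positive R^2 is meaningless).
    """
    if reference > 0:
        return candidate >= (1.0 + margin) * reference
    return candidate >= reference + margin


def choose_orientation(ages, betas, margin: float = DEFAULT_MARGIN,
                       floor: float = BETA_FLOOR):
    """Pick beta vs complementary-beta orientation for the nonlinear fits.

    Returns ``(orientation, values)`` where ``values`` is the series the
    models should be fitted on. The complement is preferred only when its
    best nonlinear R^2 is at least 5% higher than on beta.
    """
    betas = np.asarray(betas, dtype=float)
    comp = 1.0 - betas
    best_beta = max(fit_power(ages, betas, floor).r_squared,
                    fit_exponential(ages, betas, floor).r_squared)
    best_comp = max(fit_power(ages, comp, floor).r_squared,
                    fit_exponential(ages, comp, floor).r_squared)
    if _beats(best_comp, best_beta, margin) and best_comp > best_beta:
        return "complement", comp
    return "beta", betas


def classify_trend(r2_linear: float, r2_power: float, r2_exponential: float,
                   margin: float = DEFAULT_MARGIN) -> str:
    """Apply the strong (5% better) and weak (within 5%) nonlinearity rules."""
    best_nl = max(r2_power, r2_exponential)
    if _beats(best_nl, r2_linear, margin):
        return "nonlinear_power" if r2_power >= r2_exponential \
            else "nonlinear_exponential"
    if r2_linear > 0:
        weak = best_nl >= (1.0 - margin) * r2_linear
    else:
        weak = best_nl >= r2_linear - margin
    return "weak_nonlinear" if weak else "linear"


def fit_trends(ages, betas, probe_id: str = "", margin: float = DEFAULT_MARGIN,
               floor: float = BETA_FLOOR) -> TrendFits:
    """Full per-probe trend analysis: orientation, three fits, class."""
    orientation, values = choose_orientation(ages, betas, margin, floor)
    lin = fit_linear(ages, values)
    pw = fit_power(ages, values, floor)
    ex = fit_exponential(ages, values, floor)
    cls = classify_trend(lin.r_squared, pw.r_squared, ex.r_squared, margin)
    return TrendFits(probe_id=probe_id, orientation=orientation,
                     linear=lin, power=pw, exponential=ex, trend_class=cls)


def trend_table(cohort, probes=None, margin: float = DEFAULT_MARGIN,
                floor: float = BETA_FLOOR) -> pd.DataFrame:
    """Trend fits for a set of probes of a (single-sex) cohort."""
    if probes is None:
        probes = cohort.probe_ids
    ages = cohort.ages
    if (ages <= 0).any():
        raise ValueError("cohort contains non-positive ages; "
                         "power-law fits are undefined")
    rows = []
    for p in probes:
        f = fit_trends(ages, cohort.beta.loc[p].to_numpy(), p, margin, floor)
        rows.append({
            "probe_id": p, "orientation": f.orientation,
            "k": f.linear.slope, "b": f.linear.intercept,
            "r2_linear": f.linear.r_squared,
            "alpha": f.power.slope, "log_scale_power": f.power.intercept,
            "r2_power": f.power.r_squared,
            "gamma": f.exponential.slope,
            "log_scale_exp": f.exponential.intercept,
            "r2_exponential": f.exponential.r_squared,
            "trend_class": f.trend_class,
        })
    return pd.DataFrame(rows).set_index("probe_id")
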