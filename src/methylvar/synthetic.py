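"""Synthetic methylation cohorts with known ground truth.

The generator emulates the two study designs the analysis expects — a
cross-sectional cohort (one visit per individual, wide age span) and a
longitudinal twin cohort (several visits at fixed spacing, a fraction of
individuals paired as same-sex twins) — and, per probe, the two mechanisms
by which cross-sectional variance can grow with age:

``divergence``
    Heterogeneity between individuals: each individual follows its own
    straight line, with slope/intercept perturbed around the population
    trend. Twins share the perturbation up to a small intra-pair jitter.
    Visit-level measurement noise is added on top.

``random_walk``
    Within-individual stochasticity: each individual starts on the
    population curve (plus a stable personal offset, which heterogeneity
    of measurement context and stable epigenotype both produce), then
    evolves by a biased random walk whose drift equals the trend
    increment, with one episodic excursion (a transient environmental
    perturbation of magnitude ~0.02-0.05) at a random visit during
    follow-up, plus small baseline noise.

Noise magnitudes can scale with the mean to emulate the variance-mean
laws the downstream analysis infers: sigma ~ beta (constant CV),
sigma^2 ~ beta (constant Fano factor), constant sigma, or sigma^2 ~ beta^3
(neither law; used as a negative control).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

BETA_FLOOR = 1e-6  # keep betas strictly inside (0, 1) so log fits exist

TREND_LAWS = ("linear", "power", "exponential", "constant")
NOISE_SCALINGS = ("cv_constant", "fano_constant", "additive_constant", "cubic")
MECHANISMS = ("divergence", "random_walk")


class ConfigurationError(ValueError):
    """Raised when a probe's configured trajectory leaves [0, 1]."""


@dataclass(frozen=True)
class TrendSpec:
    """Population mean trajectory of one probe.

    ``law`` is one of ``linear`` (k*age + b; params ``k``, ``b``),
    ``power`` (scale * age**exponent; params ``scale``, ``exponent``),
    ``exponential`` (scale * exp(rate*age); params ``scale``, ``rate``)
    or ``constant`` (params ``level``). With ``orientation="complement"``
    the law describes 1 - beta instead of beta.
    """
    law: str
    params: dict
    orientation: str = "beta"

    def __post_init__(self):
        if self.law not in TREND_LAWS:
            raise ValueError(f"unknown trend law {self.law!r}")
        if self.orientation not in ("beta", "complement"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def raw(self, ages):
        """Law value before orientation is applied."""
        a = np.asarray(ages, dtype=float)
        p = self.params
        if self.law == "linear":
            return p["k"] * a + p["b"]
        if self.law == "power":
            return p["scale"] * a ** p["exponent"]
        if self.law == "exponential":
            return p["scale"] * np.exp(p["rate"] * a)
        return np.full_like(a, float(p["level"]))

    def mean(self, ages):
        """Mean beta value at the given ages."""
        raw = self.raw(ages)
        return 1.0 - raw if self.orientation == "complement" else raw

    def check_span(self, age_range, probe_id: str) -> None:
        lo, hi = age_range
        grid = np.linspace(lo, hi, 201)
        raw = self.raw(grid)
        if self.law in ("power", "exponential") and (raw <= 0).any():
            raise ConfigurationError(
                f"probe {probe_id!r}: {self.law} trend non-positive on [{lo}, {hi}]")
        mean = self.mean(grid)
        if (mean < 0).any() or (mean > 1).any():
            raise ConfigurationError(
                f"probe {probe_id!r}: mean trajectory leaves [0, 1] on [{lo}, {hi}]")


@dataclass(frozen=True)
class NoiseSpec:
    """Variability mechanism and noise model of one probe.

    ``scaling`` sets how the visit-level noise s.d. depends on the mean:
    ``cv_constant`` (sd = magnitude * mean), ``fano_constant``
    (sd = sqrt(magnitude * mean)), ``additive_constant`` (sd = magnitude)
    or ``cubic`` (sd = sqrt(magnitude * mean**3)).

    ``divergence_sd`` is the s.d. of the per-individual slope and
    intercept perturbations (divergence mechanism). ``step_sd`` scales
    the random-walk step (sd = step_sd * sqrt(dt)); ``offset_sd`` the
    stable per-individual level offset and ``excursion_range`` the
    magnitude bounds of the single episodic excursion per individual
    (random-walk mechanism).
    """
    scaling: str = "additive_constant"
    magnitude: float = 0.0
    mechanism: str = "divergence"
    divergence_sd: float = 0.0
    step_sd: float = 0.0
    offset_sd: float = 0.0
    excursion_range: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.scaling not in NOISE_SCALINGS:
            raise ValueError(f"unknown noise scaling {self.scaling!r}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")

    @classmethod
    def divergent(cls, magnitude: float = 0.005, divergence_sd: float = 0.001,
                  scaling: str = "additive_constant") -> "NoiseSpec":
        """Default heterogeneous-trajectory (deterministic) probe."""
        return cls(scaling=scaling, magnitude=magnitude,
                   mechanism="divergence", divergence_sd=divergence_sd)

    @classmethod
    def stochastic(cls, magnitude: float = 0.001, step_sd: float = 0.001,
                   offset_sd: float = 0.0225,
                   excursion_range: tuple = (0.02, 0.05)) -> "NoiseSpec":
        """Default fluctuation-dominated (stochastic) probe."""
        return cls(scaling="additive_constant", magnitude=magnitude,
                   mechanism="random_walk", step_sd=step_sd,
                   offset_sd=offset_sd, excursion_range=excursion_range)

    def noise_sd(self, mean):
        mean = np.asarray(mean, dtype=float)
        c = self.magnitude
        if self.scaling == "cv_constant":
            return c * mean
        if self.scaling == "fano_constant":
            return np.sqrt(c * mean)
        if self.scaling == "cubic":
            return np.sqrt(c * mean ** 3)
        return np.full_like(mean, c)


@dataclass
class CohortConfig:
    """Design of a synthetic cohort.

    ``probes`` is a list of ``(probe_id, TrendSpec, NoiseSpec)``.
    ``visits_per_individual = 1`` gives a cross-sectional design (one
    visit at a uniform random age); more visits give a longitudinal
    design with fixed ``visit_spacing``. ``twin_fraction`` of individuals
    are paired as same-sex twins sharing ages and trajectory draws up to
    ``twin_jitter_frac * divergence_sd``.
    """
    n_individuals: int
    probes: list
    visits_per_individual: int = 1
    age_range: tuple = (14.0, 94.0)
    visit_spacing: float = 3.0
    twin_fraction: float = 0.0
    sex_ratio: float = 0.5
    seed: int = 0
    twin_jitter_frac: float = 0.1
    dataset: str = "synthetic"

    def __post_init__(self):
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if not 0.0 <= self.twin_fraction <= 1.0:
            raise ValueError("twin_fraction must lie in [0, 1]")
        if self.n_individuals < 1 or self.visits_per_individual < 1:
            raise ValueError("need at least one individual and one visit")
        span = (self.visits_per_individual - 1) * self.visit_spacing
        if span >= hi - lo:
            raise ValueError("visit schedule longer than the age range")


class _Design:
    """Resolved sampling design shared by every probe of one cohort.

    Samples are laid out individual-major, visit-minor and age-sorted
    within each individual, so per-probe draws vectorize over the
    (n_individuals, visits) grid.
    """

    def __init__(self, config: CohortConfig, rng: np.random.Generator):
        n = config.n_individuals
        v = config.visits_per_individual
        sp = config.visit_spacing
        lo, hi = config.age_range
        n_pairs = int(round(config.twin_fraction * n / 2.0))
        n_lineages = n_pairs + (n - 2 * n_pairs)

        # lineage = twin pair or single; shares sex, visit ages and (for
        # divergence probes) the trajectory draw
        lin_of_ind = np.empty(n, dtype=int)
        is_twin = np.zeros(n, dtype=bool)
        pair_id = [None] * n
        for p in range(n_pairs):
            lin_of_ind[2 * p] = lin_of_ind[2 * p + 1] = p
            is_twin[2 * p] = is_twin[2 * p + 1] = True
            pair_id[2 * p] = pair_id[2 * p + 1] = f"tp{p + 1:04d}"
        lin_of_ind[2 * n_pairs:] = n_pairs + np.arange(n - 2 * n_pairs)

        lin_sex = np.where(rng.random(n_lineages) < config.sex_ratio,
                           "male", "female")
        lin_first = rng.uniform(lo, hi - sp * (v - 1), n_lineages)
        ages_by_ind = lin_first[lin_of_ind][:, None] + sp * np.arange(v)[None, :]

        rows = []
        for i in range(n):
            ind = f"ind{i + 1:05d}"
            for j in range(v):
                rows.append({
                    "sample_id": f"{ind}_v{j + 1}",
                    "individual_id": ind,
                    "age": ages_by_ind[i, j],
                    "sex": lin_sex[lin_of_ind[i]],
                    "twin_pair_id": pair_id[i] if pair_id[i] else pd.NA,
                    "dataset": config.dataset,
                })
        self.samples = pd.DataFrame(rows)
        self.n_ind, self.visits = n, v
        self.n_lineages = n_lineages
        self.lin_of_ind = lin_of_ind
        self.is_twin = is_twin
        self.ages_by_ind = ages_by_ind          # (n_ind, v)


def _divergence_values(trend, noise, config, design, rng):
    mu = trend.mean(design.ages_by_ind)
    jitter = config.twin_jitter_frac * noise.divergence_sd
    dk0 = rng.normal(0.0, noise.divergence_sd, design.n_lineages)
    db0 = rng.normal(0.0, noise.divergence_sd, design.n_lineages)
    jit_k = np.where(design.is_twin,
                     rng.normal(0.0, 1.0, design.n_ind) * jitter, 0.0)
    jit_b = np.where(design.is_twin,
                     rng.normal(0.0, 1.0, design.n_ind) * jitter, 0.0)
    dk = dk0[design.lin_of_ind] + jit_k
    db = db0[design.lin_of_ind] + jit_b
    values = mu + dk[:, None] * design.ages_by_ind + db[:, None]
    sd = noise.noise_sd(mu)
    if np.any(sd > 0):
        values = values + rng.normal(0.0, 1.0, mu.shape) * sd
    return values


def _random_walk_values(trend, noise, config, design, rng):
    """Biased walk from the population curve at the first visit.

    Each individual carries a stable level offset (twins share it up to
    the intra-pair jitter), drifts with the trend, accumulates walk
    steps of sd step_sd*sqrt(dt), receives baseline visit noise and one
    episodic excursion at a random visit during follow-up.
    """
    mu = trend.mean(design.ages_by_ind)
    n, v = design.n_ind, design.visits
    jitter = config.twin_jitter_frac * noise.offset_sd
    off0 = rng.normal(0.0, noise.offset_sd, design.n_lineages)
    jit = np.where(design.is_twin, rng.normal(0.0, 1.0, n) * jitter, 0.0)
    offset = off0[design.lin_of_ind] + jit

    values = mu + offset[:, None]
    if v > 1 and noise.step_sd > 0:
        dt = np.diff(design.ages_by_ind, axis=1)
        steps = rng.normal(0.0, 1.0, (n, v - 1)) * noise.step_sd * np.sqrt(dt)
        values = values + np.concatenate(
            [np.zeros((n, 1)), np.cumsum(steps, axis=1)], axis=1)
    sd = noise.noise_sd(mu)
    if np.any(sd > 0):
        values = values + rng.normal(0.0, 1.0, mu.shape) * sd
    lo_exc, hi_exc = noise.excursion_range
    if hi_exc > 0:
        k = rng.integers(0, v, n)
        amp = rng.uniform(lo_exc, hi_exc, n) * rng.choice([-1.0, 1.0], n)
        values[np.arange(n), k] += amp
    return values


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a cohort; the seed fully determines the output."""
    rng = np.random.default_rng(config.seed)
    design = _Design(config, rng)
    matrix = np.empty((len(config.probes), len(design.samples)))
    probe_ids = []
    for i, (probe_id, trend, noise) in enumerate(config.probes):
        trend.check_span(config.age_range, probe_id)
        if noise.mechanism == "divergence":
            vals = _divergence_values(trend, noise, config, design, rng)
        else:
            vals = _random_walk_values(trend, noise, config, design, rng)
        matrix[i] = np.clip(vals.reshape(-1), BETA_FLOOR, 1.0 - BETA_FLOOR)
        probe_ids.append(probe_id)
    beta = pd.DataFrame(matrix, index=probe_ids,
                        columns=design.samples["sample_id"])
    return Cohort(beta, design.samples)


def truth_table(config: CohortConfig) -> pd.DataFrame:
    """One row per probe: the generating law, parameters and mechanism."""
    rows = []
    for probe_id, trend, noise in config.probes:
        p = trend.params
        rows.append({
            "probe_id": probe_id,
            "law": trend.law,
            "orientation": trend.orientation,
            "k": p.get("k", np.nan),
            "b": p.get("b", np.nan),
            "scale": p.get("scale", np.nan),
            "exponent": p.get("exponent", np.nan),
            "rate": p.get("rate", np.nan),
            "level": p.get("level", np.nan),
            "scaling": noise.scaling,
            "magnitude": noise.magnitude,
            "mechanism": noise.mechanism,
            "divergence_sd": noise.divergence_sd,
            "step_sd": noise.step_sd,
        })
    cols = ["probe_id", "law", "orientation", "k", "b", "scale", "exponent",
            "rate", "level", "scaling", "magnitude", "mechanism",
            "divergence_sd", "step_sd"]
    return pd.DataFrame(rows, columns=cols)


# ----------------------------------------------------------------------
# canonical study designs
# ----------------------------------------------------------------------

def cross_sectional_config(probes, n_individuals: int = 700, seed: int = 0,
                           age_range=(14.0, 94.0), **kw) -> CohortConfig:
    """One-visit design emulating a wide-age-span population cohort."""
    return CohortConfig(n_individuals=n_individuals, probes=probes, seed=seed,
                        visits_per_individual=1, age_range=age_range,
                        dataset="synthetic-cross", **kw)


def longitudinal_config(probes, n_individuals: int = 150, seed: int = 0,
                        visits: int = 4, spacing: float = 3.0,
                        twin_fraction: float = 0.0, **kw) -> CohortConfig:
    """Repeated-visit design emulating an elderly longitudinal twin cohort."""
    return CohortConfig(n_individuals=n_individuals, probes=probes, seed=seed,
                        visits_per_individual=visits, visit_spacing=spacing,
                        age_range=(48.0, 98.0), twin_fraction=twin_fraction,
                        dataset="synthetic-long", **kw)
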