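import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import methylvar as mv

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def linear_trend(k=0.003, b=0.3):
    return mv.TrendSpec("linear", {"k": k, "b": b})


def make_cohort(values: np.ndarray, ages, sexes=None, probe_ids=None,
                individual_ids=None, twin_pair_ids=None) -> mv.Cohort:
    """Assemble a Cohort from raw arrays (one visit per sample by default)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1]
    sample_ids = [f"s{i:04d}" for i in range(n)]
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "individual_id": individual_ids or [f"i{i:04d}" for i in range(n)],
        "age": np.asarray(ages, dtype=float),
        "sex": sexes or ["female"] * n,
        "twin_pair_id": twin_pair_ids or [pd.NA] * n,
        "dataset": "test",
    })
    probe_ids = probe_ids or [f"cg{i:05d}" for i in range(values.shape[0])]
    beta = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    return mv.Cohort(beta, sheet)


@pytest.fixture(scope="session")
def mixed_longitudinal():
    """30 divergence + 30 stochastic probes, 80 individuals, half twins."""
    probes = [(f"div{i:03d}", linear_trend(), mv.NoiseSpec.divergent())
              for i in range(30)]
    probes += [(f"rw{i:03d}", linear_trend(), mv.NoiseSpec.stochastic())
               for i in range(30)]
    cfg = mv.longitudinal_config(probes, n_individuals=80, seed=7,
                                 twin_fraction=0.5)
    return cfg, mv.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cross():
    """Cross-sectional cohort with age-variable and flat probes, both sexes."""
    probes = [(f"var{i:03d}", linear_trend(), mv.NoiseSpec.divergent())
              for i in range(10)]
    probes += [(f"flat{i:03d}", mv.TrendSpec("constant", {"level": 0.5}),
                mv.NoiseSpec(scaling="additive_constant", magnitude=0.02))
               for i in range(10)]
    cfg = mv.cross_sectional_config(probes, n_individuals=500, seed=5)
    return cfg, mv.generate_cohort(cfg)
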