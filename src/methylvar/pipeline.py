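"""End-to-end orchestration of the variability analysis.

Stage order mirrors the analysis design: (optional) cell-composition
residualization -> aVMP selection (cross-sectional primary cohort
intersected with the longitudinal secondary cohort, per sex) -> SNR
profiling and deterministic/stochastic calls on the longitudinal cohort
-> aDMP/aDaVMP selection, direction classes and variance-mean scaling on
the cross-sectional cohort -> linear/power/exponential trend
classification -> genomic-context enrichment. Sexes are analysed
separately throughout. All intermediate decisions that silently drop
data (individuals with fewer than three visits, unusable twin pairs,
unannotated probes) are recorded in an exclusion log.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import io as mio
from . import nonlinearity as nl
from . import snr as snr_mod
from . import trends
from . import variability as var
from .cohort import Cohort


@dataclass
class PipelineConfig:
    """Thresholds and paths of one pipeline run; fully serializable."""
    primary_beta: str | None = None
    primary_samples: str | None = None
    secondary_beta: str | None = None
    secondary_samples: str | None = None
    annotation: str | None = None
    cell_fractions: str | None = None
    output_dir: str | None = None

    alpha_primary: float = 0.001
    alpha_secondary: float = 0.05
    alpha_adavmp: float = 0.001
    alpha_scaling: float = 0.001
    min_abs_slope: float = 0.001
    r2_percentile: float = 99.0
    margin: float = 0.05
    epsilon: float = 1e-8
    snr_cap: float = 1e6
    half_width: float = 5.0
    seed: int = 0
    stratify_by_sex: bool = True

    def __post_init__(self):
        for name in ("alpha_primary", "alpha_secondary", "alpha_adavmp",
                     "alpha_scaling", "min_abs_slope", "margin", "epsilon",
                     "snr_cap", "half_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


@dataclass
class PipelineResult:
    report: pd.DataFrame
    summary: dict
    enrichment: pd.DataFrame | None
    exclusions: list = field(default_factory=list)
    log: list = field(default_factory=list)


def _log_exclusions(cohort: Cohort, exclusions: list, label: str) -> None:
    for ind, grp in cohort.individuals().items():
        if len(grp) < 3 or grp["age"].nunique() < 3:
            exclusions.append(
                f"{label}: individual {ind} skipped for trajectories "
                f"({len(grp)} visits)")
    _, bad_pairs = cohort.twin_pairs()
    for pair in bad_pairs:
        exclusions.append(f"{label}: opposite-sex twin pair {pair} excluded")


def mark_overlap(beta_hits, residual_hits, mark: str = "X") -> dict:
    """Overlap marks for probes present in both the beta and residual lists."""
    return {p: mark for p in set(beta_hits) & set(residual_hits)}


def run_pipeline(primary: Cohort, secondary: Cohort | None = None,
                 annotation: pd.DataFrame | None = None,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage and assemble the per-probe report.

    ``primary`` is the wide-age-span cross-sectional cohort; ``secondary``
    the longitudinal (twin) cohort. Without a secondary cohort the aVMP
    intersection degrades, with an explicit warning, to the primary-only
    test, and the SNR stage is skipped.
    """
    cfg = config or PipelineConfig()
    log: list = [f"config: {json.dumps(cfg.to_dict(), default=str)}"]
    exclusions: list = []

    # --- aVMPs -------------------------------------------------------
    single_dataset = secondary is None
    if single_dataset:
        log.append("WARNING: no secondary cohort; aVMPs from primary only "
                   "(no cross-dataset intersection)")
        avmps = {}
        for sex, sub in primary.split_by_sex().items():
            t = var.sigma2_age_tests(sub, cfg.half_width)
            avmps[sex] = sorted(t.index[t["p_adjusted"] < cfg.alpha_primary])
    else:
        avmps = var.select_avmps(primary, secondary,
                                 alpha_primary=cfg.alpha_primary,
                                 alpha_secondary=cfg.alpha_secondary,
                                 half_width=cfg.half_width)
    for sex, lst in avmps.items():
        log.append(f"aVMPs ({sex}): {len(lst)}")

    # --- SNR on the longitudinal cohort ------------------------------
    profiles = {}
    if not single_dataset:
        for sex, sub in secondary.split_by_sex().items():
            probes = [p for p in avmps.get(sex, []) if p in set(sub.probe_ids)]
            _log_exclusions(sub, exclusions, f"snr/{sex}")
            if probes:
                profiles[sex] = snr_mod.snr_profile(
                    sub, probes, epsilon=cfg.epsilon, snr_cap=cfg.snr_cap,
                    half_width=cfg.half_width)

    # --- aDMP / aDaVMP / scaling / nonlinearity on the primary --------
    criteria = trends.AdmpCriteria(min_abs_slope=cfg.min_abs_slope,
                                   r2_percentile=cfg.r2_percentile,
                                   alpha_variability=cfg.alpha_adavmp)
    admps = trends.select_admps(primary, criteria)
    adavmps = trends.select_adavmps(primary, admps, alpha=cfg.alpha_adavmp,
                                    half_width=cfg.half_width)
    scaling, trend_cls = {}, {}
    for sex, sub in primary.split_by_sex().items():
        if adavmps.get(sex):
            scaling[sex] = trends.infer_noise_scaling(
                sub, adavmps[sex], alpha=cfg.alpha_scaling,
                half_width=cfg.half_width)
        if admps.get(sex):
            trend_cls[sex] = nl.trend_table(sub, admps[sex], margin=cfg.margin)
        log.append(f"aDMPs ({sex}): {len(admps.get(sex, []))}; "
                   f"aDaVMPs ({sex}): {len(adavmps.get(sex, []))}")

    # --- per-probe report --------------------------------------------
    rows = []
    sexes = sorted(set(avmps) | set(admps))
    for sex in sexes:
        av = set(avmps.get(sex, []))
        ad = set(admps.get(sex, []))
        adv = set(adavmps.get(sex, []))
        prof = profiles.get(sex)
        sc = scaling.get(sex)
        tc = trend_cls.get(sex)
        for probe in primary.probe_ids:
            row = {"probe_id": probe, "sex": sex,
                   "avmp": probe in av, "admp": probe in ad,
                   "adavmp": probe in adv,
                   "snr_trajectories": np.nan, "snr_twin_pairs": np.nan,
                   "snr_cloud": np.nan, "log10_ratio": np.nan, "ds_call": "",
                   "direction": "", "scaling_law": "", "orientation": "",
                   "trend_class": "", "alpha": np.nan, "r2_linear": np.nan,
                   "r2_power": np.nan, "r2_exponential": np.nan}
            if prof is not None and probe in prof.index:
                p = prof.loc[probe]
                row.update(snr_trajectories=p["snr_trajectories"],
                           snr_twin_pairs=p["snr_twin_pairs"],
                           snr_cloud=p["snr_cloud"],
                           log10_ratio=p["log10_ratio"], ds_call=p["call"])
            if sc is not None and probe in sc.index:
                s = sc.loc[probe]
                row.update(direction=s["direction"], scaling_law=s["law"],
                           orientation=s["orientation"])
            if tc is not None and probe in tc.index:
                t = tc.loc[probe]
                row.update(trend_class=t["trend_class"], alpha=t["alpha"],
                           r2_linear=t["r2_linear"], r2_power=t["r2_power"],
                           r2_exponential=t["r2_exponential"])
            rows.append(row)
    report = pd.DataFrame(rows)

    # flags must nest: aDaVMP => aDMP
    assert not ((report["adavmp"]) & (~report["admp"])).any()

    # --- enrichment ---------------------------------------------------
    enrich_table = None
    if annotation is not None and len(annotation):
        parts = []
        for sex in sexes:
            hits = avmps.get(sex, [])
            if not hits:
                continue
            t = enr.enrich_probe_list(hits, primary.probe_ids, annotation)
            if t.attrs.get("n_unannotated"):
                exclusions.append(
                    f"enrichment/{sex}: {t.attrs['n_unannotated']} probes "
                    "without annotation excluded")
            t.insert(0, "sex", sex)
            parts.append(t)
        if parts:
            enrich_table = pd.concat(parts, ignore_index=True)

    summary = summarize_classes(report)
    summary["single_dataset"] = single_dataset
    result = PipelineResult(report=report, summary=summary,
                            enrichment=enrich_table,
                            exclusions=exclusions, log=log)
    if cfg.output_dir:
        _write_outputs(result, cfg, annotation, avmps)
    return result


def _pct_block(series: pd.Series) -> dict:
    counts = series.value_counts().to_dict()
    total = int(sum(counts.values()))
    return {
        "counts": {str(k): int(v) for k, v in counts.items()},
        "percent": {str(k): (100.0 * v / total if total else 0.0)
                    for k, v in counts.items()},
        "total": total,
    }


def summarize_classes(report: pd.DataFrame) -> dict:
    """Counts and percentages of every classification, per sex."""
    out = {}
    for sex, grp in report.groupby("sex"):
        ds = grp.loc[grp["ds_call"].isin(["deterministic", "stochastic"]),
                     "ds_call"]
        direction = grp.loc[grp["direction"].isin(trends.DIRECTION_CLASSES),
                            "direction"]
        law = grp.loc[grp["scaling_law"].isin(trends.SCALING_LAWS),
                      "scaling_law"]
        tcls = grp.loc[grp["trend_class"].isin(nl.TREND_CLASSES), "trend_class"]
        out[str(sex)] = {
            "n_probes": int(len(grp)),
            "n_avmp": int(grp["avmp"].sum()),
            "n_admp": int(grp["admp"].sum()),
            "n_adavmp": int(grp["adavmp"].sum()),
            "determinism": _pct_block(ds),
            "direction": _pct_block(direction),
            "scaling_law": _pct_block(law),
            "trend_class": _pct_block(tcls),
        }
    return out


def _write_outputs(result: PipelineResult, cfg: PipelineConfig,
                   annotation, avmps) -> None:
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(outdir / "probe_report.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2)
    with open(outdir / "run.log", "w") as fh:
        for line in result.log:
            fh.write(line + "\n")
        fh.write("--- exclusions ---\n")
        for line in result.exclusions:
            fh.write(line + "\n")
    if result.enrichment is not None:
        result.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    if annotation is not None and len(annotation):
        all_avmps = sorted(set().union(*avmps.values())) if avmps else []
        if all_avmps:
            mio.write_probe_bed(annotation, all_avmps, outdir / "avmp.bed")
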