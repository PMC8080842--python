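"""Reading and writing the pipeline's tabular formats.

Formats
-------
Beta matrix : delimited text (TSV or CSV by extension), first column
    ``probe_id``, remaining columns one per sample. Full float precision
    (17 significant digits) on write so round trips are bit-stable.
Sample sheet : CSV with header
    ``sample_id,individual_id,age,sex,twin_pair_id,dataset``.
Probe annotation : CSV with columns ``probe_id, chromosome, position,
    island_relation, region_group, enhancer`` (closed vocabularies).
Cell fractions : CSV with ``sample_id`` plus the five leukocyte fractions.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError, SAMPLE_SHEET_COLUMNS

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
REGION_GROUPS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "Intergenic")
CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Gran")

ANNOTATION_COLUMNS = ["probe_id", "chromosome", "position",
                      "island_relation", "region_group", "enhancer"]


class ParseError(ValueError):
    """Malformed input file (bad value, unknown token, missing column)."""


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------

def read_cohort(beta_path, sample_sheet_path, value_type: str = "beta") -> Cohort:
    """Load a beta matrix and its sample sheet into a :class:`Cohort`.

    Samples are matched by id and reordered to the sample-sheet order;
    any mismatch between the two files is reported with the offending ids.
    """
    beta = pd.read_csv(beta_path, sep=_sep(beta_path), index_col=0,
                       float_precision="round_trip")
    beta.index = beta.index.astype(str)
    sheet = pd.read_csv(sample_sheet_path, float_precision="round_trip",
                        dtype={"sample_id": str, "individual_id": str,
                               "twin_pair_id": str})
    missing = [c for c in ("sample_id", "individual_id", "age", "sex")
               if c not in sheet.columns]
    if missing:
        raise ParseError(f"sample sheet missing columns {missing}")

    for col in beta.columns:
        vals = pd.to_numeric(beta[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if value_type == "beta":
            bad |= (vals < 0) | (vals > 1)
        if bad.any():
            probe = beta.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"invalid {value_type} value at probe {probe!r}, sample {col!r}: "
                f"{beta.loc[probe, col]!r}")
        beta[col] = vals
    try:
        return Cohort(beta, sheet, value_type=value_type)
    except CohortError as exc:
        raise ParseError(str(exc)) from exc


def write_cohort(cohort: Cohort, beta_path, sample_sheet_path) -> None:
    """Write matrix and sheet as delimited text at full float precision."""
    out = cohort.beta.copy()
    out.index.name = "probe_id"
    out.to_csv(beta_path, sep=_sep(beta_path), float_format="%.17g")
    cohort.samples.to_csv(sample_sheet_path, index=False, float_format="%.17g")


# ----------------------------------------------------------------------
# probe annotation
# ----------------------------------------------------------------------

def read_probe_annotation(path) -> pd.DataFrame:
    """Genomic-context table with validated closed vocabularies."""
    ann = pd.read_csv(path, dtype={"probe_id": str, "chromosome": str})
    if ann.empty and list(ann.columns) in ([], ANNOTATION_COLUMNS):
        return pd.DataFrame(columns=ANNOTATION_COLUMNS).set_index("probe_id")
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ParseError(f"annotation missing columns {missing}")
    for col, allowed in (("island_relation", ISLAND_RELATIONS),
                         ("region_group", REGION_GROUPS)):
        bad = ~ann[col].isin(allowed)
        if bad.any():
            row = int(bad.to_numpy().nonzero()[0][0])
            raise ParseError(
                f"unknown {col} token {ann[col].iloc[row]!r} at data row {row + 1}")
    if ann["probe_id"].duplicated().any():
        raise ParseError("duplicate probe ids in annotation")
    ann["enhancer"] = ann["enhancer"].astype(bool)
    ann["position"] = ann["position"].astype(int)
    return ann.set_index("probe_id")


def write_probe_bed(annotation: pd.DataFrame, probes, path) -> None:
    """Export a probe list as BED (0-based half-open single-base intervals)."""
    sub = annotation.loc[[p for p in probes if p in annotation.index]]
    bed = pd.DataFrame({
        "chrom": sub["chromosome"],
        "start": sub["position"] - 1,
        "end": sub["position"],
        "name": sub.index,
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------------
# cell-composition residualization
# ----------------------------------------------------------------------

def read_cell_fractions(path) -> pd.DataFrame:
    """Per-sample leukocyte fractions (CD8T, CD4T, NK, Bcell, Gran)."""
    fr = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in ("sample_id",) + CELL_TYPES if c not in fr.columns]
    if missing:
        raise ParseError(f"cell-fraction table missing columns {missing}")
    fr = fr.set_index("sample_id")[list(CELL_TYPES)].astype(float)
    if ((fr < 0) | (fr > 1)).any().any():
        raise ParseError("cell fractions must lie in [0, 1]")
    return fr


def adjust_for_cell_composition(cohort: Cohort, fractions: pd.DataFrame,
                                stratify_by_sex: bool = True) -> Cohort:
    """Regress out cell composition; shift residuals to be non-negative.

    Per probe (and per sex stratum when ``stratify_by_sex``), betas are
    regressed on the five fractions plus an intercept by least squares;
    the residuals are then shifted up by |min residual| whenever the
    minimum is negative, so each probe/stratum series has minimum 0 (or
    its original non-negative minimum). Rank-deficient designs (e.g.
    identical fractions across samples) are handled by the pseudoinverse,
    which is equivalent to dropping collinear columns for the purpose of
    computing residuals.
    """
    missing = [s for s in cohort.sample_ids if s not in fractions.index]
    if missing:
        raise ParseError(f"samples without cell fractions: {missing}")

    strata = (cohort.split_by_sex().values() if stratify_by_sex else [cohort])
    pieces = {}
    for sub in strata:
        ids = sub.sample_ids
        X = np.column_stack([np.ones(len(ids)),
                             fractions.loc[ids, list(CELL_TYPES)].to_numpy()])
        if len(ids) < X.shape[1] + 2:
            raise ValueError(
                f"stratum with {len(ids)} samples is too small for "
                f"{X.shape[1]} regressors")
        B = sub.values()                        # probes x samples
        coef, *_ = np.linalg.lstsq(X, B.T, rcond=None)
        resid = B - (X @ coef).T
        mins = resid.min(axis=1, keepdims=True)
        resid = resid + np.where(mins < 0, -mins, 0.0)
        for j, s in enumerate(ids):
            pieces[s] = resid[:, j]

    values = np.column_stack([pieces[s] for s in cohort.sample_ids])
    beta = pd.DataFrame(values, index=cohort.probe_ids, columns=cohort.sample_ids)
    return Cohort(beta, cohort.samples, value_type="residual")
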