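"""In-memory containers for methylation cohorts.

A :class:`Cohort` couples a probes-by-samples matrix of methylation beta
values (fractions in [0, 1]) with a per-sample metadata table (individual,
age, sex, optional twin pairing, dataset label). Residualized cohorts reuse
the same container with ``value_type="residual"``, in which case values may
exceed 1 after the positivity shift.
"""
from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

VALID_SEXES = ("female", "male")

#: Required columns of a sample sheet, in canonical order.
SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "individual_id",
    "age",
    "sex",
    "twin_pair_id",
    "dataset",
]


class CohortError(ValueError):
    """Raised when a cohort violates its structural invariants."""


class Cohort:
    """Beta matrix plus sample metadata.

    Parameters
    ----------
    beta
        DataFrame of shape (n_probes, n_samples); index = probe ids,
        columns = sample ids, values in [0, 1] for ``value_type="beta"``.
    samples
        DataFrame with one row per sample, columns as in
        :data:`SAMPLE_SHEET_COLUMNS` (``twin_pair_id`` and ``dataset``
        optional). Row order defines the canonical sample order; the beta
        columns are reindexed to it.
    value_type
        ``"beta"`` (bounded in [0, 1]) or ``"residual"`` (only required to
        be finite and non-negative after shifting).
    """

    def __init__(self, beta: pd.DataFrame, samples: pd.DataFrame,
                 value_type: str = "beta"):
        if value_type not in ("beta", "residual"):
            raise CohortError(f"unknown value_type {value_type!r}")
        samples = samples.copy()
        if "twin_pair_id" not in samples.columns:
            samples["twin_pair_id"] = pd.NA
        if "dataset" not in samples.columns:
            samples["dataset"] = "unknown"
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
        if missing:
            raise CohortError(f"sample sheet missing columns: {missing}")
        samples = samples[SAMPLE_SHEET_COLUMNS].reset_index(drop=True)

        if samples["sample_id"].duplicated().any():
            dupes = samples.loc[samples["sample_id"].duplicated(), "sample_id"]
            raise CohortError(f"duplicate sample ids: {sorted(set(dupes))}")

        sheet_ids = list(samples["sample_id"])
        matrix_ids = list(beta.columns)
        only_matrix = sorted(set(matrix_ids) - set(sheet_ids))
        only_sheet = sorted(set(sheet_ids) - set(matrix_ids))
        if only_matrix or only_sheet:
            raise CohortError(
                "sample ids do not reconcile: "
                f"in matrix only {only_matrix}; in sheet only {only_sheet}"
            )

        if beta.index.has_duplicates:
            raise CohortError("duplicate probe ids in beta matrix")
        if beta.index.isna().any():
            raise CohortError("missing probe ids in beta matrix")

        ages = pd.to_numeric(samples["age"], errors="coerce")
        if ages.isna().any() or (ages < 0).any():
            bad = samples.loc[ages.isna() | (ages < 0), "sample_id"].tolist()
            raise CohortError(f"invalid (missing or negative) ages for samples {bad}")
        samples["age"] = ages.astype(float)

        bad_sex = ~samples["sex"].isin(VALID_SEXES)
        if bad_sex.any():
            raise CohortError(
                "sex must be one of "
                f"{VALID_SEXES}; offending samples "
                f"{samples.loc[bad_sex, 'sample_id'].tolist()}"
            )

        self._check_twins(samples)

        beta = beta[sheet_ids].astype(float)
        values = beta.to_numpy()
        if not np.isfinite(values).all():
            raise CohortError("beta matrix contains non-finite values")
        if value_type == "beta" and ((values < 0) | (values > 1)).any():
            i, j = np.argwhere((values < 0) | (values > 1))[0]
            raise CohortError(
                f"beta value out of [0, 1] at probe {beta.index[i]!r}, "
                f"sample {beta.columns[j]!r}: {values[i, j]}"
            )

        self.beta = beta
        self.samples = samples
        self.value_type = value_type

    @staticmethod
    def _check_twins(samples: pd.DataFrame) -> None:
        paired = samples.dropna(subset=["twin_pair_id"])
        for pair_id, grp in paired.groupby("twin_pair_id"):
            inds = grp.drop_duplicates("individual_id")
            if len(inds) != 2:
                raise CohortError(
                    f"twin pair {pair_id!r} has {len(inds)} individuals, expected 2"
                )
            sex_per_ind = grp.groupby("individual_id")["sex"].nunique()
            if (sex_per_ind > 1).any():
                raise CohortError(f"inconsistent sex within individual in pair {pair_id!r}")

    # ------------------------------------------------------------------
    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def probe_ids(self) -> list:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list:
        return list(self.samples["sample_id"])

    @property
    def ages(self) -> np.ndarray:
        return self.samples["age"].to_numpy()

    def values(self) -> np.ndarray:
        """Matrix view, shape (n_probes, n_samples)."""
        return self.beta.to_numpy()

    # ------------------------------------------------------------------
    def subset(self, probes: Iterable | None = None,
               samples: Iterable | None = None) -> "Cohort":
        beta = self.beta
        if probes is not None:
            probes = list(probes)
            missing = set(probes) - set(beta.index)
            if missing:
                raise CohortError(f"unknown probes requested: {sorted(missing)}")
            beta = beta.loc[probes]
        sheet = self.samples
        if samples is not None:
            samples = list(samples)
            sheet = sheet[sheet["sample_id"].isin(samples)]
            beta = beta[list(sheet["sample_id"])]
        return Cohort(beta, sheet, value_type=self.value_type)

    def split_by_sex(self) -> dict:
        """Return ``{sex: sub-cohort}`` for each sex present."""
        out = {}
        for sex in VALID_SEXES:
            ids = self.samples.loc[self.samples["sex"] == sex, "sample_id"]
            if len(ids):
                out[sex] = self.subset(samples=ids)
        return out

    def individuals(self) -> dict:
        """Map individual id -> sample sheet rows sorted by age."""
        return {
            ind: grp.sort_values("age")
            for ind, grp in self.samples.groupby("individual_id", sort=True)
        }

    def twin_pairs(self):
        """Same-sex twin pairs as (pair_id, individual_a, individual_b).

        Opposite-sex pairs are excluded; their ids are returned separately
        so callers can log them.
        """
        pairs, excluded = [], []
        tw = self.samples.dropna(subset=["twin_pair_id"])
        for pair_id, grp in tw.groupby("twin_pair_id"):
            inds = grp.drop_duplicates("individual_id")
            a, b = list(inds["individual_id"])[:2]
            if inds["sex"].nunique() == 1:
                pairs.append((pair_id, a, b))
            else:
                excluded.append(pair_id)
        return pairs, excluded

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Cohort({self.n_probes} probes x {self.n_samples} samples, "
                f"value_type={self.value_type!r})")
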