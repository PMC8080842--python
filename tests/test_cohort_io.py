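"""Containers, file round trips and cell-composition residualization."""
import numpy as np
import pandas as pd
import pytest

import methylvar as mv
from methylvar.io import CELL_TYPES, ParseError, read_probe_annotation

from conftest import make_cohort


class TestCohort:
    def test_reorders_beta_columns_to_sheet_order(self):
        cohort = make_cohort([[0.1, 0.2, 0.3]], ages=[30, 40, 50])
        shuffled = mv.Cohort(cohort.beta[["s0002", "s0000", "s0001"]],
                             cohort.samples)
        assert shuffled.sample_ids == cohort.sample_ids
        assert np.allclose(shuffled.values(), cohort.values())

    def test_rejects_out_of_range_beta_with_location(self):
        with pytest.raises(mv.CohortError, match="cg00000.*s0001"):
            make_cohort([[0.1, 1.2]], ages=[30, 40])

    def test_rejects_unreconciled_sample_ids(self):
        cohort = make_cohort([[0.1, 0.2]], ages=[30, 40])
        with pytest.raises(mv.CohortError, match="s0001"):
            mv.Cohort(cohort.beta, cohort.samples.iloc[:1])

    def test_rejects_negative_age_and_bad_sex(self):
        with pytest.raises(mv.CohortError, match="age"):
            make_cohort([[0.1]], ages=[-1.0])
        with pytest.raises(mv.CohortError, match="sex"):
            make_cohort([[0.1]], ages=[10], sexes=["unknown"])

    def test_twin_pair_must_have_two_individuals(self):
        with pytest.raises(mv.CohortError, match="tp1"):
            make_cohort([[0.1, 0.2, 0.3]], ages=[30, 40, 50],
                        twin_pair_ids=["tp1", "tp1", "tp1"])

    def test_split_by_sex_partitions_samples(self):
        cohort = make_cohort([[0.1, 0.2, 0.3, 0.4]], ages=[30, 40, 50, 60],
                             sexes=["male", "female", "male", "female"])
        parts = cohort.split_by_sex()
        assert {s.n_samples for s in parts.values()} == {2}
        assert sum(s.n_samples for s in parts.values()) == 4


class TestRoundTrip:
    @pytest.mark.parametrize("ext", ["tsv", "csv"])
    def test_cohort_round_trip_is_bit_stable(self, tmp_path, ext):
        rng = np.random.default_rng(0)
        cohort = make_cohort(rng.uniform(0.001, 0.999, (5, 4)),
                             ages=rng.uniform(20, 80, 4))
        bp, sp = tmp_path / f"b.{ext}", tmp_path / "s.csv"
        mv.write_cohort(cohort, bp, sp)
        back = mv.read_cohort(bp, sp)
        assert (back.values() == cohort.values()).all()
        assert back.sample_ids == cohort.sample_ids
        pd.testing.assert_series_equal(back.samples["age"],
                                       cohort.samples["age"])

    def test_read_rejects_out_of_unit_interval(self, tmp_path):
        cohort = make_cohort([[0.1, 0.2]], ages=[30, 40])
        bp, sp = tmp_path / "b.tsv", tmp_path / "s.csv"
        mv.write_cohort(cohort, bp, sp)
        text = bp.read_text().replace("0.2", "1.2")
        bp.write_text(text)
        with pytest.raises(ParseError, match="cg00000"):
            mv.read_cohort(bp, sp)

    def test_empty_probe_list_writes_header_only(self, tmp_path):
        cohort = make_cohort(np.empty((0, 2)), ages=[30, 40], probe_ids=[])
        mv.write_cohort(cohort, tmp_path / "b.tsv", tmp_path / "s.csv")
        assert len((tmp_path / "b.tsv").read_text().strip().splitlines()) == 1


class TestAnnotation:
    def test_parses_valid_rows(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("probe_id,chromosome,position,island_relation,"
                        "region_group,enhancer\n"
                        "cg000001,1,1000,Island,TSS1500,True\n")
        ann = read_probe_annotation(path)
        assert ann.loc["cg000001", "island_relation"] == "Island"
        assert bool(ann.loc["cg000001", "enhancer"]) is True

    def test_unknown_token_rejected_with_row(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("probe_id,chromosome,position,island_relation,"
                        "region_group,enhancer\n"
                        "cg1,1,5,Shore,Body,False\n")
        with pytest.raises(ParseError, match="Shore.*row 1"):
            read_probe_annotation(path)

    def test_empty_file_gives_empty_annotation(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("probe_id,chromosome,position,island_relation,"
                        "region_group,enhancer\n")
        assert read_probe_annotation(path).empty


def _fractions(sample_ids, rng):
    # independent draws (not summing to 1) keep the design full-rank
    raw = rng.uniform(0.05, 0.35, size=(len(sample_ids), 5))
    return pd.DataFrame(raw, index=pd.Index(sample_ids, name="sample_id"),
                        columns=list(CELL_TYPES))


class TestResidualization:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        n = 12
        cohort = make_cohort(rng.uniform(0.2, 0.8, (3, n)),
                             ages=rng.uniform(20, 80, n))
        fr = _fractions(cohort.sample_ids, rng)
        adj = mv.adjust_for_cell_composition(cohort, fr, stratify_by_sex=False)
        X = np.column_stack([np.ones(n), fr.to_numpy()])
        for i in range(3):
            y = cohort.values()[i]
            beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta_hat
            shifted = resid + max(0.0, -resid.min())
            assert np.allclose(adj.values()[i], shifted, atol=1e-10)

    def test_shift_makes_minimum_zero_when_negative(self):
        rng = np.random.default_rng(2)
        n = 10
        cohort = make_cohort(rng.uniform(0.2, 0.8, (4, n)),
                             ages=rng.uniform(20, 80, n))
        adj = mv.adjust_for_cell_composition(cohort,
                                             _fractions(cohort.sample_ids, rng),
                                             stratify_by_sex=False)
        mins = adj.values().min(axis=1)
        assert np.allclose(mins, 0.0, atol=1e-12)

    def test_exact_linear_dependence_gives_zero_residuals(self):
        rng = np.random.default_rng(3)
        n = 10
        fr = _fractions([f"s{i:04d}" for i in range(n)], rng)
        values = (0.2 + 0.5 * fr["CD8T"].to_numpy())[None, :]
        cohort = make_cohort(values, ages=rng.uniform(20, 80, n))
        adj = mv.adjust_for_cell_composition(cohort, fr, stratify_by_sex=False)
        assert np.allclose(adj.values(), 0.0, atol=1e-12)

    def test_collinear_fractions_degrade_to_mean_centering(self):
        # identical fractions across samples: design collapses to intercept
        rng = np.random.default_rng(4)
        n = 9
        fr = pd.DataFrame(np.tile([0.1, 0.3, 0.1, 0.2, 0.3], (n, 1)),
                          index=pd.Index([f"s{i:04d}" for i in range(n)],
                                         name="sample_id"),
                          columns=list(CELL_TYPES))
        y = rng.uniform(0.2, 0.8, (1, n))
        cohort = make_cohort(y, ages=rng.uniform(20, 80, n))
        adj = mv.adjust_for_cell_composition(cohort, fr, stratify_by_sex=False)
        centered = y[0] - y[0].mean()
        assert np.allclose(adj.values()[0], centered - centered.min(),
                           atol=1e-10)

    def test_reregression_on_fractions_gives_null_slopes(self):
        rng = np.random.default_rng(5)
        n = 30
        cohort = make_cohort(rng.uniform(0.2, 0.8, (5, n)),
                             ages=rng.uniform(20, 80, n),
                             sexes=["male"] * 15 + ["female"] * 15)
        fr = _fractions(cohort.sample_ids, rng)
        adj = mv.adjust_for_cell_composition(cohort, fr, stratify_by_sex=True)
        for sex, sub in adj.split_by_sex().items():
            X = np.column_stack([np.ones(sub.n_samples),
                                 fr.loc[sub.sample_ids].to_numpy()])
            for row in sub.values():
                coef, *_ = np.linalg.lstsq(X, row, rcond=None)
                assert np.all(np.abs(coef[1:]) < 1e-8)

    def test_too_few_samples_raises(self):
        rng = np.random.default_rng(6)
        cohort = make_cohort(rng.uniform(0.2, 0.8, (1, 6)),
                             ages=rng.uniform(20, 80, 6))
        with pytest.raises(ValueError, match="too small"):
            mv.adjust_for_cell_composition(cohort,
                                           _fractions(cohort.sample_ids, rng),
                                           stratify_by_sex=False)
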