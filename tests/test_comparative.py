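"""Two-contrast joins: Venn counts, divergence, concordance, correlation."""

import numpy as np
import pandas as pd
import pytest

from dmfkit.comparative import (
    VennCounts,
    concordance_summary,
    cross_cohort_diff,
    intersect_dmfs,
    inventory_by_region,
    pearson_common,
    select_divergent,
)


def dmf_table(ids, deltas, passes=True, start0=0):
    n = len(ids)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(start0, start0 + n) * 1000,
            "end": np.arange(start0, start0 + n) * 1000 + 100,
            "mean_case": 50.0 + np.asarray(deltas),
            "mean_ref": 50.0,
            "delta": np.asarray(deltas, dtype=float),
            "p": 0.01,
            "direction": ["hyper" if d > 0 else "hypo" for d in deltas],
            "passes": passes,
        },
        index=pd.Index(ids, name="fragment_id"),
    )


class TestIntersect:
    def test_published_cohort_sizes_force_venn(self):
        # 429- and 214-record sets sharing 118 fragments -> (311, 118, 96)
        shared = [f"s{i}" for i in range(118)]
        a = dmf_table(shared + [f"a{i}" for i in range(311)], [20.0] * 429)
        b_ids = shared + [f"b{i}" for i in range(96)]
        b = dmf_table(b_ids, [15.0] * 214)
        b.iloc[118:, b.columns.get_loc("start")] = (
            np.arange(118, 214) * 1000 + 7
        )  # distinct coords for the b-only fragments
        b.iloc[118:, b.columns.get_loc("end")] = np.arange(118, 214) * 1000 + 107
        common, venn = intersect_dmfs(a, b)
        assert venn == VennCounts(only_a=311, common=118, only_b=96)
        assert venn.size_a == 429 and venn.size_b == 214
        assert len(common) == 118

    def test_disjoint_and_identical(self):
        a = dmf_table(["x", "y"], [12, -15])
        b = dmf_table(["p", "q"], [11, 13], start0=50)
        common, venn = intersect_dmfs(a, b)
        assert len(common) == 0 and venn.common == 0
        common, venn = intersect_dmfs(a, a.copy())
        assert venn == VennCounts(0, 2, 0)
        assert np.allclose(common["delta_ab"], 0.0)

    def test_only_passing_records_count(self):
        a = dmf_table(["x", "y"], [12, 15])
        a.loc["y", "passes"] = False
        b = dmf_table(["x", "y"], [11, 13])
        _, venn = intersect_dmfs(a, b)
        assert (venn.only_a, venn.common, venn.only_b) == (0, 1, 1)

    def test_coordinate_mismatch_errors(self):
        a = dmf_table(["x"], [12])
        b = dmf_table(["x"], [11])
        b["start"] = 999
        with pytest.raises(ValueError, match="coordinate"):
            intersect_dmfs(a, b)


class TestCrossCohortDiff:
    @pytest.mark.parametrize(
        "da,db,expected",
        [(-13.9, 15.1, -29.0), (21.7, -11.1, 32.8), (5.0, 5.0, 0.0)],
    )
    def test_examples(self, da, db, expected):
        assert cross_cohort_diff(da, db) == pytest.approx(expected)


class TestSelectDivergent:
    def test_strict_boundary(self):
        rec = pd.DataFrame({"delta_a": [10.0, 10.1, -12], "delta_b": [0.0, 0.0, -1.0]})
        out = select_divergent(rec, 10.0)
        assert list(out["delta_a"]) == [-12.0, 10.1]  # 10.0 excluded, sorted asc

    def test_empty_input(self):
        rec = pd.DataFrame({"delta_a": [], "delta_b": []})
        assert len(select_divergent(rec)) == 0

    def test_matches_brute_force_filter(self, rng):
        rec = pd.DataFrame(
            {"delta_a": rng.uniform(-40, 40, 200), "delta_b": rng.uniform(-40, 40, 200)}
        )
        out = select_divergent(rec, 10.0)
        expect = [
            i
            for i in rec.index
            if abs(rec.delta_a[i] - rec.delta_b[i]) > 10.0
        ]
        assert sorted(out.index) == sorted(expect)
        assert (out["delta_ab"].diff().dropna() >= 0).all()


class TestConcordance:
    def test_single_record_classes(self):
        s = concordance_summary(pd.DataFrame({"delta_a": [5.0], "delta_b": [3.0]}))
        assert (s.both_hyper, s.hyper_larger_a) == (1, 1)
        s = concordance_summary(pd.DataFrame({"delta_a": [-5.0], "delta_b": [3.0]}))
        assert (s.opposite, s.opposite_hyper_b) == (1, 1)

    def test_partition_invariant(self, rng):
        rec = pd.DataFrame(
            {"delta_a": rng.uniform(-30, 30, 100), "delta_b": rng.uniform(-30, 30, 100)}
        )
        s = concordance_summary(rec)
        assert s.both_hyper + s.both_hypo + s.opposite + s.unchanged == s.n

    def test_global_sign_flip_swaps_hyper_hypo(self, rng):
        rec = pd.DataFrame(
            {"delta_a": rng.uniform(-30, 30, 80), "delta_b": rng.uniform(-30, 30, 80)}
        )
        s1 = concordance_summary(rec)
        s2 = concordance_summary(-rec)
        assert (s1.both_hyper, s1.both_hypo) == (s2.both_hypo, s2.both_hyper)
        assert s1.opposite == s2.opposite

    def test_zero_delta_goes_to_unchanged(self):
        s = concordance_summary(pd.DataFrame({"delta_a": [0.0], "delta_b": [12.0]}))
        assert s.unchanged == 1
        assert s.both_hyper == s.both_hypo == s.opposite == 0


class TestPearson:
    def test_trivial_cases(self):
        rec = pd.DataFrame(
            {"mean_case_a": [1.0, 2, 3], "mean_case_b": [1.0, 2, 3]}
        )
        assert pearson_common(rec) == pytest.approx(1.0)
        rec["mean_case_b"] = [6.0, 4, 2]
        assert pearson_common(rec) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.uniform(0, 100, 50)
        y = 0.7 * x + rng.normal(0, 10, 50)
        rec = pd.DataFrame({"mean_case_a": x, "mean_case_b": y})
        r = pearson_common(rec)
        manual = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(manual, rel=1e-12)

    def test_symmetry_and_affine_invariance(self, rng):
        x = rng.uniform(0, 100, 30)
        y = rng.uniform(0, 100, 30)
        a = pearson_common(pd.DataFrame({"mean_case_a": x, "mean_case_b": y}))
        b = pearson_common(pd.DataFrame({"mean_case_a": y, "mean_case_b": x}))
        c = pearson_common(
            pd.DataFrame({"mean_case_a": 3 * x + 5, "mean_case_b": y})
        )
        assert a == pytest.approx(b)
        assert a == pytest.approx(c)

    def test_deltas_mode_and_errors(self):
        rec = pd.DataFrame(
            {"delta_a": [1.0, 2, 3], "delta_b": [2.0, 4, 6],
             "mean_case_a": [5.0, 5, 5], "mean_case_b": [1.0, 2, 3]}
        )
        assert pearson_common(rec, mode="deltas") == pytest.approx(1.0)
        with pytest.raises(ValueError, match="zero variance"):
            pearson_common(rec)
        with pytest.raises(ValueError, match="at least 3"):
            pearson_common(rec.iloc[:2], mode="deltas")


def test_inventory_partitions_by_region():
    rec = pd.DataFrame(
        {
            "location": ["promoter", "promoter", "exon", "exon", "exon"],
            "delta_a": [5.0, -4.0, 3.0, -2.0, 6.0],
            "delta_b": [4.0, -1.0, 2.0, 3.0, 5.0],
        }
    )
    tables, tally = inventory_by_region(rec)
    assert set(tables) == {"promoter", "exon"}
    assert tally.loc["promoter", "hyper_in_both"] == 1
    assert tally.loc["promoter", "hypo_in_both"] == 1
    assert tally.loc["exon", "discordant"] == 1
    assert tally["n"].sum() == len(rec)
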