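"""Coverage parsing, fragment aggregation, completeness filter, summaries."""

import logging

import numpy as np
import pandas as pd
import pytest

from dmfkit.coverage import (
    CoverageParseError,
    FragmentMatrix,
    SampleSheet,
    aggregate_to_fragments,
    build_matrix,
    destrand_calls,
    filter_complete,
    global_summaries,
    read_bismark_coverage,
)
from dmfkit.digest import FragmentCatalog


def make_catalog(cpgs_per_fragment):
    """Catalog of adjacent 50 bp fragments on chr1 with given CpG positions."""
    rows, pos = [], []
    for i, cpgs in enumerate(cpgs_per_fragment):
        start = i * 50
        rows.append(("chr1", start, start + 50, f"chr1:{start}-{start + 50}", 50, False, len(cpgs)))
        pos.append(np.asarray(cpgs))
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "fragment_id", "length", "terminal", "n_cpg"]
    )
    return FragmentCatalog(frame=frame, cpg_positions=pos)


def calls_frame(items):
    return pd.DataFrame(items, columns=["chrom", "pos", "meth", "unmeth"])


class TestReadBismark:
    def test_example_line(self, tmp_path):
        p = tmp_path / "s.cov"
        p.write_text("chr1\t105\t105\t80\t8\t2\n")
        calls = read_bismark_coverage(p)
        assert calls.iloc[0].tolist() == ["chr1", 104, 8, 2]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.cov"
        p.write_text("")
        assert read_bismark_coverage(p).empty

    def test_percent_disagreement_warns_counts_win(self, tmp_path, caplog):
        p = tmp_path / "w.cov"
        p.write_text("chr1\t10\t10\t10\t8\t2\n")  # counts say 80%
        with caplog.at_level(logging.WARNING, logger="dmfkit.coverage"):
            calls = read_bismark_coverage(p)
        assert "counts win" in caplog.text
        assert calls.iloc[0].meth == 8

    @pytest.mark.parametrize(
        "line", ["chr1\t10\t10\t50\tfive\t5", "chr1\t10\t5\t50\t5\t5", "chr1\t10\t10\t50\t-1\t5", "chr1\t10\t10"]
    )
    def test_bad_lines_name_line_number(self, tmp_path, line):
        p = tmp_path / "bad.cov"
        p.write_text("chr1\t5\t5\t100\t3\t0\n" + line + "\n")
        with pytest.raises(CoverageParseError, match="line 2"):
            read_bismark_coverage(p)


class TestDestrand:
    def test_adjacent_pair_merged_and_idempotent(self):
        calls = calls_frame([("chr1", 10, 3, 1), ("chr1", 11, 2, 2)])
        once = destrand_calls(calls)
        assert once.pos.tolist() == [10]
        assert once.meth.tolist() == [5]
        pd.testing.assert_frame_equal(destrand_calls(once), once)

    def test_known_cpg_set_is_exact(self):
        # both 10 and 11 are real plus-strand CpGs (CGCG): no merging
        calls = calls_frame([("chr1", 10, 3, 1), ("chr1", 11, 2, 2)])
        out = destrand_calls(calls, {"chr1": np.array([10, 11])})
        assert out.pos.tolist() == [10, 11]

    def test_commutes_with_aggregation(self):
        cat = make_catalog([[10, 20]])
        stranded = calls_frame(
            [("chr1", 10, 6, 0), ("chr1", 11, 4, 2), ("chr1", 20, 5, 5)]
        )
        merged = calls_frame([("chr1", 10, 10, 2), ("chr1", 20, 5, 5)])
        a = aggregate_to_fragments(
            destrand_calls(stranded, {"chr1": np.array([10, 20])}), cat
        )
        b = aggregate_to_fragments(merged, cat)
        pd.testing.assert_frame_equal(a, b)


class TestAggregate:
    def test_weighted_mean_example(self):
        cat = make_catalog([[10, 20]])
        calls = calls_frame([("chr1", 10, 8, 2), ("chr1", 20, 2, 8)])
        out = aggregate_to_fragments(calls, cat)
        assert out.percent.iloc[0] == pytest.approx(50.0)
        assert out.total_reads.iloc[0] == 20

    def test_unweighted_mode(self):
        cat = make_catalog([[10, 20]])
        calls = calls_frame([("chr1", 10, 9, 1), ("chr1", 20, 1, 9)])
        out = aggregate_to_fragments(calls, cat, weighted=False)
        assert out.percent.iloc[0] == pytest.approx(50.0)

    def test_min_cpgs_threshold(self):
        cat = make_catalog([[10, 20]])
        calls = calls_frame([("chr1", 10, 30, 0)])
        out = aggregate_to_fragments(calls, cat, min_cpgs=2)
        assert np.isnan(out.percent.iloc[0])
        assert out.n_cpgs.iloc[0] == 1

    def test_min_reads_threshold(self):
        cat = make_catalog([[10, 20]])
        calls = calls_frame([("chr1", 10, 3, 1), ("chr1", 20, 2, 3)])
        assert np.isnan(
            aggregate_to_fragments(calls, cat, min_total_reads=10).percent.iloc[0]
        )
        assert aggregate_to_fragments(calls, cat, min_total_reads=9).percent.iloc[
            0
        ] == pytest.approx(100 * 5 / 9)

    def test_off_catalog_positions_ignored(self):
        cat = make_catalog([[10, 20]])
        calls = calls_frame(
            [("chr1", 10, 5, 5), ("chr1", 20, 5, 5), ("chr1", 999, 9, 9)]
        )
        out = aggregate_to_fragments(calls, cat)
        assert out.total_reads.iloc[0] == 20

    def test_matches_brute_force_oracle_on_simulation(self, sim):
        sample = sim.sheet.samples[0]
        calls = sim.calls_by_sample[sample]
        out = aggregate_to_fragments(calls, sim.catalog, min_total_reads=1, min_cpgs=1)
        lookup = {
            (c, p): (m, u)
            for c, p, m, u in calls.itertuples(index=False)
        }
        for row, cpgs, got in zip(
            sim.catalog.frame.itertuples(), sim.catalog.cpg_positions, out.itertuples()
        ):
            meth = tot = 0
            for p in cpgs:
                m, u = lookup.get((row.chrom, p), (0, 0))
                meth += m
                tot += m + u
            assert got.total_reads == tot  # conservation of read counts
            if tot > 0:
                assert got.percent == pytest.approx(100 * meth / tot)
            else:
                assert np.isnan(got.percent)


class TestFilterComplete:
    def test_single_missing_sample_drops_fragment(self, matrix):
        complete = filter_complete(matrix)
        mask = matrix.percent.notna().all(axis=1)  # oracle over the missingness mask
        assert len(complete) == int(mask.sum())
        assert set(complete.percent.index) == set(matrix.percent.index[mask])

    def test_monotone_in_samples(self, matrix):
        all_groups = filter_complete(matrix)
        two_groups = filter_complete(matrix, groups=["HC", "LC"])
        assert set(all_groups.percent.index) <= set(two_groups.percent.index)

    def test_empty_group_errors(self, matrix):
        with pytest.raises(KeyError):
            filter_complete(matrix, groups=["nope"])


class TestSampleSheet:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SampleSheet(pd.DataFrame({"sample_id": ["a", "a"], "group": ["x", "y"]}))

    def test_testability_requirements(self):
        sheet = SampleSheet(
            pd.DataFrame({"sample_id": ["a", "b", "c"], "group": ["x", "x", "y"]})
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            sheet.require_testable()
        with pytest.raises(ValueError, match="two groups"):
            SampleSheet(
                pd.DataFrame({"sample_id": ["a", "b"], "group": ["x", "x"]})
            ).require_testable()


def test_global_summaries_constant_and_midpoint():
    sheet = SampleSheet(
        pd.DataFrame({"sample_id": ["a", "b"], "group": ["g1", "g2"]})
    )
    shape = pd.DataFrame({"a": [50.0, 50.0], "b": [0.0, 100.0]}, index=["f1", "f2"])
    m = FragmentMatrix(
        percent=shape, coverage=shape * 0, cpg_count=shape * 0, sheet=sheet
    )
    summ = global_summaries(m).set_index("group")
    assert summ.loc["g1", "median"] == 50.0
    assert summ.loc["g2", "median"] == 50.0  # midpoint of 0 and 100


def test_matrix_roundtrip_preserves_missing(tmp_path, matrix):
    path = tmp_path / "m.tsv"
    matrix.write(path)
    back = FragmentMatrix.read(path, matrix.sheet)
    pd.testing.assert_frame_equal(
        back.percent, matrix.percent, check_exact=False, atol=1e-9
    )


def test_build_matrix_requires_all_samples(sim):
    partial = dict(list(sim.calls_by_sample.items())[:3])
    with pytest.raises(ValueError, match="no calls"):
        build_matrix(partial, sim.catalog, sim.sheet)
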