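"""Cohort statistics, filtering, Ago support and final selection."""

import numpy as np
import pandas as pd
import pytest

from snofrag.aligner import Alignment
from snofrag.cohort import (
    SelectionConfig,
    ago_support,
    build_expression_matrix,
    compute_cohort_stats,
    filter_differential,
    select_final_candidates,
)
from snofrag.fragcall import FragmentCall
from snofrag.ingest import Condition


def matrix_from(values, n_tumor, n_normal):
    """values: fragment_id -> list of RPMs, tumor samples first."""
    samples = [f"t{i}" for i in range(n_tumor)] + [f"n{i}" for i in range(n_normal)]
    conditions = {
        s: Condition.TUMOR if s.startswith("t") else Condition.NORMAL
        for s in samples
    }
    frame = pd.DataFrame(values, index=samples).T
    return build_expression_matrix(frame, conditions)


class TestBuildMatrix:
    def test_union_of_fragments_with_zero_fill(self):
        per_lib = {
            "t0": {"f1": 50.0, "f2": 10.0},
            "n0": {"f1": 40.0, "f3": 5.0},
        }
        mat = build_expression_matrix(
            per_lib, {"t0": Condition.TUMOR, "n0": Condition.NORMAL}
        )
        assert mat.values.shape == (3, 2)
        assert mat.values.loc["f2", "n0"] == 0.0
        assert mat.values.loc["f3", "t0"] == 0.0

    def test_single_library_is_column_vector(self):
        mat = build_expression_matrix(
            {"t0": {"f1": 1.0, "f2": 2.0}}, {"t0": Condition.TUMOR}
        )
        assert mat.values.shape == (2, 1)

    def test_unknown_library_rejected(self):
        with pytest.raises(KeyError, match="mystery"):
            build_expression_matrix({"mystery": {"f1": 1.0}}, {})

    def test_duplicate_fragment_rows_rejected(self):
        frame = pd.DataFrame(
            [[1.0], [2.0]], index=["f1", "f1"], columns=["t0"]
        )
        with pytest.raises(ValueError, match="duplicate"):
            build_expression_matrix(frame, {"t0": Condition.TUMOR})


class TestCohortStats:
    def test_prevalence_from_counts(self):
        # 40 RPM in 9/10 tumors and 2/5 normals
        mat = matrix_from(
            {"f1": [40.0] * 9 + [0.0] + [40.0] * 2 + [0.0] * 3}, 10, 5
        )
        stats = compute_cohort_stats(mat)
        assert stats.loc["f1", "prev_tumor"] == pytest.approx(0.9)
        assert stats.loc["f1", "prev_normal"] == pytest.approx(0.4)

    def test_identical_classes_give_unit_fold_change(self):
        mat = matrix_from({"f1": [50.0, 0.0, 100.0] * 2}, 3, 3)
        stats = compute_cohort_stats(mat)
        assert stats.loc["f1", "fold_change"] == 1.0

    def test_pseudocount_handles_all_zero_normals(self):
        mat = matrix_from({"f1": [99.0] * 4 + [0.0] * 2}, 4, 2)
        stats = compute_cohort_stats(mat)
        assert stats.loc["f1", "mean_rpm_tumor"] == 99.0
        assert stats.loc["f1", "fold_change"] == 100.0  # (99+1)/(0+1)

    def test_empty_class_rejected(self):
        frame = pd.DataFrame({"t0": {"f1": 1.0}})
        mat = build_expression_matrix(frame, {"t0": Condition.TUMOR})
        with pytest.raises(ValueError, match="at least one"):
            compute_cohort_stats(mat)

    def test_expressing_only_means_ignore_silent_samples(self):
        mat = matrix_from({"f1": [100.0, 0.0, 0.0, 50.0, 0.0]}, 3, 2)
        config = SelectionConfig(mean_over_expressing_only=True)
        stats = compute_cohort_stats(mat, config)
        assert stats.loc["f1", "mean_rpm_tumor"] == 100.0
        assert stats.loc["f1", "mean_rpm_normal"] == 50.0

    def test_raising_threshold_never_raises_prevalence(self):
        rng = np.random.default_rng(4)
        rpms = (rng.gamma(2, 60, size=20)).tolist()
        mat = matrix_from({"f1": rpms, "f2": rpms[::-1]}, 12, 8)
        prev = [
            compute_cohort_stats(
                mat, SelectionConfig(expressed_threshold=thr)
            )[["prev_tumor", "prev_normal"]]
            for thr in (10.0, 30.0, 90.0, 200.0)
        ]
        for lo, hi in zip(prev, prev[1:]):
            assert (hi.values <= lo.values).all()


def stats_frame(rows):
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "fragment_id"
    return frame


class TestFilterDifferential:
    def base_row(self, **kw):
        row = dict(
            prev_tumor=0.95, prev_normal=0.3, mean_rpm_tumor=100.0,
            mean_rpm_normal=20.0, fold_change=5.0,
        )
        row.update(kw)
        return row

    def test_fold_change_boundary(self):
        stats = stats_frame({
            "keep": self.base_row(fold_change=2.0),
            "drop": self.base_row(fold_change=1.9),
        })
        assert list(filter_differential(stats).index) == ["keep"]

    def test_tumor_prevalence_boundary(self):
        stats = stats_frame({
            "keep": self.base_row(prev_tumor=0.5),
            "drop": self.base_row(prev_tumor=0.49),
        })
        assert list(filter_differential(stats).index) == ["keep"]

    def test_ranking_matches_brute_force_sort(self):
        rng = np.random.default_rng(9)
        rows = {
            f"f{i}": self.base_row(
                prev_tumor=round(float(rng.uniform(0.3, 1.0)), 2),
                fold_change=round(float(rng.uniform(0.5, 8.0)), 2),
            )
            for i in range(12)
        }
        stats = stats_frame(rows)
        got = list(filter_differential(stats).index)
        expected = sorted(
            (
                fid
                for fid, r in rows.items()
                if r["fold_change"] >= 2.0 and r["prev_tumor"] >= 0.5
            ),
            key=lambda fid: (-rows[fid]["prev_tumor"], -rows[fid]["fold_change"], fid),
        )
        assert got == expected

    def test_raising_min_fold_shrinks_candidate_set(self):
        rng = np.random.default_rng(2)
        stats = stats_frame({
            f"f{i}": self.base_row(fold_change=float(rng.uniform(1, 6)))
            for i in range(20)
        })
        sizes = [
            filter_differential(stats, SelectionConfig(min_fold=mf)).shape[0]
            for mf in (1.5, 2.0, 3.0, 5.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestAgoSupport:
    frag = FragmentCall(
        fragment_id="SNO1:30-52", ncrna_id="SNO1", start=30, end=52,
        sequence="", read_support=10,
    )

    def ago(self, intervals, ncrna_id="SNO1"):
        return [
            Alignment(f"a{i}", ncrna_id, s, e)
            for i, (s, e) in enumerate(intervals)
        ]

    def test_contained_reads_counted(self):
        alns = self.ago([(30, 52), (31, 51), (32, 52), (29, 52), (80, 102)])
        assert ago_support(self.frag, alns) == 4

    def test_no_reads_on_precursor(self):
        assert ago_support(self.frag, self.ago([(10, 32)], "OTHER")) == 0

    def test_read_straddling_beyond_slop_excluded(self):
        assert ago_support(self.frag, self.ago([(25, 47)]), boundary_slop=3) == 0


class TestFinalSelection:
    def ranked(self, rows):
        return filter_differential(stats_frame(rows))

    @pytest.mark.parametrize(
        "prev_tumor,prev_normal,ago,kept",
        [
            (0.92, 0.40, 3, True),
            (0.92, 0.55, 3, False),  # normals too prevalent
            (0.95, 0.10, 0, False),  # no Ago association
            (0.90, 0.10, 3, False),  # bound is strict: > 0.9
        ],
    )
    def test_predicate_truth_table(self, prev_tumor, prev_normal, ago, kept):
        rows = {
            "f1": dict(
                prev_tumor=prev_tumor, prev_normal=prev_normal,
                mean_rpm_tumor=100.0, mean_rpm_normal=10.0, fold_change=5.0,
            )
        }
        final = select_final_candidates(self.ranked(rows), {"f1": ago})
        assert ("f1" in final.index) is kept

    def test_rank_order_preserved(self):
        rows = {
            "low": dict(prev_tumor=0.93, prev_normal=0.2, mean_rpm_tumor=1.0,
                        mean_rpm_normal=0.0, fold_change=2.5),
            "high": dict(prev_tumor=0.99, prev_normal=0.2, mean_rpm_tumor=1.0,
                         mean_rpm_normal=0.0, fold_change=2.5),
        }
        final = select_final_candidates(
            self.ranked(rows), {"low": 2, "high": 2}
        )
        assert list(final.index) == ["high", "low"]
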