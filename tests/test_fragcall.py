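"""Coverage profiles, Haar edge detection, fragment calling, RPM."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from snofrag.aligner import Alignment
from snofrag.fragcall import (
    CoverageProfile,
    FragCallParams,
    build_coverage,
    call_fragments,
    discover_on_pooled,
    haar_edge_scores,
    quantify_per_library,
    quantify_rpm,
)
from snofrag.ingest import NcRNARecord, RnaClass

from conftest import random_record


def make_record(length=120, rec_id="SNO1", seed=3):
    return random_record(np.random.default_rng(seed), rec_id, length)


def pulse_alignments(start, end, height, rec_id="SNO1", lib="lib1"):
    return [
        Alignment(read_id=f"r{i}", ncrna_id=rec_id, start=start, end=end,
                  library_id=lib)
        for i in range(height)
    ]


class TestBuildCoverage:
    def test_rectangular_pulse(self):
        rec = make_record()
        prof = build_coverage(pulse_alignments(20, 42, 10), rec)
        assert prof.depth[20:42].tolist() == [10] * 22
        assert prof.depth.sum() == 10 * 22
        assert (np.delete(prof.depth, range(20, 42)) == 0).all()

    def test_two_disjoint_pulses_are_additive(self):
        rec = make_record()
        alns = pulse_alignments(10, 32, 5) + pulse_alignments(60, 88, 3)
        prof = build_coverage(alns, rec)
        assert prof.depth[15] == 5 and prof.depth[70] == 3
        assert prof.depth.sum() == 5 * 22 + 3 * 28

    def test_empty_alignments(self):
        prof = build_coverage([], make_record())
        assert (prof.depth == 0).all() and prof.n_alignments == 0

    def test_out_of_bounds_alignment_rejected(self):
        rec = make_record(length=100)
        with pytest.raises(ValueError, match="outside"):
            build_coverage([Alignment("r", "SNO1", 90, 112)], rec)

    @given(st.lists(st.tuples(st.integers(0, 90), st.integers(16, 30)),
                    max_size=30))
    def test_depth_conserves_alignment_length(self, spans):
        rec = make_record(length=120)
        alns = [
            Alignment(f"r{i}", "SNO1", s, s + L) for i, (s, L) in enumerate(spans)
        ]
        prof = build_coverage(alns, rec)
        assert prof.depth.sum() == sum(L for _, L in spans)
        assert (prof.depth >= 0).all()


class TestHaarEdgeScores:
    def test_zero_profile_gives_zero_track(self):
        scores = haar_edge_scores(np.zeros(50), half_width=4)
        assert scores.shape == (51,) and (scores == 0).all()

    @pytest.mark.parametrize("h,w", [(5, 4), (20, 4), (7, 3)])
    def test_unit_step_response_is_triangular_with_apex_at_step(self, h, w):
        depth = np.zeros(80)
        s = 40
        depth[s:] = h
        scores = haar_edge_scores(depth, half_width=w)
        assert scores[s] == pytest.approx(h)
        for d in range(1, w + 1):  # closed form: h * (1 - d/w)
            assert scores[s - d] == pytest.approx(h * (w - d) / w)
            assert scores[s + d] == pytest.approx(h * (w - d) / w)
        assert abs(scores[: s - w]).max() == 0

    def test_pulse_boundaries_score_antisymmetrically(self):
        depth = np.zeros(100)
        depth[30:52] = 9
        scores = haar_edge_scores(depth, half_width=4)
        assert scores[30] == pytest.approx(9)
        assert scores[52] == pytest.approx(-9)


class TestCallFragments:
    def test_single_pulse_called_exactly(self):
        rec = make_record()
        prof = build_coverage(pulse_alignments(30, 52, 20), rec)
        (call,) = call_fragments(prof, sequence=rec.sequence)
        assert (call.start, call.end) == (30, 52)
        assert call.read_support == 20
        assert call.sequence == rec.sequence[30:52]
        assert call.fragment_id == "SNO1:30-52"

    def test_two_pulses_on_one_precursor(self):
        rec = make_record()
        alns = pulse_alignments(10, 32, 15) + pulse_alignments(60, 88, 25)
        calls = call_fragments(build_coverage(alns, rec), sequence=rec.sequence)
        assert [(c.start, c.end) for c in calls] == [(10, 32), (60, 88)]

    def test_uniform_low_coverage_yields_no_calls(self):
        prof = CoverageProfile(
            ncrna_id="SNO1", depth=np.ones(120, dtype=int), n_alignments=0
        )
        assert call_fragments(prof) == []

    def test_overlong_pulse_not_called(self):
        rec = make_record()
        prof = build_coverage(pulse_alignments(30, 75, 20), rec)  # 45 nt
        assert call_fragments(prof, sequence=rec.sequence) == []

    @pytest.mark.parametrize("background", [1, 2])
    def test_uniform_background_leaves_boundaries_unchanged(self, background):
        rec = make_record()
        prof = build_coverage(pulse_alignments(30, 52, 20), rec)
        prof.depth = prof.depth + background
        (call,) = call_fragments(prof, sequence=rec.sequence)
        assert (call.start, call.end) == (30, 52)

    def test_random_noise_free_pulses_recovered_exactly(self, rng):
        params = FragCallParams()
        for _ in range(100):
            n = int(rng.integers(80, 301))
            rec = random_record(rng, "R", n)
            L = int(rng.integers(params.len_min, params.len_max + 1))
            s = int(rng.integers(0, n - L + 1))
            h = int(rng.integers(params.min_support, 200))
            prof = build_coverage(pulse_alignments(s, s + L, h, "R"), rec)
            calls = call_fragments(prof, params, sequence=rec.sequence)
            assert [(c.start, c.end, c.read_support) for c in calls] == [
                (s, s + L, h)
            ]


class TestQuantifyRpm:
    @pytest.mark.parametrize(
        "support,total,expected",
        [(300, 10_000_000, 30.0), (0, 1000, 0.0), (711, 1_000_000, 711.0)],
    )
    def test_values(self, support, total, expected):
        assert quantify_rpm(support, total) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            quantify_rpm(5, 0)

    @given(st.integers(0, 10**6), st.integers(1, 10**8))
    def test_identity_up_to_ulp(self, n, total):
        assert quantify_rpm(n, total) * total / 1e6 == pytest.approx(
            n, rel=1e-12
        )


class TestTwoPassDiscovery:
    def setup_cohort(self):
        rec = make_record(length=150, rec_id="SNO1", seed=5)
        per_lib = {
            "lib1": pulse_alignments(40, 68, 30, lib="lib1"),
            "lib2": pulse_alignments(40, 68, 12, lib="lib2"),
            "lib3": pulse_alignments(40, 68, 18, lib="lib3"),
        }
        return rec, per_lib

    def test_shared_catalogue_and_per_library_rpm(self):
        rec, per_lib = self.setup_cohort()
        catalogue = discover_on_pooled(per_lib, [rec])
        assert [c.fragment_id for c in catalogue] == ["SNO1:40-68"]
        rpm = quantify_per_library(
            catalogue, per_lib, {"lib1": 1_000_000, "lib2": 100_000, "lib3": 10_000}
        )
        assert rpm.loc["SNO1:40-68"].tolist() == [30.0, 120.0, 1800.0]

    def test_fragment_absent_from_library_is_zero_rpm(self):
        rec, per_lib = self.setup_cohort()
        per_lib["lib2"] = []
        catalogue = discover_on_pooled(per_lib, [rec])
        rpm = quantify_per_library(
            catalogue, per_lib, {k: 1_000_000 for k in per_lib}
        )
        assert rpm.loc["SNO1:40-68", "lib2"] == 0.0
        assert rpm.loc["SNO1:40-68", "lib1"] > 0

    def test_empty_cohort_gives_empty_catalogue(self):
        rec, _ = self.setup_cohort()
        assert discover_on_pooled({}, [rec]) == []

    def test_catalogue_independent_of_library_order(self):
        rec, per_lib = self.setup_cohort()
        forward = discover_on_pooled(per_lib, [rec])
        reversed_order = discover_on_pooled(
            dict(reversed(list(per_lib.items()))), [rec]
        )
        assert forward == reversed_order
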