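import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from rose.comparison import (
    call_repressed_tss,
    deviation_histogram,
    match_tss_sets,
    venn_counts,
)
from rose.errors import ParameterError
from rose.io_formats import ReadStartProfile
from rose.tss_detection import DetectionParams, TSSCall


def optimal_matching_size_and_cost(query, reference, tolerance):
    """Maximum-cardinality, minimum-total-|deviation| assignment (Hungarian).

    Big-M penalties make cardinality dominate the total-deviation term.
    """
    nq, nr = len(query), len(reference)
    BIG = 10 * (tolerance + 1) * (nq + nr + 1)
    size = max(nq, nr)
    cost = np.full((size, size), BIG, dtype=float)
    for i, (qp, qs) in enumerate(query):
        for j, (rp, rs) in enumerate(reference):
            if qs == rs and abs(rp - qp) <= tolerance:
                cost[i, j] = abs(rp - qp)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(i, j) for i, j in zip(rows, cols)
             if i < nq and j < nr and cost[i, j] < BIG]
    return len(pairs), sum(cost[i, j] for i, j in pairs)


class TestMatching:
    def test_deviation_of_three_matches(self):
        report = match_tss_sets([(100, "+")], [(103, "+")], tolerance=3)
        (m,) = report.matches
        assert m.deviation == 3

    def test_beyond_tolerance(self):
        report = match_tss_sets([(100, "+")], [(104, "+")], tolerance=3)
        assert not report.matches
        assert report.query_only == [(100, "+")]
        assert report.reference_only == [(104, "+")]

    def test_one_to_one_prefers_exact(self):
        # brute force over one-to-one assignments of {100,101}x{101}: the
        # optimum pairs 101 with 101 (deviation 0) and leaves 100 unmatched
        report = match_tss_sets([(100, "+"), (101, "+")], [(101, "+")], tolerance=3)
        (m,) = report.matches
        assert (m.query_position, m.reference_position, m.deviation) == (101, 101, 0)
        assert report.query_only == [(100, "+")]

    def test_strand_mismatch_never_pairs(self):
        report = match_tss_sets([(100, "+")], [(100, "-")], tolerance=3)
        assert not report.matches

    def test_minus_strand_deviation_in_transcript_orientation(self):
        # reference downstream of the query on the minus strand means a
        # LOWER genomic coordinate, and the deviation is positive
        (m,) = match_tss_sets([(100, "-")], [(98, "-")], tolerance=3).matches
        assert m.deviation == 2

    def test_negative_tolerance_is_error(self):
        with pytest.raises(ParameterError):
            match_tss_sets([], [], tolerance=-1)

    @pytest.mark.parametrize("seed", range(30))
    def test_greedy_equals_optimal_assignment_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        q = [(int(p), "+") for p in rng.integers(1, 40, size=rng.integers(1, 13))]
        r = [(int(p), "+") for p in rng.integers(1, 40, size=rng.integers(1, 13))]
        report = match_tss_sets(q, r, tolerance=3)
        n_opt, cost_opt = optimal_matching_size_and_cost(q, r, 3)
        assert len(report.matches) == n_opt
        assert sum(abs(m.deviation) for m in report.matches) == cost_opt

    def test_cardinality_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        q = [(int(p), "+") for p in rng.integers(1, 200, size=40)]
        r = [(int(p), "+") for p in rng.integers(1, 200, size=35)]
        fwd = match_tss_sets(q, r, 3)
        rev = match_tss_sets(r, q, 3)
        assert len(fwd.matches) == len(rev.matches)

    def test_endpoints_unique(self):
        rng = np.random.default_rng(5)
        q = [(int(p), "+") for p in rng.integers(1, 100, size=50)]
        r = [(int(p), "+") for p in rng.integers(1, 100, size=50)]
        report = match_tss_sets(q, r, 3)
        q_used = [(m.query_position, m.strand) for m in report.matches]
        # counts of used endpoints never exceed their multiplicity in the input
        from collections import Counter

        assert not Counter(q_used) - Counter(q)
        assert len(report.matches) + len(report.query_only) == len(q)
        assert len(report.matches) + len(report.reference_only) == len(r)


class TestDeviationHistogram:
    def test_absolute_deviation_bins(self):
        report = match_tss_sets([(10, "+"), (20, "+"), (30, "+"), (40, "+")],
                                [(10, "+"), (20, "+"), (31, "+"), (39, "+")], 3)
        hist = deviation_histogram(report)
        assert hist == {0: 0.5, 1: 0.5}

    def test_all_exact(self):
        report = match_tss_sets([(10, "+")], [(10, "+")], 3)
        assert deviation_histogram(report) == {0: 1.0}

    def test_no_matches_is_error(self):
        report = match_tss_sets([(10, "+")], [(99, "+")], 3)
        with pytest.raises(ParameterError):
            deviation_histogram(report)


class TestVenn:
    def test_identical_sets(self):
        s = [(i * 50, "+") for i in range(1, 6)]
        counts = venn_counts(s, s, s, 3)
        assert counts["abc"] == 5
        assert sum(v for k, v in counts.items() if k != "abc") == 0

    def test_disjoint_sets(self):
        a = [(i, "+") for i in (100, 200)]
        b = [(i, "+") for i in (300, 400, 500)]
        c = [(i, "+") for i in (600, 700, 800, 900)]
        counts = venn_counts(a, b, c, 3)
        assert (counts["a_only"], counts["b_only"], counts["c_only"]) == (2, 3, 4)
        assert counts["ab"] == counts["ac"] == counts["bc"] == counts["abc"] == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_region_sums_are_partitions(self, seed):
        rng = np.random.default_rng(seed)
        def random_set(n):
            return [(int(p), "+" if rng.random() < 0.5 else "-")
                    for p in rng.integers(1, 300, size=n)]
        a, b, c = random_set(20), random_set(15), random_set(25)
        counts = venn_counts(a, b, c, 3)
        assert counts["a_only"] + counts["ab"] + counts["ac"] + counts["abc"] == len(a)
        assert sum(counts.values()) <= len(a) + len(b) + len(c)
        assert all(v >= 0 for v in counts.values())


def _call(pos, sample, count=100, strand="+"):
    return TSSCall("c", pos, strand, count, 20.0, sample)


class TestPanel:
    PANEL_KW = dict(rose_sample="rose", wildtype="wt", knockouts=["fur", "fis"])

    def test_repressed_by_fur(self):
        panel = {"rose": [_call(500, "rose", 1494)], "wt": [],
                 "fur": [_call(500, "fur", 300)], "fis": []}
        (call,) = call_repressed_tss(panel, **self.PANEL_KW)
        assert call.verdict == "repressed-by-fur"
        assert call.repressors == ("fur",)

    def test_constitutive_precedence(self):
        panel = {"rose": [_call(500, "rose")], "wt": [_call(500, "wt")],
                 "fur": [_call(500, "fur")], "fis": []}
        (call,) = call_repressed_tss(panel, **self.PANEL_KW)
        assert call.verdict == "constitutive"

    def test_in_vitro_only(self):
        # ndh-like: silent in the wildtype and in every single knockout
        panel = {"rose": [_call(500, "rose", 200)], "wt": [], "fur": [], "fis": []}
        (call,) = call_repressed_tss(panel, **self.PANEL_KW)
        assert call.verdict == "in-vitro-only"

    def test_verdicts_partition_candidates(self):
        rng = np.random.default_rng(2)
        panel = {s: [_call(int(p), s) for p in rng.integers(1, 500, size=12)]
                 for s in ("rose", "wt", "fur", "fis")}
        calls = call_repressed_tss(panel, **self.PANEL_KW, tolerance=2)
        assert calls
        for c in calls:
            assert sum([
                c.verdict == "constitutive",
                c.verdict.startswith("repressed-by-"),
                c.verdict == "in-vitro-only",
                c.verdict == "knockout-only",
            ]) == 1

    def test_unknown_sample_is_error(self):
        with pytest.raises(ParameterError):
            call_repressed_tss({"rose": []}, "rose", "wt", [])

    def test_profiles_detected_with_sample_thresholds(self):
        # sub-threshold reads in the wildtype (glcC-like trickle) do not
        # count as presence, so the promoter is still called repressed
        rose = ReadStartProfile("rose", "r", "c", {500: 493}, {})
        wt = ReadStartProfile("wt", "r", "c", {500: 2}, {})
        fur = ReadStartProfile("fur", "r", "c", {500: 35}, {})
        params = DetectionParams(3, 5, 50)
        calls = call_repressed_tss({"rose": rose, "wt": wt, "fur": fur},
                                   "rose", "wt", ["fur"], params=params)
        (call,) = calls
        assert call.verdict == "repressed-by-fur"
        assert call.read_starts["wt"] == 0  # no call in the wildtype
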