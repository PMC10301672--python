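"""Compare TSS catalogs with positional tolerance and call repressed promoters.

Two catalogs are matched one-to-one, pairing same-strand positions that
differ by at most ``tolerance`` nt (the pipeline default is 3 nt, which
absorbs template-supercoiling shifts between experimental methods).  The
matcher solves the exact assignment problem — maximum cardinality first,
then minimum total |deviation| — decomposed over connected components of
the candidate-pair graph, so it stays linear-ish in catalog size while
giving the provably optimal matching (a greedy nearest-first rule can
strand a matchable pair in chained configurations).

The knockout-panel caller labels every candidate TSS across a
ROSE/wildtype/knockout sample panel: *constitutive* (present in the
wildtype), *repressed-by-X* (present in vitro and in knockout X but absent
in the wildtype), *in-vitro-only* (present only in the run-off sample) or
*knockout-only*.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ParameterError
from .io_formats import ReadStartProfile
from .tss_detection import DetectionParams, TSSCall, detect_tss

PosStrand = tuple[int, str]


def _pos_strand(item) -> PosStrand:
    if isinstance(item, tuple):
        return int(item[0]), item[1]
    return int(item.position), item.strand


def _signed_deviation(query: int, reference: int, strand: str) -> int:
    """reference - query in transcript orientation (+ = reference downstream)."""
    return reference - query if strand == "+" else query - reference


@dataclass(frozen=True)
class TSSMatch:
    query_position: int
    reference_position: int
    strand: str
    deviation: int


@dataclass
class TSSMatchReport:
    matches: list[TSSMatch]
    query_only: list[PosStrand]
    reference_only: list[PosStrand]
    tolerance: int

    @property
    def n_query(self) -> int:
        return len(self.matches) + len(self.query_only)

    @property
    def match_fraction(self) -> float:
        return len(self.matches) / self.n_query if self.n_query else 0.0


def _candidate_pairs(
    q: list[PosStrand], r: list[PosStrand], tolerance: int
) -> list[tuple[int, int, int]]:
    """All same-strand (q_idx, r_idx, deviation) pairs within tolerance."""
    by_strand: dict[str, list[tuple[int, int]]] = {}
    for j, (rp, rs) in enumerate(r):
        by_strand.setdefault(rs, []).append((rp, j))
    for refs in by_strand.values():
        refs.sort()
    pairs = []
    for i, (qp, qs) in enumerate(q):
        refs = by_strand.get(qs, [])
        lo = bisect.bisect_left(refs, (qp - tolerance, -1))
        hi = bisect.bisect_right(refs, (qp + tolerance, len(r)))
        for rp, j in refs[lo:hi]:
            pairs.append((i, j, _signed_deviation(qp, rp, qs)))
    return pairs


def _match_indices(
    q: list[PosStrand], r: list[PosStrand], tolerance: int
) -> list[tuple[int, int, int]]:
    """Optimal one-to-one matching; returns (q_idx, r_idx, deviation).

    Maximum cardinality first, minimum total |deviation| second, computed
    exactly by solving an assignment problem on each connected component of
    the candidate-pair graph (components are small because candidate pairs
    only link positions within ``tolerance`` of each other).
    """
    import numpy as np
    from scipy.optimize import linear_sum_assignment

    pairs = _candidate_pairs(q, r, tolerance)
    if not pairs:
        return []

    # union-find over query nodes 0..nq-1 and reference nodes nq..nq+nr-1
    nq = len(q)
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i, j, _dev in pairs:
        union(i, nq + j)

    by_comp: dict[int, list[tuple[int, int, int]]] = {}
    for i, j, dev in pairs:
        by_comp.setdefault(find(i), []).append((i, j, dev))

    out: list[tuple[int, int, int]] = []
    for comp_pairs in by_comp.values():
        q_idx = sorted({i for i, _, _ in comp_pairs})
        r_idx = sorted({j for _, j, _ in comp_pairs})
        size = max(len(q_idx), len(r_idx))
        big = float((tolerance + 1) * (size + 1) * 10)
        cost = np.full((size, size), big)
        dev_of: dict[tuple[int, int], int] = {}
        qmap = {i: a for a, i in enumerate(q_idx)}
        rmap = {j: b for b, j in enumerate(r_idx)}
        for i, j, dev in comp_pairs:
            cost[qmap[i], rmap[j]] = abs(dev)
            dev_of[(i, j)] = dev
        rows, cols = linear_sum_assignment(cost)
        for a, b in zip(rows, cols):
            if a < len(q_idx) and b < len(r_idx) and cost[a, b] < big:
                i, j = q_idx[a], r_idx[b]
                out.append((i, j, dev_of[(i, j)]))
    return out


def match_tss_sets(
    query: Sequence, reference: Sequence, tolerance: int = 3
) -> TSSMatchReport:
    """One-to-one tolerance matching of two strand-annotated TSS catalogs.

    Items may be ``(position, strand)`` tuples or objects with ``position``
    and ``strand`` attributes.  Only same-strand pairs within ``tolerance``
    nt can match; deviations are signed reference - query in transcript
    orientation.
    """
    if tolerance < 0:
        raise ParameterError("tolerance must be non-negative")
    q = [_pos_strand(x) for x in query]
    r = [_pos_strand(x) for x in reference]
    pairs = _match_indices(q, r, tolerance)
    matched_q = {i for i, _, _ in pairs}
    matched_r = {j for _, j, _ in pairs}
    matches = sorted(
        (TSSMatch(q[i][0], r[j][0], q[i][1], dev) for i, j, dev in pairs),
        key=lambda m: (m.query_position, m.strand),
    )
    return TSSMatchReport(
        matches=matches,
        query_only=[q[i] for i in range(len(q)) if i not in matched_q],
        reference_only=[r[j] for j in range(len(r)) if j not in matched_r],
        tolerance=tolerance,
    )


def deviation_histogram(report: TSSMatchReport) -> dict[int, float]:
    """Fraction of matches at each absolute deviation; fractions sum to 1."""
    if not report.matches:
        raise ParameterError("no matches to histogram")
    counts: dict[int, int] = {}
    for m in report.matches:
        counts[abs(m.deviation)] = counts.get(abs(m.deviation), 0) + 1
    n = len(report.matches)
    return {d: c / n for d, c in sorted(counts.items())}


def venn_counts(
    set_a: Sequence, set_b: Sequence, set_c: Sequence, tolerance: int = 3
) -> dict[str, int]:
    """Three-way overlap counts under tolerance matching, anchored on set a.

    Tolerance matching is not transitive, so the Venn is anchor-based: each
    a-member is labeled by which of b and c it matches pairwise; the b- and
    c-only regions come from matching the leftovers of b and c against each
    other.  By construction |a| = a_only + ab + ac + abc.
    """
    a = [_pos_strand(x) for x in set_a]
    b = [_pos_strand(x) for x in set_b]
    c = [_pos_strand(x) for x in set_c]

    pairs_ab = _match_indices(a, b, tolerance)
    pairs_ac = _match_indices(a, c, tolerance)
    a_in_b = {i for i, _, _ in pairs_ab}
    a_in_c = {i for i, _, _ in pairs_ac}
    counts = {k: 0 for k in ("a_only", "b_only", "c_only", "ab", "ac", "bc", "abc")}
    for i in range(len(a)):
        hit_b, hit_c = i in a_in_b, i in a_in_c
        if hit_b and hit_c:
            counts["abc"] += 1
        elif hit_b:
            counts["ab"] += 1
        elif hit_c:
            counts["ac"] += 1
        else:
            counts["a_only"] += 1

    b_used = {j for _, j, _ in pairs_ab}
    c_used = {j for _, j, _ in pairs_ac}
    b_rest = [b[j] for j in range(len(b)) if j not in b_used]
    c_rest = [c[j] for j in range(len(c)) if j not in c_used]
    pairs_bc = _match_indices(b_rest, c_rest, tolerance)
    counts["bc"] = len(pairs_bc)
    counts["b_only"] = len(b_rest) - len(pairs_bc)
    counts["c_only"] = len(c_rest) - len(pairs_bc)
    return counts


# ---------------------------------------------------------------------------
# wildtype / knockout / in vitro panel
# ---------------------------------------------------------------------------

@dataclass
class PresenceCall:
    position: int
    strand: str
    present_in: dict[str, bool]
    read_starts: dict[str, int]
    verdict: str
    repressors: tuple[str, ...] = ()

    def as_record(self) -> dict:
        rec = {"position": self.position, "strand": self.strand, "verdict": self.verdict}
        for s, p in self.present_in.items():
            rec[f"present_{s}"] = p
            rec[f"reads_{s}"] = self.read_starts.get(s, 0)
        return rec


def call_repressed_tss(
    panel: Mapping[str, Sequence[TSSCall] | ReadStartProfile],
    rose_sample: str,
    wildtype: str,
    knockouts: Sequence[str],
    params: DetectionParams | Mapping[str, DetectionParams] | None = None,
    tolerance: int = 0,
) -> list[PresenceCall]:
    """Classify candidate TSSs by their presence pattern across a sample panel.

    ``panel`` maps sample id to either an already-detected TSS call list or a
    raw :class:`ReadStartProfile` (detected here with ``params``, which may be
    shared or per-sample).  Candidates are the union of all calls, merged at
    ``tolerance``.  "Absent" means the sample has no call within tolerance —
    a sub-threshold trickle of reads does not count as presence.

    Verdict precedence: constitutive > repressed-by-X > in-vitro-only >
    knockout-only, so verdicts partition the candidate set.
    """
    for sid in [rose_sample, wildtype, *knockouts]:
        if sid not in panel:
            raise ParameterError(f"unknown sample id {sid!r}")

    calls: dict[str, list[TSSCall]] = {}
    for sid, data in panel.items():
        if isinstance(data, ReadStartProfile):
            p = params.get(sid) if isinstance(params, Mapping) else params
            calls[sid] = detect_tss(data, p or DetectionParams())
        else:
            calls[sid] = list(data)

    by_strand: dict[str, list[tuple[int, str, int]]] = {}
    for sid, sample_calls in calls.items():
        for call in sample_calls:
            by_strand.setdefault(call.strand, []).append(
                (call.position, sid, call.read_starts)
            )
    out: list[PresenceCall] = []
    sample_ids = list(panel)
    for strand, items in by_strand.items():
        items.sort()
        clusters: list[list[tuple[int, str, int]]] = [[]]
        for item in items:
            if clusters[-1] and item[0] - clusters[-1][-1][0] > tolerance:
                clusters.append([])
            clusters[-1].append(item)
        for cluster in clusters:
            if not cluster:
                continue
            by_pos: dict[int, int] = {}
            present: dict[str, bool] = {s: False for s in sample_ids}
            reads: dict[str, int] = {s: 0 for s in sample_ids}
            for pos, sid, count in cluster:
                by_pos[pos] = by_pos.get(pos, 0) + count
                present[sid] = True
                reads[sid] += count
            consensus_pos = min(by_pos, key=lambda p: (-by_pos[p], p))
            repressors = tuple(sorted(k for k in knockouts if present[k]))
            if present[wildtype]:
                verdict = "constitutive"
            elif present[rose_sample] and repressors:
                verdict = "repressed-by-" + ",".join(repressors)
            elif present[rose_sample]:
                verdict = "in-vitro-only"
            else:
                verdict = "knockout-only"
            out.append(
                PresenceCall(consensus_pos, strand, present, reads, verdict, repressors)
            )
    out.sort(key=lambda c: (c.position, c.strand))
    return out
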