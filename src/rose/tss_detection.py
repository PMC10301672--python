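"""TSS calling from 5'-end read-start stacks and cross-replicate consensus.

A transcription start site shows up in a native-5'-end library as a sharp
stack of read 5'-ends at the +1 position.  A position is called when its
read-start count clears an absolute threshold and is strongly enriched over
the local read-start background immediately upstream on the same strand.
Replicate consensus keeps positions supported by a minimum number of
replicates (the default pipeline setting is 4 of 6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import NoSignalError, ParameterError
from .io_formats import ReadStartProfile

STRANDS = "+-"


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds for single-replicate TSS detection.

    ``min_read_starts`` is the absolute stack-height floor;
    ``min_fold_enrichment`` compares the stack against the mean read-start
    count over ``background_window`` nt strictly upstream (plus one
    pseudocount, so an isolated stack over a silent background has a finite
    fold value).
    """

    min_read_starts: int = 3
    min_fold_enrichment: float = 5.0
    background_window: int = 50
    auto_estimated: bool = False

    def __post_init__(self) -> None:
        if self.min_read_starts < 1:
            raise ParameterError("min_read_starts must be >= 1")
        if self.min_fold_enrichment < 1:
            raise ParameterError("min_fold_enrichment must be >= 1")
        if self.background_window < 1:
            raise ParameterError("background_window must be >= 1")


@dataclass(frozen=True)
class TSSCall:
    contig_id: str
    position: int
    strand: str
    read_starts: int
    fold_enrichment: float
    replicate_id: str

    def as_record(self) -> dict:
        return {
            "contig": self.contig_id,
            "position": self.position,
            "strand": self.strand,
            "read_starts": self.read_starts,
            "fold": round(self.fold_enrichment, 4),
            "replicate": self.replicate_id,
        }


@dataclass
class ConsensusTSS:
    contig_id: str
    position: int
    strand: str
    n_support: int
    per_replicate_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_read_starts(self) -> int:
        return sum(self.per_replicate_counts.values())

    def as_record(self) -> dict:
        return {
            "contig": self.contig_id,
            "position": self.position,
            "strand": self.strand,
            "support": self.n_support,
            "total_read_starts": self.total_read_starts,
        }


def estimate_params(
    profile: ReadStartProfile,
    target_quantile: float = 0.9,
    min_fold_enrichment: float = 5.0,
    background_window: int = 50,
) -> DetectionParams:
    """Data-adaptive threshold estimation for one replicate.

    ``min_read_starts`` is the ceiling of the ``target_quantile`` quantile
    (upper nearest-rank interpolation) of the nonzero per-position read-start
    counts, floored at 3 reads.  The fold threshold stays at its fixed
    default.  Raises :class:`NoSignalError` on an all-zero profile.
    """
    if not 0 < target_quantile < 1:
        raise ParameterError("target_quantile must be in (0, 1)")
    nonzero = np.array(
        [c for c in profile.counts_fw.values() if c > 0]
        + [c for c in profile.counts_rv.values() if c > 0]
    )
    if nonzero.size == 0:
        raise NoSignalError(f"no signal in {profile.sample_id}/{profile.replicate_id}")
    q = float(np.quantile(nonzero, target_quantile, method="higher"))
    return DetectionParams(
        min_read_starts=max(3, math.ceil(q)),
        min_fold_enrichment=min_fold_enrichment,
        background_window=background_window,
        auto_estimated=True,
    )


def _upstream_background_mean(
    arr: np.ndarray, pos: int, strand: str, window: int, circular: bool
) -> float:
    """Mean read-start count over ``window`` nt strictly upstream of ``pos``.

    Upstream means lower coordinates on + and higher on -.  On circular
    contigs the window wraps; on linear contigs it is truncated at the
    boundary (mean over the positions that exist; 0.0 if none).
    """
    length = arr.size  # index 0 == position 1
    idx = pos - 1
    if strand == "+":
        if circular:
            sel = (np.arange(idx - window, idx)) % length
        else:
            lo = max(0, idx - window)
            sel = np.arange(lo, idx)
    else:
        if circular:
            sel = (np.arange(idx + 1, idx + 1 + window)) % length
        else:
            hi = min(length, idx + 1 + window)
            sel = np.arange(idx + 1, hi)
    if sel.size == 0:
        return 0.0
    return float(arr[sel].mean())


def detect_tss(
    profile: ReadStartProfile,
    params: DetectionParams,
    contig_length: int | None = None,
    circular: bool = False,
) -> list[TSSCall]:
    """Call TSS positions in one replicate.

    Position p on strand s is called iff count(p) >= min_read_starts and
    count(p) / (1 + mean upstream background) >= min_fold_enrichment, where
    the background is the mean read-start count over ``background_window``
    positions strictly upstream of p on s (excluding p itself).
    """
    length = contig_length or profile.max_position
    calls: list[TSSCall] = []
    for strand in STRANDS:
        counts = profile.counts(strand)
        if not counts:
            continue
        arr = np.zeros(length, dtype=np.int64)
        for pos, c in counts.items():
            if not 1 <= pos <= length:
                raise ParameterError(f"position {pos} outside contig of length {length}")
            arr[pos - 1] = c
        candidates = np.flatnonzero(arr >= params.min_read_starts) + 1
        for pos in candidates:
            bg = _upstream_background_mean(arr, int(pos), strand, params.background_window, circular)
            fold = arr[pos - 1] / (1.0 + bg)
            if fold >= params.min_fold_enrichment:
                calls.append(
                    TSSCall(
                        contig_id=profile.contig_id,
                        position=int(pos),
                        strand=strand,
                        read_starts=int(arr[pos - 1]),
                        fold_enrichment=float(fold),
                        replicate_id=profile.replicate_id,
                    )
                )
    calls.sort(key=lambda c: (c.position, c.strand))
    return calls


def pool_profiles(
    profiles: list[ReadStartProfile],
    sample_id: str | None = None,
) -> ReadStartProfile:
    """Sum read-start counts across replicates into one pooled profile."""
    if not profiles:
        raise ParameterError("no profiles to pool")
    pooled_fw: dict[int, int] = {}
    pooled_rv: dict[int, int] = {}
    for prof in profiles:
        for target, counts in ((pooled_fw, prof.counts_fw), (pooled_rv, prof.counts_rv)):
            for pos, c in counts.items():
                target[pos] = target.get(pos, 0) + c
    return ReadStartProfile(
        sample_id=sample_id or profiles[0].sample_id,
        replicate_id="pooled",
        contig_id=profiles[0].contig_id,
        counts_fw=pooled_fw,
        counts_rv=pooled_rv,
    )


def consensus_tss(
    calls_by_replicate: list[list[TSSCall]],
    min_support: int = 4,
    merge_tolerance: int = 0,
) -> list[ConsensusTSS]:
    """Cluster per-replicate calls into consensus TSSs.

    Same-strand calls within ``merge_tolerance`` nt are clustered by
    single linkage across replicates.  The consensus position of a cluster
    is the member position with the highest summed read starts (ties break
    to the smallest position); clusters supported by fewer than
    ``min_support`` distinct replicates are dropped.
    """
    n_replicates = len(calls_by_replicate)
    if min_support > n_replicates:
        raise ParameterError(
            f"min_support {min_support} exceeds number of replicates {n_replicates}"
        )
    if merge_tolerance < 0:
        raise ParameterError("merge_tolerance must be non-negative")

    grouped: dict[tuple[str, str], list[tuple[int, str, int]]] = {}
    for i, calls in enumerate(calls_by_replicate):
        for call in calls:
            rep = call.replicate_id or f"rep{i + 1}"
            grouped.setdefault((call.contig_id, call.strand), []).append(
                (call.position, rep, call.read_starts)
            )

    out: list[ConsensusTSS] = []
    for (contig, strand), items in grouped.items():
        items.sort()
        cluster: list[tuple[int, str, int]] = []
        clusters: list[list[tuple[int, str, int]]] = []
        for item in items:
            if cluster and item[0] - cluster[-1][0] > merge_tolerance:
                clusters.append(cluster)
                cluster = []
            cluster.append(item)
        if cluster:
            clusters.append(cluster)
        for cluster in clusters:
            reps: dict[str, int] = {}
            by_pos: dict[int, int] = {}
            for pos, rep, count in cluster:
                reps[rep] = reps.get(rep, 0) + count
                by_pos[pos] = by_pos.get(pos, 0) + count
            if len(reps) < min_support:
                continue
            consensus_pos = min(by_pos, key=lambda p: (-by_pos[p], p))
            out.append(
                ConsensusTSS(
                    contig_id=contig,
                    position=consensus_pos,
                    strand=strand,
                    n_support=len(reps),
                    per_replicate_counts=reps,
                )
            )
    out.sort(key=lambda t: (t.contig_id, t.position, t.strand))
    return out
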