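"""Promoter window extraction and -10/-35 motif discovery by ZOOPS EM.

The motif model is a position weight matrix with a discretized-Gaussian
positional prior over motif start offsets within the fixed-width promoter
window, plus a zero-or-one-occurrence-per-sequence (ZOOPS) component: each
window either carries one motif occurrence (probability ``occurrence_prob``)
at a prior-weighted offset, or is pure background.  Sequences are scored in
bits as the best-offset log2-odds of motif versus background, including the
positional-prior term, and a score cutoff is calibrated on
mononucleotide-shuffled copies of the real windows (the randomized null).

For a sigma-70 promoter the -10 hexamer (consensus TATAAT) sits about
7 nt upstream of the +1 position and the -35 hexamer (TTGACA) a further
~17-nt spacer upstream, which fixes the default prior means used by the
pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import ParameterError
from .io_formats import BASES, GenomeSequence, revcomp
from .tss_detection import ConsensusTSS

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# promoter windows
# ---------------------------------------------------------------------------

@dataclass
class PromoterSequence:
    """The upstream window (-W..-1) of one TSS, in transcript orientation.

    ``plus1``/``minus1`` are the transcript-orientation bases at +1 and -1;
    the -1 base equals the last character of the window.  Windows clipped at
    a linear contig edge are flagged ``truncated`` and excluded from EM.
    """

    tss: ConsensusTSS
    window: str
    plus1: str
    minus1: str
    truncated: bool = False

    @property
    def sequence_id(self) -> str:
        return f"{self.tss.contig_id}:{self.tss.position}:{self.tss.strand}"

    @property
    def has_n(self) -> bool:
        return "N" in self.window or self.plus1 == "N" or self.minus1 == "N"

    def as_record(self) -> dict:
        return {
            "contig": self.tss.contig_id,
            "position": self.tss.position,
            "strand": self.tss.strand,
            "window": self.window,
            "plus1": self.plus1,
            "minus1": self.minus1,
            "truncated": self.truncated,
        }


def extract_promoters(
    genome: GenomeSequence,
    tss_list: list[ConsensusTSS],
    window: int = 50,
) -> list[PromoterSequence]:
    """Extract the -window..-1 upstream sequence of each TSS.

    Plus strand: genome[pos-W .. pos-1].  Minus strand: reverse complement
    of genome[pos+1 .. pos+W].  On circular contigs windows wrap; on linear
    contigs they are truncated at the edge and flagged.
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    out: list[PromoterSequence] = []
    L = genome.length
    for tss in tss_list:
        pos = tss.position
        if not 1 <= pos <= L:
            raise ParameterError(f"TSS position {pos} outside contig {genome.contig_id}")
        truncated = False
        if tss.strand == "+":
            lo = pos - window
            if lo < 1 and not genome.circular:
                lo, truncated = 1, True
            win = genome.subseq(lo, pos - 1) if (genome.circular or pos > 1) else ""
            truncated = truncated or (pos == 1 and not genome.circular)
            plus1 = genome.base(pos)
        else:
            hi = pos + window
            if hi > L and not genome.circular:
                hi, truncated = L, True
            win = (
                revcomp(genome.subseq(pos + 1, hi))
                if (genome.circular or pos < L)
                else ""
            )
            truncated = truncated or (pos == L and not genome.circular)
            plus1 = revcomp(genome.base(pos))
        minus1 = win[-1] if win else "N"
        out.append(PromoterSequence(tss, win, plus1, minus1, truncated))
    return out


# ---------------------------------------------------------------------------
# motif model
# ---------------------------------------------------------------------------

@dataclass
class MotifModel:
    """PWM + background + Gaussian positional prior + ZOOPS occurrence prob."""

    width: int
    column_probs: np.ndarray  # (width, 4), rows sum to 1, all > 0
    background: np.ndarray  # (4,), sums to 1
    position_prior_mean: float
    position_prior_sd: float
    occurrence_prob: float = 0.5
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        self.column_probs = np.asarray(self.column_probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.column_probs.shape != (self.width, 4):
            raise ParameterError("column_probs must have shape (width, 4)")
        if np.any(self.column_probs <= 0) or np.any(self.background <= 0):
            raise ParameterError("all model probabilities must be > 0 (pseudocounted)")
        if not np.allclose(self.column_probs.sum(axis=1), 1, atol=1e-9):
            raise ParameterError("PWM columns must each sum to 1")
        if not math.isclose(float(self.background.sum()), 1, abs_tol=1e-9):
            raise ParameterError("background must sum to 1")
        if self.position_prior_sd <= 0:
            raise ParameterError("position_prior_sd must be > 0")

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.column_probs.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-column relative entropy vs background, in bits."""
        return (
            self.column_probs * np.log2(self.column_probs / self.background)
        ).sum(axis=1)

    def offset_prior(self, n_offsets: int) -> np.ndarray:
        """Discretized Gaussian prior over valid motif start offsets, normalized."""
        grid = np.arange(n_offsets)
        w = norm.pdf(grid, loc=self.position_prior_mean, scale=self.position_prior_sd)
        total = w.sum()
        if total <= 0:
            return np.full(n_offsets, 1.0 / n_offsets)
        return w / total

    def as_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.column_probs, columns=list(BASES))
        df.index.name = "column"
        return df


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    score: float


@dataclass
class ScoreCutoff:
    """Upper-tail score cutoff calibrated on a randomized (shuffled) null.

    ``cutoff`` is the k-th largest null score with k = ceil((1-quantile)*n),
    so exactly k of the stored null scores are >= cutoff when scores are
    distinct (nearest-rank upper-tail quantile).
    """

    quantile: float
    cutoff: float
    null_size: int
    seed: int
    null_scores: np.ndarray = field(repr=False, default=None)


def _encode(windows: list[str]) -> np.ndarray:
    arr = np.empty((len(windows), len(windows[0])), dtype=np.int8)
    for i, w in enumerate(windows):
        arr[i] = [_BASE_INDEX[b] for b in w]
    return arr


def _em_windows(promoters: list[PromoterSequence], width: int) -> list[PromoterSequence]:
    return [
        p
        for p in promoters
        if not p.truncated and not p.has_n and len(p.window) >= width
    ]


def discover_motif(
    promoters: list[PromoterSequence],
    width: int = 6,
    prior_mean: float = 38.0,
    prior_sd: float = 4.0,
    n_seeds: int = 5,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
) -> MotifModel:
    """Fit a ZOOPS motif model by EM with random restarts.

    E-step: per sequence, the posterior over motif start offsets o is
    proportional to lambda * prior(o) * prod_j pwm[j, base(o+j)] / bg(base),
    against a no-occurrence component with weight (1 - lambda).  M-step:
    posterior-weighted base counts plus ``pseudocount`` give the new PWM;
    lambda and the prior mean/sd are re-estimated from the posteriors.
    The best of ``n_seeds`` seeded random restarts (by final log-likelihood)
    is returned; the log-likelihood is asserted non-decreasing within a run.

    ``prior_mean`` is the expected 0-based motif start offset within the
    window (window index 0 is position -W).  Needs >= 10 clean full-length
    windows.
    """
    usable = _em_windows(promoters, width)
    if len(usable) < 10:
        raise ParameterError(
            f"motif discovery needs >= 10 untruncated N-free windows, got {len(usable)}"
        )
    if prior_sd <= 0:
        raise ParameterError("prior_sd must be > 0")
    W = min(len(p.window) for p in usable)
    usable = [p for p in usable if len(p.window) == W]
    seqs = _encode([p.window for p in usable])
    n, _ = seqs.shape
    K = W - width + 1  # number of valid offsets
    if K < 1:
        raise ParameterError("window shorter than motif width")

    if background is None:
        background = np.bincount(seqs.ravel(), minlength=4).astype(float)
        background = (background + 1.0) / (background.sum() + 4.0)
    background = np.asarray(background, dtype=float)
    log_bg = np.log(background)
    const_ll = float(log_bg[seqs].sum())  # background log-prob of every base

    # per-offset base index views: slab[j] gives base at offset o + j
    slabs = [seqs[:, j : j + K] for j in range(width)]

    rng = np.random.default_rng(seed)
    best: MotifModel | None = None
    for _restart in range(n_seeds):
        pwm = rng.dirichlet(np.full(4, 2.0), size=width)
        pwm = np.clip(pwm, 1e-3, None)
        pwm /= pwm.sum(axis=1, keepdims=True)
        lam = 0.5
        mean, sd = float(prior_mean), float(prior_sd)
        grid = np.arange(K)

        def _log_prior(m_: float, s_: float) -> np.ndarray:
            w = norm.pdf(grid, loc=m_, scale=s_)
            w = w / w.sum() if w.sum() > 0 else np.full(K, 1.0 / K)
            with np.errstate(divide="ignore"):
                return np.log(w)

        prev_ll = -np.inf
        prev_obj = -np.inf  # MAP objective: data LL + Dirichlet pseudocount term
        for _it in range(max_iter):
            log_prior = _log_prior(mean, sd)
            log_ratio = np.zeros((n, K))
            log_pwm = np.log(pwm)
            for j in range(width):
                log_ratio += log_pwm[j, slabs[j]] - log_bg[slabs[j]]
            log_joint = np.log(lam) + log_prior[None, :] + log_ratio
            log_none = np.log1p(-lam)
            m = np.maximum(log_joint.max(axis=1), log_none)
            denom = np.exp(log_joint - m[:, None]).sum(axis=1) + np.exp(log_none - m)
            ll = const_ll + float((m + np.log(denom)).sum())
            obj = ll + pseudocount * float(np.log(pwm).sum())
            # The M-step exactly maximizes the pseudocount-penalized objective
            # (the prior update is guarded below), so obj is non-decreasing.
            if obj + 1e-8 * max(1.0, abs(obj)) < prev_obj:
                raise AssertionError("EM objective decreased")
            z = np.exp(log_joint - m[:, None]) / denom[:, None]  # (n, K)
            if abs(obj - prev_obj) < tol:
                prev_ll, prev_obj = ll, obj
                break
            prev_ll, prev_obj = ll, obj
            # M-step
            occ = z.sum(axis=1)  # per-sequence occurrence posterior
            lam = float(np.clip(occ.mean(), 1e-3, 1 - 1e-3))
            counts = np.zeros((width, 4))
            for j in range(width):
                for b in range(4):
                    counts[j, b] = z[slabs[j] == b].sum()
            pwm = counts + pseudocount
            pwm /= pwm.sum(axis=1, keepdims=True)
            total_occ = occ.sum()
            if total_occ > 0:
                offset_mass = z.sum(axis=0)
                new_mean = float((offset_mass * grid).sum() / total_occ)
                var = float((offset_mass * (grid - new_mean) ** 2).sum() / total_occ)
                new_sd = max(math.sqrt(var), 0.5)
                # discretization makes the moment update approximate: accept it
                # only if it does not lower the expected prior term
                def _expected(m_: float, s_: float) -> float:
                    lp = _log_prior(m_, s_)
                    with np.errstate(invalid="ignore"):
                        terms = np.where(offset_mass > 0, offset_mass * lp, 0.0)
                    return float(terms.sum())

                if _expected(new_mean, new_sd) >= _expected(mean, sd):
                    mean, sd = new_mean, new_sd
        model = MotifModel(
            width=width,
            column_probs=pwm,
            background=background,
            position_prior_mean=mean,
            position_prior_sd=sd,
            occurrence_prob=lam,
            log_likelihood=prev_ll,
        )
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    return best


# ---------------------------------------------------------------------------
# scoring, null calibration, filtering
# ---------------------------------------------------------------------------

def _score_window(model: MotifModel, window: str) -> tuple[int, float]:
    """Best-offset log2-odds score (bits) and its 0-based offset.

    score(o) = sum_j log2(pwm[j, b]/bg[b]) + log2(prior(o) / (1/K)); the
    argmax ties break to the smaller offset.
    """
    K = len(window) - model.width + 1
    if K < 1:
        raise ParameterError("window shorter than motif width")
    idx = np.array([_BASE_INDEX[b] for b in window], dtype=np.int8)
    log2_pwm = np.log2(model.column_probs)
    log2_bg = np.log2(model.background)
    scores = np.zeros(K)
    for j in range(model.width):
        sl = idx[j : j + K]
        scores += log2_pwm[j, sl] - log2_bg[sl]
    prior = model.offset_prior(K)
    with np.errstate(divide="ignore"):
        scores += np.log2(prior * K)
    o = int(np.argmax(scores))
    return o, float(scores[o])


def score_sequence(model: MotifModel, promoter: PromoterSequence) -> MotifHit | None:
    """Score one promoter window; returns None for windows containing N."""
    if promoter.has_n:
        return None
    offset, score = _score_window(model, promoter.window)
    return MotifHit(promoter.sequence_id, offset, score)


def shuffle_window(window: str, rng: np.random.Generator) -> str:
    """Mononucleotide shuffle (seeded Fisher-Yates via rng.permutation)."""
    chars = np.array(list(window))
    return "".join(chars[rng.permutation(len(chars))])


def dinucleotide_shuffle(window: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Eulerian-path method).

    Adjacent base pairs are the edges of a multigraph over the bases; a
    uniform-ish random Eulerian walk with the original start and end bases
    reorders the sequence while keeping every dinucleotide count intact.
    """
    if len(window) <= 2:
        return window
    edges: dict[str, list[str]] = {}
    for a, b in zip(window, window[1:]):
        edges.setdefault(a, []).append(b)
        edges.setdefault(b, [])
    last = window[-1]
    vertices = [v for v in edges]
    while True:
        # pick a candidate "last exit" edge per vertex; retry until these
        # edges form a tree oriented toward the final base (connectivity
        # condition of the Altschul-Erickson algorithm)
        last_edge = {
            v: edges[v][int(rng.integers(len(edges[v])))]
            for v in vertices
            if v != last and edges[v]
        }
        ok = True
        for v in last_edge:
            seen: set[str] = set()
            u = v
            while u != last and u in last_edge and u not in seen:
                seen.add(u)
                u = last_edge[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    out_edges: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        order = rng.permutation(len(rest))
        out_edges[v] = [rest[i] for i in order] + (
            [last_edge[v]] if v in last_edge else []
        )
    walk = [window[0]]
    ptr = {v: 0 for v in vertices}
    v = window[0]
    for _ in range(len(window) - 1):
        nxt = out_edges[v][ptr[v]]
        ptr[v] += 1
        walk.append(nxt)
        v = nxt
    return "".join(walk)


def null_score_cutoff(
    model: MotifModel,
    promoters: list[PromoterSequence],
    quantile: float = 0.95,
    seed: int = 0,
    shuffle: str = "mononucleotide",
) -> ScoreCutoff:
    """Score cutoff from mononucleotide-shuffled copies of the real windows.

    The cutoff is the k-th largest null score, k = ceil((1-quantile)*n):
    the nearest-rank upper-tail quantile, under which exactly k null scores
    are >= cutoff.  Because scores of a discrete alphabet can tie exactly
    (two shuffles hitting the same best hexamer at the same offset), a
    seeded uniform jitter of at most 1e-9 bits is added to the null scores
    before ranking — the randomized-tie-breaking device used for discrete
    test statistics — which makes the empirical quantile well-defined while
    leaving the score scale untouched.
    """
    if not 0 < quantile < 1:
        raise ParameterError("quantile must be in (0, 1)")
    if shuffle == "mononucleotide":
        shuffler = shuffle_window
    elif shuffle == "dinucleotide":
        shuffler = dinucleotide_shuffle
    else:
        raise ParameterError("shuffle must be 'mononucleotide' or 'dinucleotide'")
    windows = [p.window for p in promoters if not p.truncated and not p.has_n]
    if not windows:
        raise ParameterError("no usable promoter windows for the null")
    rng = np.random.default_rng(seed)
    null_scores = np.array(
        [_score_window(model, shuffler(w, rng))[1] for w in windows]
    )
    null_scores = null_scores + rng.uniform(0.0, 1e-9, size=null_scores.size)
    n = null_scores.size
    # round before ceil: binary float error in (1-q)*n must not shift the rank
    k = math.ceil(round((1 - quantile) * n, 9))
    k = max(1, min(k, n))
    cutoff = float(np.sort(null_scores)[n - k])
    return ScoreCutoff(quantile=quantile, cutoff=cutoff, null_size=n, seed=seed,
                       null_scores=null_scores)


def filter_by_score(
    promoters: list[PromoterSequence],
    model: MotifModel,
    cutoff: ScoreCutoff,
) -> tuple[list[tuple[PromoterSequence, MotifHit]], list[tuple[PromoterSequence, MotifHit | None]]]:
    """Partition promoters into (score >= cutoff, rest); N-windows fail with no hit."""
    passing, failing = [], []
    for p in promoters:
        hit = score_sequence(model, p) if not p.truncated else None
        if hit is not None and hit.score >= cutoff.cutoff:
            passing.append((p, hit))
        else:
            failing.append((p, hit))
    return passing, failing


def dual_motif_report(
    promoters: list[PromoterSequence],
    model_10: MotifModel,
    model_35: MotifModel,
    cutoff_10: ScoreCutoff,
    cutoff_35: ScoreCutoff,
) -> tuple[list[dict], dict[int, int]]:
    """Per-promoter -10/-35 presence flags and the spacer-length distribution.

    The spacer is the gap between the -35 hexamer's 3' end and the -10
    hexamer's 5' start: offset(-10) - (offset(-35) + width(-35)).  The
    distribution is tallied over promoters flagged as carrying both motifs.
    """
    rows: list[dict] = []
    spacers: dict[int, int] = {}
    for p in promoters:
        hit10 = score_sequence(model_10, p) if not p.truncated else None
        hit35 = score_sequence(model_35, p) if not p.truncated else None
        has10 = hit10 is not None and hit10.score >= cutoff_10.cutoff
        has35 = hit35 is not None and hit35.score >= cutoff_35.cutoff
        spacer = None
        if has10 and has35:
            spacer = hit10.offset - (hit35.offset + model_35.width)
            spacers[spacer] = spacers.get(spacer, 0) + 1
        rows.append(
            {
                "sequence_id": p.sequence_id,
                "has_minus10": has10,
                "has_minus35": has35,
                "both": has10 and has35,
                "neither": not has10 and not has35,
                "score_minus10": hit10.score if hit10 else None,
                "score_minus35": hit35.score if hit35 else None,
                "spacer": spacer,
            }
        )
    return rows, dict(sorted(spacers.items()))


def logo_counts(
    promoters: list[PromoterSequence],
    model: MotifModel,
    flank: int = 0,
) -> np.ndarray:
    """Base-count matrix over promoters aligned at their motif hit offsets.

    Returns a (width + 2*flank, 4) matrix; only promoters whose aligned
    span (including flanks) lies fully inside the window contribute, so all
    row sums are equal.  With the default flank 0 every scoreable promoter
    contributes.
    """
    span = model.width + 2 * flank
    counts = np.zeros((span, 4), dtype=np.int64)
    n_used = 0
    for p in promoters:
        hit = score_sequence(model, p) if not p.truncated else None
        if hit is None:
            continue
        start = hit.offset - flank
        if start < 0 or start + span > len(p.window):
            continue
        sub = p.window[start : start + span]
        for i, b in enumerate(sub):
            counts[i, _BASE_INDEX[b]] += 1
        n_used += 1
    if n_used == 0:
        raise ParameterError("no promoters with a usable motif hit")
    return counts
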