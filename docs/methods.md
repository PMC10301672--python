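# Methods

This note documents the models and procedures implemented in `rose-seq`, the
defaults and why they were chosen, the numerical decisions that matter, and
what the synthetic study conditions do and do not demonstrate.

## Coordinates and strand conventions

All internal coordinates are 1-based inclusive genome positions. BedGraph
input/output converts from the standard 0-based half-open dialect at the
boundary. The 5′-end of a reverse-mapped read is its highest genomic
coordinate; "upstream" of a minus-strand position means higher coordinates.
Promoter windows, deviations and +1/−1 bases are always reported in
transcript orientation. Circular contigs wrap both the detection background
window and promoter extraction; linear contigs truncate (truncated windows
are flagged and excluded from motif fitting).

## TSS detection

A 5′-end-specific library shows a TSS as a sharp stack of read starts at the
+1 position. Position *p* on strand *s* is called when

- `count(p) ≥ min_read_starts`, and
- `count(p) / (1 + mean_bg) ≥ min_fold_enrichment`, where `mean_bg` is the
  mean read-start count over `background_window` (default 50) positions
  strictly upstream of *p* on *s*, excluding *p*.

Background is computed from read-start counts, not full coverage, because
read-start density is the native signal of a 5′-end library. The +1
pseudocount in the denominator keeps the fold finite over silent background.

**Automatic threshold estimation.** `min_read_starts` is the ceiling of an
upper quantile (default 0.9, upper nearest-rank interpolation) of the nonzero
per-position stack heights, floored at 3 reads; `min_fold_enrichment` stays
at its fixed default of 5. This is a deliberately simple, reproducible,
data-adaptive rule: the quantile separates the many 1–2-read noise positions
from genuine stacks without assuming a library size. Both thresholds are
overridable.

**Consensus.** Same-strand calls across replicates are clustered by single
linkage at `merge_tolerance` (default 0 nt — start sites are expected to be
single-nucleotide reproducible; the tolerance is exposed because template
supercoiling can shift starts by a few nt). A cluster's consensus position
is the member position with the highest summed read starts (ties to the
smaller position); clusters seen in fewer than `min_support` replicates
(default 4 of 6) are dropped. Raising either detection threshold can only
remove calls (monotonicity), and consensus output is invariant under
replicate order.

## Classification

Categories follow the established dRNA-seq annotation scheme: **primary**
(same strand, 0–300 nt upstream of a gene's 5′ end), **intragenic** (same
strand, within the gene body), **antisense** (opposite strand, within a
closed ±100 nt flank) and **orphan**. When several definitions apply the
priority is primary > intragenic > antisense, so the four categories
partition any catalog; the nearest qualifying gene (smallest |distance|,
then smaller gene start) is associated. A TSS exactly at the annotated gene
start counts as primary with distance 0. The 300 nt primary cutoff is a
common bacterial convention — the "right" value depends on UTR length
distributions and is configurable.

## Catalog comparison

Two catalogs are matched one-to-one; only same-strand pairs within
`tolerance` (default 3 nt) may pair. Deviations are signed
reference − query in transcript orientation (+ = reference downstream). The
matching maximizes cardinality first and minimizes total |deviation| second,
solved exactly as an assignment problem on each connected component of the
candidate-pair graph; components are tiny because pairs only link positions
within the tolerance, so the exact solution costs about the same as a greedy
pass. (A greedy nearest-first rule was considered and rejected: in chained
configurations — e.g. query {0, 1} against reference {1, 4} at tolerance 3 —
greedy strands a matchable pair.) Among equally optimal matchings one is
selected deterministically. Because tolerance matching is not transitive,
the three-way overlap (Venn) is anchor-based: each member of the first set
is labeled by its pairwise matches into the other two; the remaining
b-only/c-only/bc regions come from matching the leftovers.

## Repression panel

Candidates are the union of per-sample TSS calls merged at the tolerance.
"Present" in a sample means the sample has a call under its own detection
thresholds — a sub-threshold trickle of reads is absence, which matters for
promoters with leaky wildtype signal. Verdicts, in precedence order:
**constitutive** (present in the wildtype), **repressed-by-X** (absent in
the wildtype, present in vitro and in knockout ΔX), **in-vitro-only**
(present only in vitro; the signature of multi-factor repression) and
**knockout-only**. The precedence makes verdicts a partition of the
candidate set. For multi-replicate samples the pipeline pools replicate
counts before detection, which makes per-sample presence robust to
single-replicate dropout.

## Promoter windows, motif model and scoring

Windows cover −W…−1 upstream of each TSS in transcript orientation
(default W = 50), with the +1 and −1 bases recorded separately. Windows
containing N are excluded from model fitting and scoring (PWM columns assume
{A,C,G,T}).

The motif model is a PWM of width 6 with a ZOOPS occurrence component and a
discretized-Gaussian prior over motif start offsets. EM alternates:

- **E-step**: per window, posterior over offsets
  `∝ λ · prior(o) · Π_j p_j(base)/bg(base)` against a no-occurrence
  component with weight 1 − λ.
- **M-step**: PWM from posterior-weighted counts + 0.25 pseudocount per
  base; λ and the prior mean/sd re-estimated from the posteriors (sd floored
  at 0.5 offsets).

The M-step exactly maximizes the pseudocount-penalized (MAP) objective, so
that objective — not the raw likelihood — is asserted non-decreasing every
iteration; the prior-parameter moment update is approximate under grid
discretization and is accepted only when it does not lower the expected
prior term, preserving the guarantee. EM runs from several seeded random
restarts (default 5; 10–20 recommended for small datasets, where a
register-shifted local optimum is the typical failure) and returns the
highest-likelihood model. Background frequencies are estimated from the
windows themselves.

Prior means encode σ70 promoter geometry: the −10 hexamer ends ≈ 7 nt
upstream of +1 (prior mean W − 12) and the −35 hexamer sits a ~17 nt spacer
further upstream (prior mean W − 37), sd 4 nt.

**Scoring** is the best-offset log2-odds in bits, including the positional
prior term: `score = max_o [ Σ_j log2(p_j/bg) + log2(prior(o)·K) ]` over the
K valid offsets. The score scale is defined by this package; it is not
comparable to other motif tools' internal scores.

**Null calibration.** Each real window is mononucleotide-shuffled (seeded
Fisher–Yates; the shuffle preserves composition, destroying only order) and
scored; the cutoff is the k-th largest null score with k = ⌈(1−q)·n⌉
(default q = 0.95), i.e. the upper-tail nearest-rank quantile. Scores over a
discrete alphabet can tie exactly (two shuffles sharing the best hexamer at
the best offset), and a tie across the rank boundary would make "exactly k
nulls above the cutoff" unattainable for any threshold; a seeded uniform
jitter of ≤ 1e-9 bits — the standard randomized-tie-breaking device for
discrete test statistics — is added to the null scores before ranking,
which leaves the scale untouched while making the quantile well-defined.
Filtering partitions promoters at score ≥ cutoff; the dual-motif report
flags −10/−35 presence independently and tallies spacer lengths
(−10 offset − (−35 offset + 6)) over promoters carrying both.

On pure-noise windows the fitted model's information content stays low
(≈ 0.25–0.3 bits/column on average), but the ZOOPS occurrence probability λ
drifts high (often 0.7–1.0): with ~45 candidate offsets per window, a weakly
overfit PWM attains a likelihood ratio > 1 somewhere in most windows. λ is
therefore not a noise diagnostic; column information content and the
null-calibrated score cutoff are.

## Synthetic study conditions

The generator plants, per gene: −35 hexamer (TTGACA, per-base mutation rate
0.20), spacer 15–19 nt, −10 hexamer (TATAAT, rate 0.10 — more conserved than
the −35, as in real σ70 promoters), a 6–8 nt discriminator (so the −10 ends
6–8 nt upstream of +1), the +1 base (A .50 / G .31 / C .09 / T .10) and −1
base (T .41 / C .36 / A .12 / G .11) emulating the purine/pyrimidine
initiator preference, a 20–100 nt 5′ UTR and a 300–900 nt gene body; genes
are non-overlapping on random strands, so every planted TSS is primary by
construction. Read starts: negative-binomial stacks (mean 200, dispersion 5)
at active TSSs with a 5% per-read ±1 nt smear, Poisson background
(0.01/nt/strand), 6 replicates with 10% per-replicate dropout. 15% of
promoters are assigned a repressing factor (fur/fis/hns round-robin):
repression removes the signal in the wildtype and in every knockout except
the factor's own (a `repressed_residual` mode keeps a fraction of the mean
for leaky-repression scenarios). Reference catalogs are jittered copies of
the truth (default shift mass: 0.65 at 0, 0.07 at ±1, 0.07 at ±2, 0.035 at
±3) plus optional novel extras. All three generator operations are
byte-deterministic under the seed.

**What passing these conditions does not show.** The simulator has a single
contig, no rRNA contamination, no processing sites (every 5′-end is a true
TSS), no operons or overlapping genes, no intragenic or antisense planted
starts, composition-homogeneous background sequence, and repression modeled
as clean signal removal. Real libraries violate all of these; in particular
the detector's false-positive behavior at processed 5′-ends and the
classifier's behavior in dense operonic neighborhoods are untested by
construction. The planted-motif recovery results say the EM finds a motif at
the planted conservation level (10% mutation) — weaker or wider real motifs
may need larger windows, more restarts or a different width.

## Problem sizes and defaults used in the shipped analyses

The default fixture is 200 promoters over a ~190 kb genome with 6
replicates — large enough for stable fractions (binomial CI half-widths of a
few percent at n ≈ 200) while a full pipeline run, including two EM fits and
null calibration, completes in seconds. `scripts/acceptance.py` runs exactly
these conditions under the given seed; per-quantity sample sizes are
reported in its output.

## Known limitations

- Detection has no local-maximum constraint, so strong read smear can
  produce ±1 nt satellite calls next to a genuine TSS (visible as ~10–15%
  extra consensus positions on the default fixture). Downstream analyses
  that must not double-count should match at tolerance ≥ 1 or merge at
  consensus time.
- The automatic threshold rule is a stand-in for interactive parameter
  choice; on libraries with heavy-tailed noise the 0.9 quantile may sit
  inside the noise and the floor of 3 reads dominates.
- ZOOPS EM fits one motif per run; overlapping or variant motifs (e.g.
  extended −10) require separate runs with adjusted priors.
- The score cutoff controls the per-window false-positive rate at ~5% under
  a mononucleotide null; dinucleotide structure (available as an option) or
  genomic composition heterogeneity can make the effective rate higher.
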