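# rose-seq

TSS calling, σ70 promoter motif discovery and in vivo-repression analysis
for **run-off transcription / 5′-end RNA-seq** data.

## The problem

Genome-wide in vitro run-off transcription followed by native-5′-end
transcriptome sequencing characterizes bacterial promoters bottom-up: purified
RNA polymerase holoenzyme transcribes sheared genomic DNA, and sequencing the
unprocessed transcript 5′-ends produces sharp read stacks at each transcription
start site (TSS, the +1 position). Because the assay contains no transcription
factors, promoters that are repressed in vivo transcribe freely in vitro —
comparing the in vitro TSS catalog against wildtype and transcription-factor
knockout strains reveals which promoters a given repressor silences.

This package implements the computational workflow downstream of read mapping:

1. **TSS detection** — a position *p* on strand *s* is called when its
   read-start count *c(p)* satisfies *c(p) ≥ m* and
   *c(p) / (1 + mean background)* ≥ *f*, where the background is the mean
   read-start count over a window (default 50 nt) strictly upstream of *p*
   on *s*. Thresholds *m*, *f* can be estimated from the data
   (*m* = upper quantile of the nonzero stack heights, floor 3; *f* = 5).
2. **Replicate consensus** — same-strand calls across replicates are
   single-linkage clustered (default tolerance 0 nt) and kept when supported
   by at least *k* of *n* replicates (default 4 of 6).
3. **Classification** — each consensus TSS is labeled *primary* (≤ 300 nt
   upstream of a gene's 5′ end, same strand), *intragenic*, *antisense*
   (opposite strand within ±100 nt of a gene) or *orphan*, with priority
   primary > intragenic > antisense so the categories partition the catalog.
4. **Promoter windows and motifs** — the −50…−1 upstream window of each TSS is
   mined for the −10 (TATAAT) and −35 (TTGACA) hexamers by a ZOOPS EM
   (zero-or-one occurrence per sequence) with a discretized-Gaussian
   positional prior; sequences are scored in bits as
   `max_o Σ_j log2(p_j(b)/bg(b)) + log2(prior(o)/uniform)` and filtered at a
   95% cutoff calibrated on mononucleotide-shuffled windows.
5. **Catalog comparison** — two TSS catalogs are matched one-to-one within a
   ±3 nt tolerance (exact minimum-deviation assignment), yielding match
   fractions, signed-deviation histograms and three-way (Venn) overlaps.
6. **Repression panel** — candidate TSSs across an in vitro (“ROSE”),
   wildtype and knockout sample panel are labeled *constitutive*,
   *repressed-by-X*, *in-vitro-only* or *knockout-only* from their
   presence/absence pattern under each sample's detection thresholds.

A first-class synthetic-data module generates genomes with planted σ70
promoters, simulated replicate read-start profiles and jittered reference
catalogs, so the entire pipeline is testable without any external download.

## Worked example

Simulate a fixture (200 planted promoters, 6 replicates), run the pipeline,
and inspect the summary:

```bash
rose simulate --out fixtures --seed 1
rose detect --fw fixtures/rose_rep1.fw.bedgraph --rv fixtures/rose_rep1.rv.bedgraph \
     --out rep1.tsv
# ... repeat for rep2..rep6, then:
rose consensus rep*.tsv --min-support 4 --out consensus.tsv
rose classify --gff fixtures/genes.gff3 --tss consensus.tsv --out classified.tsv
```

Or in Python:

```python
from rose import (SimulationConfig, generate_genome, simulate_read_starts,
                  estimate_params, detect_tss, consensus_tss)

config = SimulationConfig(seed=1)          # 200 promoters, 6 replicates
genome, genes, truth = generate_genome(config)
profiles = simulate_read_starts(truth, config, genome.length)
calls = [detect_tss(p, estimate_params(p), genome.length)
         for p in profiles["rose"]]
consensus = consensus_tss(calls, min_support=4)
print(len(consensus))                      # 228
```

On this fixture the pipeline recovers **98.0%** of the 200 planted TSSs at
the exact planted +1 position (the 228 consensus calls include ±1 nt
satellite stacks from read smear); all planted promoters classify as
primary. The +1 base is a purine in **82.1%** of recovered promoters and the
−1 base a pyrimidine in **74.0%** — matching the simulated initiator
preference. Motif discovery returns consensus TATAAT with **7.3 bits** total
information for the −10 model versus **5.8 bits** for the −35 (TTGACA) model,
reflecting the planted conservation difference; **91.8%** of real windows
but only **6.6%** of shuffled windows clear the null-calibrated −10 score
cutoff. Matching against a jittered reference catalog pairs 100% of TSSs
with **64.5%** at zero deviation, and the wildtype/knockout panel reproduces
every planted repression verdict (**100%** agreement, 30 repressed
promoters called).

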