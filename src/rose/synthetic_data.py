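"""Synthetic genomes with planted sigma-70 promoters and simulated 5'-end reads.

The generator emulates the signal structure of a run-off-transcription
5'-end library: a sharp, overdispersed read stack at each active +1
position (negative binomial across replicates, with a small +/-1 nt
positional smear), sparse Poisson background elsewhere, and per-replicate
dropout.  Each planted promoter is laid out in transcript orientation as
-35 hexamer, spacer, -10 hexamer, discriminator, +1 — with the -10 element
ending about 7 nt upstream of the start site — followed by a short 5' UTR
and a gene body, so every planted TSS is primary by construction.

A fraction of promoters is assigned a repressing transcription factor:
those are silent in the simulated wildtype and in every knockout except
their own, but always active in the in vitro (run-off) sample, mirroring a
wildtype/knockout/in vitro panel.  All outputs are deterministic under the
configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .io_formats import (
    GeneAnnotation,
    GenomeSequence,
    ReadStartProfile,
    revcomp,
    write_annotation,
    write_genome,
    write_read_starts,
)

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixture.

    Defaults: 200 genes each with one planted promoter, six replicates with
    4-of-6-style dropout, a strong TSS signal (mean 200 read starts) over a
    sparse background (0.01 read starts/nt), TATAAT/TTGACA consensus motifs
    with the -10 more conserved than the -35, a 15-19 nt spacer around the
    canonical 17, and a purine-biased +1 / pyrimidine-biased -1 base.
    """

    genome_length: int | None = None  # None: sized to fit the gene blocks
    n_genes: int = 200
    n_promoters: int | None = None  # None: one per gene
    fraction_repressed: float = 0.15
    motif_10: tuple[str, float] = ("TATAAT", 0.10)  # consensus, per-base mutation rate
    motif_35: tuple[str, float] = ("TTGACA", 0.20)
    spacer_range: tuple[int, int] = (15, 19)
    discriminator_range: tuple[int, int] = (6, 8)
    plus1_distribution: dict[str, float] = field(
        default_factory=lambda: {"A": 0.50, "C": 0.09, "G": 0.31, "T": 0.10}
    )
    minus1_distribution: dict[str, float] = field(
        default_factory=lambda: {"A": 0.12, "C": 0.36, "G": 0.11, "T": 0.41}
    )
    signal_mean: float = 200.0
    signal_dispersion: float = 5.0
    background_rate: float = 0.01
    smear_prob: float = 0.05  # per-read probability of a +/-1 nt shift
    n_replicates: int = 6
    replicate_dropout: float = 0.1
    repressed_residual: float = 0.0  # fraction of signal kept when repressed
    knockout_factors: tuple[str, ...] = ("fur", "fis", "hns")
    utr_range: tuple[int, int] = (20, 100)
    gene_length_range: tuple[int, int] = (300, 900)
    intergenic_gap: int = 120
    promoter_margin: int = 60  # clear background upstream of each promoter
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_repressed <= 1:
            raise ParameterError("fraction_repressed must be in [0, 1]")
        for dist in (self.plus1_distribution, self.minus1_distribution):
            if abs(sum(dist.values()) - 1.0) > 1e-9 or set(dist) != set("ACGT"):
                raise ParameterError("base distributions must cover ACGT and sum to 1")
        if self.spacer_range[0] > self.spacer_range[1] or self.spacer_range[0] < 1:
            raise ParameterError("invalid spacer_range")
        if self.n_promoters is not None and self.n_promoters > self.n_genes:
            raise ParameterError("n_promoters cannot exceed n_genes")

    @property
    def resolved_n_promoters(self) -> int:
        return self.n_promoters if self.n_promoters is not None else self.n_genes

    @property
    def sample_ids(self) -> list[str]:
        return ["rose", "wildtype"] + [f"ko_{f}" for f in self.knockout_factors]


@dataclass
class TruthRow:
    """Ground truth for one planted promoter/TSS."""

    tss_position: int
    strand: str
    gene_id: str
    gene_start: int
    gene_end: int
    category: str  # primary by construction
    repressing_factor: str | None
    repressed_in: tuple[str, ...]
    spacer: int
    plus1_base: str

    def as_record(self) -> dict:
        return {
            "position": self.tss_position,
            "strand": self.strand,
            "gene_id": self.gene_id,
            "gene_start": self.gene_start,
            "gene_end": self.gene_end,
            "category": self.category,
            "repressing_factor": self.repressing_factor or "",
            "repressed_in": ",".join(self.repressed_in),
            "spacer": self.spacer,
            "plus1": self.plus1_base,
        }


def _mutate(motif: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for b in motif:
        if rng.random() < rate:
            out.append(rng.choice([x for x in "ACGT" if x != b]))
        else:
            out.append(b)
    return "".join(out)


def _sample_base(dist: dict[str, float], rng: np.random.Generator) -> str:
    bases = sorted(dist)
    return str(rng.choice(bases, p=[dist[b] for b in bases]))


def generate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneAnnotation], list[TruthRow]]:
    """Build a genome with non-overlapping genes and planted promoters.

    Byte-deterministic under ``config.seed``.  Gene blocks are laid out
    sequentially on alternating random strands; if ``genome_length`` is set
    and the blocks do not fit, an error suggests a larger genome.
    """
    rng = np.random.default_rng([config.seed, 0])
    cons10, rate10 = config.motif_10
    cons35, rate35 = config.motif_35
    w10, w35 = len(cons10), len(cons35)

    n_prom = config.resolved_n_promoters
    # which promoters are repressed, and by which factor
    n_rep = int(round(config.fraction_repressed * n_prom))
    repressed_idx = set(rng.choice(n_prom, size=n_rep, replace=False).tolist()) if n_rep else set()
    factors = list(config.knockout_factors)

    blocks = []  # (strand, spacer, disc, utr, glen, has_promoter)
    for i in range(config.n_genes):
        blocks.append(
            (
                "+" if rng.random() < 0.5 else "-",
                int(rng.integers(config.spacer_range[0], config.spacer_range[1] + 1)),
                int(rng.integers(config.discriminator_range[0], config.discriminator_range[1] + 1)),
                int(rng.integers(config.utr_range[0], config.utr_range[1] + 1)),
                int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1)),
                i < n_prom,
            )
        )

    genes: list[GeneAnnotation] = []
    truth: list[TruthRow] = []
    edits: dict[int, str] = {}  # 1-based position -> base (plus-strand)
    cursor = config.intergenic_gap  # leftmost unused position - 1
    rep_assigned = 0
    for i, (strand, spacer, disc, utr, glen, has_prom) in enumerate(blocks):
        gene_id = f"g{i + 1:04d}"
        promoter_span = w35 + spacer + w10 + disc + 1  # -35 .. +1 inclusive
        factor = None
        if has_prom and i in repressed_idx:
            factor = factors[rep_assigned % len(factors)]
            rep_assigned += 1
        plus1 = _sample_base(config.plus1_distribution, rng)
        minus1 = _sample_base(config.minus1_distribution, rng)
        m10 = _mutate(cons10, rate10, rng)
        m35 = _mutate(cons35, rate35, rng)

        if strand == "+":
            m35_start = cursor + config.promoter_margin + 1
            t = m35_start + w35 + spacer + w10 + disc
            g1 = t + utr
            g2 = g1 + glen - 1
            block_end = g2
            if has_prom:
                for k, b in enumerate(m35):
                    edits[m35_start + k] = b
                m10_start = m35_start + w35 + spacer
                for k, b in enumerate(m10):
                    edits[m10_start + k] = b
                edits[t] = plus1
                edits[t - 1] = minus1
        else:
            g1 = cursor + config.intergenic_gap + 1
            g2 = g1 + glen - 1
            t = g2 + utr
            block_end = t + promoter_span - 1 + config.promoter_margin
            if has_prom:
                # upstream on - strand is rightward in genomic coordinates
                edits[t] = _COMP[plus1]
                edits[t + 1] = _COMP[minus1]
                m10_start = t + disc + 1  # genomic left end of the -10 hexamer
                for k, b in enumerate(revcomp(m10)):
                    edits[m10_start + k] = b
                m35_start = m10_start + w10 + spacer
                for k, b in enumerate(revcomp(m35)):
                    edits[m35_start + k] = b
        genes.append(GeneAnnotation(gene_id, "synth1", g1, g2, strand))
        if has_prom:
            truth.append(
                TruthRow(
                    tss_position=t,
                    strand=strand,
                    gene_id=gene_id,
                    gene_start=g1,
                    gene_end=g2,
                    category="primary",
                    repressing_factor=factor,
                    repressed_in=tuple(
                        s
                        for s in config.sample_ids
                        if factor is not None
                        and s != "rose"
                        and s != f"ko_{factor}"
                    ),
                    spacer=spacer,
                    plus1_base=plus1,
                )
            )
        cursor = block_end + config.intergenic_gap

    needed = cursor + config.intergenic_gap
    length = config.genome_length or needed
    if length < needed:
        raise ParameterError(
            f"genome_length {length} too small for {config.n_genes} gene blocks; "
            f"need >= {needed}"
        )
    seq = rng.choice(_BASES, size=length)
    for pos, b in edits.items():
        seq[pos - 1] = b
    genome = GenomeSequence("synth1", "".join(seq))
    return genome, genes, truth


def _active(row: TruthRow, sample_id: str) -> bool:
    return sample_id not in row.repressed_in


def simulate_read_starts(
    truth: list[TruthRow],
    config: SimulationConfig,
    genome_length: int,
) -> dict[str, list[ReadStartProfile]]:
    """Simulate per-replicate read-start profiles for every panel sample.

    Active TSSs draw a negative-binomial stack (mean ``signal_mean``,
    dispersion ``signal_dispersion``); each read smears to +/-1 nt with
    probability ``smear_prob``.  Background positions draw Poisson
    (``background_rate``).  A replicate drops a TSS entirely with
    probability ``replicate_dropout``; a repressed TSS keeps
    ``repressed_residual`` of its mean signal in samples where it is silent.
    """
    rng = np.random.default_rng([config.seed, 1])
    k = config.signal_dispersion
    p_nb = k / (k + config.signal_mean)
    profiles: dict[str, list[ReadStartProfile]] = {}
    for sample_id in config.sample_ids:
        reps = []
        for r in range(config.n_replicates):
            fw = rng.poisson(config.background_rate, size=genome_length)
            rv = rng.poisson(config.background_rate, size=genome_length)
            for row in truth:
                arr = fw if row.strand == "+" else rv
                active = _active(row, sample_id)
                if active:
                    if config.replicate_dropout and rng.random() < config.replicate_dropout:
                        continue
                    n_reads = int(rng.negative_binomial(k, p_nb))
                elif config.repressed_residual > 0:
                    p_res = k / (k + config.signal_mean * config.repressed_residual)
                    n_reads = int(rng.negative_binomial(k, p_res))
                else:
                    continue
                if n_reads == 0:
                    continue
                smeared = int(rng.binomial(n_reads, config.smear_prob))
                up = int(rng.binomial(smeared, 0.5))
                down = smeared - up
                idx = row.tss_position - 1
                arr[idx] += n_reads - smeared
                if idx - 1 >= 0:
                    arr[idx - 1] += up
                if idx + 1 < genome_length:
                    arr[idx + 1] += down
            reps.append(
                ReadStartProfile(
                    sample_id=sample_id,
                    replicate_id=f"{sample_id}_rep{r + 1}",
                    contig_id="synth1",
                    counts_fw={int(p) + 1: int(c) for p, c in zip(*[np.flatnonzero(fw), fw[np.flatnonzero(fw)]])},
                    counts_rv={int(p) + 1: int(c) for p, c in zip(*[np.flatnonzero(rv), rv[np.flatnonzero(rv)]])},
                )
            )
        profiles[sample_id] = reps
    return profiles


DEFAULT_JITTER = {0: 0.65, 1: 0.07, -1: 0.07, 2: 0.07, -2: 0.07, 3: 0.035, -3: 0.035}


def generate_reference_catalog(
    truth: list[TruthRow],
    jitter_distribution: dict[int, float] | None = None,
    subset_fraction: float = 1.0,
    extra_fraction: float = 0.0,
    seed: int = 0,
    genome_length: int | None = None,
) -> list[tuple[int, str]]:
    """A reference TSS catalog: jittered subset of the truth plus novel extras.

    Emulates an independently derived catalog whose positions deviate from
    the truth by small sampled shifts (most mass at 0).  Deterministic under
    ``seed``.
    """
    if not 0 <= subset_fraction <= 1 or extra_fraction < 0:
        raise ParameterError("fractions out of range")
    jitter = jitter_distribution or DEFAULT_JITTER
    shifts = sorted(jitter)
    probs = np.array([jitter[s] for s in shifts], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ParameterError("jitter probabilities must sum to 1")
    rng = np.random.default_rng([seed, 2])
    n_keep = int(round(subset_fraction * len(truth)))
    keep = sorted(rng.choice(len(truth), size=n_keep, replace=False).tolist())
    catalog: list[tuple[int, str]] = []
    taken = set()
    for i in keep:
        row = truth[i]
        shift = int(rng.choice(shifts, p=probs))
        pos = row.tss_position + shift
        catalog.append((pos, row.strand))
        taken.add((pos, row.strand))
    n_extra = int(round(extra_fraction * len(truth)))
    if n_extra:
        length = genome_length or (max(r.tss_position for r in truth) + 1000)
        truth_pos = {(r.tss_position, r.strand) for r in truth}
        while n_extra > 0:
            pos = int(rng.integers(1, length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            # keep extras clearly away from real sites
            if (pos, strand) in taken or any(
                abs(pos - tp) <= 5 and strand == ts for tp, ts in truth_pos
            ):
                continue
            catalog.append((pos, strand))
            taken.add((pos, strand))
            n_extra -= 1
    catalog.sort()
    return catalog


def write_fixture(
    outdir: str | Path,
    config: SimulationConfig,
) -> dict:
    """Emit FASTA, GFF3, BedGraph pairs per sample/replicate and a truth TSV."""
    import pandas as pd
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = generate_genome(config)
    profiles = simulate_read_starts(truth, config, genome.length)
    write_genome([genome], outdir / "genome.fasta")
    write_annotation(genes, outdir / "genes.gff3")
    pd.DataFrame([r.as_record() for r in truth]).to_csv(
        outdir / "truth.tsv", sep="\t", index=False
    )
    paths: dict[str, list[tuple[str, str]]] = {}
    for sample_id, reps in profiles.items():
        paths[sample_id] = []
        for prof in reps:
            fw = outdir / f"{prof.replicate_id}.fw.bedgraph"
            rv = outdir / f"{prof.replicate_id}.rv.bedgraph"
            write_read_starts(prof, fw, rv)
            paths[sample_id].append((str(fw), str(rv)))
    resolved = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()}
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    return {"genome": str(outdir / "genome.fasta"), "gff": str(outdir / "genes.gff3"),
            "truth": str(outdir / "truth.tsv"), "profiles": paths}
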