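"""Readers and writers for every external representation the pipeline touches.

Internal coordinates are 1-based inclusive genome positions throughout the
package; the BedGraph reader/writer converts from/to the standard 0-based
half-open dialect at the boundary.  The 5'-end of a reverse-mapped read is its
highest genomic coordinate (5'-end semantics are strand-relative).
"""

from __future__ import annotations

import io
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """A single contig: upper-case DNA over {A,C,G,T,N}, 1-based coordinates."""

    contig_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise FormatError("contig_id must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.contig_id!r}: non-nucleotide characters {sorted(bad)}"
            )
        if not self.sequence:
            raise FormatError(f"record {self.contig_id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position; wraps on circular contigs."""
        if self.circular:
            position = (position - 1) % self.length + 1
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside contig {self.contig_id}")
        return self.sequence[position - 1]

    def subseq(self, start: int, end: int) -> str:
        """Plus-strand slice [start, end], 1-based inclusive, wrapping if circular."""
        if start > end:
            raise ValueError(f"start {start} > end {end}")
        if self.circular:
            return "".join(self.base(p) for p in range(start, end + 1))
        if start < 1 or end > self.length:
            raise IndexError(
                f"[{start}, {end}] outside linear contig {self.contig_id} (1..{self.length})"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature, GFF3-style 1-based inclusive coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(f"gene {self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the gene's 5' end (start on +, end on -)."""
        return self.start if self.strand == "+" else self.end


@dataclass
class ReadStartProfile:
    """Per-position counts of transcript 5'-ends for one sample/replicate.

    ``counts_fw``/``counts_rv`` map 1-based genome positions to non-negative
    read-start counts on the plus and minus strand respectively.
    """

    sample_id: str
    replicate_id: str
    contig_id: str
    counts_fw: dict[int, int] = field(default_factory=dict)
    counts_rv: dict[int, int] = field(default_factory=dict)

    @property
    def library_size(self) -> int:
        return sum(self.counts_fw.values()) + sum(self.counts_rv.values())

    def counts(self, strand: str) -> dict[int, int]:
        return self.counts_fw if strand == "+" else self.counts_rv

    @property
    def max_position(self) -> int:
        positions = list(self.counts_fw) + list(self.counts_rv)
        return max(positions) if positions else 0


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def load_genome(path: str | Path, ambiguous: str = "reject") -> list[GenomeSequence]:
    """Load all records of a FASTA file as :class:`GenomeSequence` objects.

    Parameters
    ----------
    ambiguous
        ``"reject"`` (default) raises on IUPAC codes other than N;
        ``"to_n"`` maps them to N.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"FASTA file not found: {path}")
    genomes = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"record {record.id!r}: empty sequence")
        extra = set(seq) - _VALID_BASES
        if extra:
            if ambiguous == "to_n":
                seq = "".join(b if b in _VALID_BASES else "N" for b in seq)
            else:
                raise FormatError(
                    f"record {record.id!r}: ambiguous/non-nucleotide characters "
                    f"{sorted(extra)} (use ambiguous='to_n' to mask them)"
                )
        genomes.append(GenomeSequence(record.id, seq))
    if not genomes:
        raise FormatError(f"no FASTA records in {path}")
    return genomes


def write_genome(genomes: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.contig_id}\n")
            for i in range(0, g.length, width):
                fh.write(g.sequence[i : i + width] + "\n")


def _gff3_attribute(attrs: str, key: str) -> str | None:
    for chunk in attrs.strip().split(";"):
        if chunk.startswith(key + "="):
            return chunk[len(key) + 1 :]
    return None


def load_annotation(
    path: str | Path,
    feature_types: set[str] | None = None,
) -> list[GeneAnnotation]:
    """Read a GFF3 file, keeping only the requested feature types.

    GFF3 is tab-delimited and 1-based inclusive; coordinates are taken
    verbatim.  A kept feature with strand other than +/- or with end < start
    is a format error reported with its line number.
    """
    if feature_types is None:
        feature_types = {"gene", "CDS"}
    path = Path(path)
    if not path.exists():
        raise FormatError(f"GFF3 file not found: {path}")
    genes: list[GeneAnnotation] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end < start:
                raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: strand {strand!r} on a kept feature")
            gene_id = (
                _gff3_attribute(attrs, "ID")
                or _gff3_attribute(attrs, "locus_tag")
                or _gff3_attribute(attrs, "Name")
                or f"{ftype}_{lineno}"
            )
            if gene_id in seen_ids:
                raise FormatError(f"{path}:{lineno}: duplicate feature ID {gene_id!r}")
            seen_ids.add(gene_id)
            genes.append(GeneAnnotation(gene_id, contig, start, end, strand))
    return genes


def write_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig_id}\trose\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BedGraph read-start tracks
# ---------------------------------------------------------------------------

def _read_bedgraph(path: str | Path, contig_length: int | None) -> tuple[str | None, dict[int, int]]:
    counts: dict[int, int] = defaultdict(int)
    contig_id: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 whitespace-separated columns")
            contig, start_s, end_s, value_s = fields
            try:
                start, end = int(start_s), int(end_s)
                value = float(value_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric interval") from None
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative value {value}")
            if value != int(value):
                raise FormatError(f"{path}:{lineno}: non-integer read-start count {value}")
            if contig_id is None:
                contig_id = contig
            elif contig != contig_id:
                raise FormatError(f"{path}:{lineno}: multiple contigs in one track")
            if contig_length is not None and end > contig_length:
                raise FormatError(
                    f"{path}:{lineno}: interval end {end} beyond contig length {contig_length}"
                )
            # BedGraph is 0-based half-open; internal positions are 1-based.
            for pos in range(start + 1, end + 1):
                counts[pos] += int(value)
    return contig_id, {p: c for p, c in counts.items() if c > 0}


def load_read_starts(
    fw_path: str | Path,
    rv_path: str | Path,
    sample_id: str = "sample",
    replicate_id: str = "rep1",
    contig_length: int | None = None,
) -> ReadStartProfile:
    """Load a strand-specific pair of BedGraph read-start tracks."""
    contig_fw, counts_fw = _read_bedgraph(fw_path, contig_length)
    contig_rv, counts_rv = _read_bedgraph(rv_path, contig_length)
    if contig_fw and contig_rv and contig_fw != contig_rv:
        raise FormatError(f"strand tracks disagree on contig: {contig_fw} vs {contig_rv}")
    contig = contig_fw or contig_rv or "unknown"
    return ReadStartProfile(sample_id, replicate_id, contig, counts_fw, counts_rv)


def write_read_starts(profile: ReadStartProfile, fw_path: str | Path, rv_path: str | Path) -> None:
    """Write a profile as a BedGraph pair (single-base intervals, sorted)."""
    for counts, path in ((profile.counts_fw, fw_path), (profile.counts_rv, rv_path)):
        with open(path, "w") as fh:
            for pos in sorted(counts):
                fh.write(f"{profile.contig_id}\t{pos - 1}\t{pos}\t{counts[pos]}\n")


def read_starts_from_bam(
    path: str | Path,
    contig_id: str,
    sample_id: str = "sample",
    replicate_id: str = "rep1",
) -> ReadStartProfile:
    """Extract read 5'-ends from a coordinate-sorted BAM/SAM file.

    For a forward-mapped read the 5'-end is its lowest aligned coordinate;
    for a reverse-mapped read it is the highest.  Requires pysam (``bam``
    extra); BedGraph is the canonical interchange and needs no alignment
    dependency.
    """
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise RoseImportError from exc
    counts_fw: dict[int, int] = defaultdict(int)
    counts_rv: dict[int, int] = defaultdict(int)
    with pysam.AlignmentFile(str(path)) as bam:
        for read in bam.fetch(contig_id):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_reverse:
                counts_rv[read.reference_end] += 1  # reference_end is 0-based exclusive == 1-based last base
            else:
                counts_fw[read.reference_start + 1] += 1
    return ReadStartProfile(sample_id, replicate_id, contig_id, dict(counts_fw), dict(counts_rv))


class RoseImportError(ImportError):
    def __init__(self) -> None:
        super().__init__("BAM support requires pysam; install the 'bam' extra")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_tss_table(records: Sequence[Mapping], path: str | Path) -> None:
    """Write TSS-like records (mappings or dataclass ``as_record()`` dicts) as TSV."""
    if not len(records):
        raise ValueError("refusing to write an empty TSS table")
    pd.DataFrame(list(records)).to_csv(path, sep="\t", index=False)


def read_tss_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"TSS table not found: {path}")
    return pd.read_csv(path, sep="\t")


def write_logo_matrix(counts: np.ndarray | pd.DataFrame, path: str | Path) -> None:
    """Write a position x {A,C,G,T} count matrix as TSV (WebLogo-compatible input).

    Rows are 0-based alignment positions, columns A, C, G, T.
    """
    if isinstance(counts, pd.DataFrame):
        df = counts.loc[:, list(BASES)]
    else:
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("logo matrix must have shape (width, 4)")
        df = pd.DataFrame(counts, columns=list(BASES))
    if df.empty:
        raise ValueError("refusing to write an empty logo matrix")
    df.index.name = "position"
    df.to_csv(path, sep="\t")


def read_logo_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="position")
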