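"""Classify consensus TSSs relative to a gene annotation.

Each TSS gets exactly one of four categories (the scheme of Sharma-style
dRNA-seq annotation): *primary* (on the gene's strand, at most
``max_upstream_primary`` nt upstream of a gene's 5' end), *intragenic*
(within a gene body on the same strand), *antisense* (on the opposite strand
within ``antisense_flank`` nt of a gene, boundaries inclusive) and *orphan*
(none of the above).  When a TSS satisfies several definitions the priority
is primary > intragenic > antisense, so the categories partition the TSS set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import ParameterError
from .io_formats import GeneAnnotation
from .tss_detection import ConsensusTSS

CATEGORIES = ("primary", "intragenic", "antisense", "orphan")


@dataclass(frozen=True)
class ClassParams:
    max_upstream_primary: int = 300
    antisense_flank: int = 100

    def __post_init__(self) -> None:
        if self.max_upstream_primary < 1 or self.antisense_flank < 1:
            raise ParameterError("classification distances must be >= 1")


@dataclass
class ClassifiedTSS:
    tss: ConsensusTSS
    category: str
    gene_id: str | None
    distance_to_feature: int | None

    def as_record(self) -> dict:
        rec = self.tss.as_record()
        rec.update(
            category=self.category,
            gene_id=self.gene_id if self.gene_id is not None else "",
            distance=self.distance_to_feature if self.distance_to_feature is not None else "",
        )
        return rec


def _primary_distance(pos: int, gene: GeneAnnotation) -> int:
    """Distance from the TSS to the gene's 5' end, positive when upstream."""
    return gene.start - pos if gene.strand == "+" else pos - gene.end


def _antisense_distance(pos: int, gene: GeneAnnotation) -> int:
    """Signed genomic offset to the nearest gene boundary; 0 inside the gene."""
    if pos < gene.start:
        return pos - gene.start
    if pos > gene.end:
        return pos - gene.end
    return 0


def classify_tss(
    tss: ConsensusTSS,
    genes: list[GeneAnnotation],
    params: ClassParams | None = None,
) -> ClassifiedTSS:
    """Assign one category to a TSS; the nearest qualifying gene is associated.

    A TSS exactly at the annotated gene start (distance 0) is primary.
    Ties between equally near genes break to the smaller gene start.
    """
    params = params or ClassParams()
    pos, strand = tss.position, tss.strand
    same = [g for g in genes if g.contig_id == tss.contig_id and g.strand == strand]
    opposite = [g for g in genes if g.contig_id == tss.contig_id and g.strand != strand]

    primary = [
        (g, _primary_distance(pos, g))
        for g in same
        if 0 <= _primary_distance(pos, g) <= params.max_upstream_primary
    ]
    if primary:
        gene, dist = min(primary, key=lambda gd: (abs(gd[1]), gd[0].start))
        return ClassifiedTSS(tss, "primary", gene.gene_id, dist)

    intragenic = [
        (g, pos - g.start if g.strand == "+" else g.end - pos)
        for g in same
        if g.start <= pos <= g.end
    ]
    if intragenic:
        gene, dist = min(intragenic, key=lambda gd: (abs(gd[1]), gd[0].start))
        return ClassifiedTSS(tss, "intragenic", gene.gene_id, dist)

    antisense = [
        (g, _antisense_distance(pos, g))
        for g in opposite
        if g.start - params.antisense_flank <= pos <= g.end + params.antisense_flank
    ]
    if antisense:
        gene, dist = min(antisense, key=lambda gd: (abs(gd[1]), gd[0].start))
        return ClassifiedTSS(tss, "antisense", gene.gene_id, dist)

    return ClassifiedTSS(tss, "orphan", None, None)


def classify_all(
    tss_list: list[ConsensusTSS],
    genes: list[GeneAnnotation],
    params: ClassParams | None = None,
) -> list[ClassifiedTSS]:
    return [classify_tss(t, genes, params) for t in tss_list]


def classification_summary(classified: list[ClassifiedTSS]) -> dict[str, tuple[int, float]]:
    """Category -> (count, fraction) over a non-empty classified TSS list."""
    if not classified:
        raise ParameterError("cannot summarize an empty classification")
    counts = Counter(c.category for c in classified)
    n = len(classified)
    return {cat: (counts.get(cat, 0), counts.get(cat, 0) / n) for cat in CATEGORIES}
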