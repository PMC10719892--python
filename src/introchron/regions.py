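"""Coordinate-aware genome model.

Genes, promoters, distal regulatory elements (cCRE-like) and variant
sites, with interval intersection and a deterministic region-class
annotation. All coordinates are 0-based half-open internally; VCF-style
1-based positions are converted on construction via
:meth:`VariantSite.from_vcf`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "RegulatoryElement",
    "VariantSite",
    "RegionAnnotation",
    "build_promoter",
    "assign_flanking_elements",
    "annotate_variants",
]

REGION_CLASSES = ("gene_body", "promoter", "distal_regulatory", "none")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."  # "+", "-" or "." (unstranded)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) must be >= start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap between closest edges; 0 if overlapping or adjacent-overlap.

        Defined only on the same chromosome.
        """
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.end <= other.start:
            return other.start - self.end
        if other.end <= self.start:
            return self.start - other.end
        return 0


@dataclass(frozen=True)
class GeneModel:
    """A gene collapsed to a single genomic span with a TSS anchor."""

    gene_id: str
    symbol: str
    body: GenomicInterval
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        if not (self.body.start <= self.tss <= self.body.end):
            raise ValueError(
                f"TSS {self.tss} outside gene body [{self.body.start}, {self.body.end}]"
            )


@dataclass(frozen=True)
class RegulatoryElement:
    element_id: str
    span: GenomicInterval
    element_class: str = ""


@dataclass(frozen=True)
class VariantSite:
    """Bi-allelic variant; ``pos`` is 0-based internally."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ancestral_allele: str | None = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.ancestral_allele is not None and self.ancestral_allele not in (
            self.ref_allele,
            self.alt_allele,
        ):
            raise ValueError("ancestral allele, when known, must equal ref or alt")
        if self.pos < 0:
            raise ValueError("position must be >= 0")

    @classmethod
    def from_vcf(
        cls,
        chrom: str,
        pos_1based: int,
        ref: str,
        alt: str,
        ancestral: str | None = None,
    ) -> "VariantSite":
        return cls(chrom, pos_1based - 1, ref, alt, ancestral)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


def build_promoter(
    gene: GeneModel, upstream_bp: int = 5000, downstream_bp: int = 1000
) -> GenomicInterval:
    """Strand-oriented promoter window around the TSS.

    Covers ``upstream_bp`` before to ``downstream_bp`` after the TSS in
    transcription orientation, clipped at coordinate 0. With both windows
    zero the result is the empty interval at the TSS.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window sizes must be >= 0")
    if gene.strand == "+":
        start, end = gene.tss - upstream_bp, gene.tss + downstream_bp
    elif gene.strand == "-":
        start, end = gene.tss - downstream_bp, gene.tss + upstream_bp
    else:  # pragma: no cover - GeneModel already rejects this
        raise ValueError("promoter orientation undefined for unstranded gene")
    return GenomicInterval(gene.body.chrom, max(0, start), max(0, end), gene.strand)


def assign_flanking_elements(
    genes: Sequence[GeneModel],
    elements: Sequence[RegulatoryElement],
    window_bp: int = 1_000_000,
) -> dict[str, list[RegulatoryElement]]:
    """Map each gene to the regulatory elements within ``window_bp`` of its body.

    Distance is the gap between closest interval edges (0 when
    overlapping); the boundary is inclusive (distance == window_bp is
    assigned). An element may flank several genes.
    """
    by_chrom: dict[str, list[RegulatoryElement]] = {}
    for el in elements:
        by_chrom.setdefault(el.span.chrom, []).append(el)
    out: dict[str, list[RegulatoryElement]] = {}
    for gene in genes:
        hits = [
            el
            for el in by_chrom.get(gene.body.chrom, [])
            if gene.body.distance_to(el.span) <= window_bp
        ]
        out[gene.gene_id] = hits
    return out


@dataclass
class RegionAnnotation:
    """Per-variant region class plus the circadian genes it is assigned to.

    Every variant receives exactly one class under the precedence
    gene_body > promoter > distal_regulatory > none; gene assignments are
    only present for non-none classes.
    """

    classes: dict[tuple[str, int, str, str], str] = field(default_factory=dict)
    gene_sets: dict[tuple[str, int, str, str], frozenset[str]] = field(default_factory=dict)

    def region_class(self, variant: VariantSite) -> str:
        return self.classes.get(variant.key, "none")

    def genes(self, variant: VariantSite) -> frozenset[str]:
        return self.gene_sets.get(variant.key, frozenset())

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in REGION_CLASSES}
        for c in self.classes.values():
            counts[c] += 1
        return counts


def _tree_per_chrom(
    spans: Iterable[tuple[GenomicInterval, str]]
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for span, gene_id in spans:
        if span.length == 0:
            continue  # empty intervals contain no position
        trees.setdefault(span.chrom, IntervalTree()).addi(span.start, span.end, gene_id)
    return trees


def annotate_variants(
    variants: Sequence[VariantSite],
    genes: Sequence[GeneModel],
    promoters: Mapping[str, GenomicInterval],
    flanking_map: Mapping[str, Sequence[RegulatoryElement]],
) -> RegionAnnotation:
    """Annotate variants with a single region class and the genes involved.

    Precedence gene_body > promoter > distal_regulatory: a variant inside
    a gene body is gene_body even when it also falls in a promoter window
    or flanking element. Deterministic and independent of variant order.
    """
    gene_trees = _tree_per_chrom((g.body, g.gene_id) for g in genes)
    prom_trees = _tree_per_chrom(
        (span, gene_id) for gene_id, span in promoters.items()
    )
    flank_trees = _tree_per_chrom(
        (el.span, gene_id)
        for gene_id, els in flanking_map.items()
        for el in els
    )
    ann = RegionAnnotation()
    known_chroms = set(gene_trees) | set(prom_trees) | set(flank_trees)
    for v in variants:
        if v.chrom not in known_chroms:
            logger.debug("variant %s on chromosome absent from annotation", v.key)
            ann.classes[v.key] = "none"
            continue
        for cls, trees in (
            ("gene_body", gene_trees),
            ("promoter", prom_trees),
            ("distal_regulatory", flank_trees),
        ):
            tree = trees.get(v.chrom)
            hits = tree[v.pos] if tree is not None else set()
            if hits:
                ann.classes[v.key] = cls
                ann.gene_sets[v.key] = frozenset(h.data for h in hits)
                break
        else:
            ann.classes[v.key] = "none"
    return ann
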