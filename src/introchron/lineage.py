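"""Lineage-specific (fixed) variant classification and region enrichment.

A human-specific variant is a site where every modern individual carries
the derived allele while every archaic individual is homozygous
ancestral; an archaic-specific variant is homozygous derived in every
archaic while the derived allele is absent or extremely rare (frequency
<= 1e-5, boundary inclusive, in every modern population). Sites with a
heterozygous or missing archaic genotype are "neither" — fixation in the
archaic lineage requires dosage 2 in all individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .regions import RegionAnnotation, VariantSite
from .stats import ContingencyTable2x2, EnrichmentResult, fisher_exact

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeSummary",
    "UnpolarizedSiteError",
    "classify_lineage_specific",
    "enrich_fixed_in_regions",
]

LINEAGE_LABELS = ("human_specific", "archaic_specific", "neither")


class UnpolarizedSiteError(ValueError):
    """Raised when the ancestral allele of a site is unknown."""


@dataclass(frozen=True)
class GenotypeSummary:
    """Joint modern + archaic genotype summary at one site.

    ``archaic_dosages`` maps archaic individual name to derived-allele
    dosage in {0, 1, 2} or None for missing.
    """

    variant: VariantSite
    derived_freq_overall: float
    derived_freq_by_pop: Mapping[str, float]
    archaic_dosages: Mapping[str, int | None]

    def __post_init__(self) -> None:
        if not self.archaic_dosages:
            raise ValueError("at least one archaic individual required")
        freqs = [self.derived_freq_overall, *self.derived_freq_by_pop.values()]
        if any(f < 0 or f > 1 for f in freqs):
            raise ValueError("derived-allele frequencies must lie in [0, 1]")
        for name, d in self.archaic_dosages.items():
            if d is not None and d not in (0, 1, 2):
                raise ValueError(f"archaic dosage for {name} must be 0/1/2 or missing")


def classify_lineage_specific(
    summary: GenotypeSummary, rare_threshold: float = 1e-5
) -> str:
    """Classify a polarized site as human_specific / archaic_specific / neither."""
    if summary.variant.ancestral_allele is None:
        raise UnpolarizedSiteError(
            f"site {summary.variant.key} has unknown ancestral allele"
        )
    dosages = list(summary.archaic_dosages.values())
    if any(d is None for d in dosages):
        logger.debug("site %s has missing archaic genotype; neither", summary.variant.key)
        return "neither"
    if summary.derived_freq_overall == 1.0 and all(d == 0 for d in dosages):
        return "human_specific"
    if all(d == 2 for d in dosages) and all(
        f <= rare_threshold for f in summary.derived_freq_by_pop.values()
    ):
        return "archaic_specific"
    return "neither"


def enrich_fixed_in_regions(
    fixed_variants: Sequence[VariantSite],
    background_variants: Sequence[VariantSite],
    annotation: RegionAnnotation,
    region_classes: Iterable[str] = ("gene_body", "promoter", "distal_regulatory"),
) -> dict[str, EnrichmentResult]:
    """Fisher enrichment of fixed variants per region class.

    For each class the 2x2 is (fixed vs background) x (in-class vs not);
    ``background_variants`` are the lineage-derived but non-fixed sites
    and must be disjoint from the fixed set.
    """
    fixed_keys = {v.key for v in fixed_variants}
    if fixed_keys & {v.key for v in background_variants}:
        raise ValueError("fixed and background variant sets must be disjoint")
    results: dict[str, EnrichmentResult] = {}
    for region_class in region_classes:
        a = sum(1 for v in fixed_variants if annotation.region_class(v) == region_class)
        b = len(fixed_variants) - a
        c = sum(
            1 for v in background_variants if annotation.region_class(v) == region_class
        )
        d = len(background_variants) - c
        res = fisher_exact(ContingencyTable2x2(a, b, c, d))
        res.label = region_class
        results[region_class] = res
    return results
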