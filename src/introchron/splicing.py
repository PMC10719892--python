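"""Archaic splice-altering variants (SAVs) and shuffle-null gene enrichment.

A SAV is a variant whose maximum splice-delta probability (precomputed
upstream by a splice-effect predictor; this module never computes
deltas) strictly exceeds 0.2 and which is absent from the modern human
panel. SAVs are classified by which of the four sequenced archaic
individuals carry them, and circadian-gene enrichment is assessed
against a null that shuffles the delta column over the variant table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .stats import PermutationResult, permutation_enrichment

__all__ = [
    "ARCHAIC_INDIVIDUALS",
    "NEANDERTHALS",
    "SpliceDeltaRecord",
    "SavCall",
    "call_savs",
    "classify_sharing",
    "sav_gene_enrichment",
]

ARCHAIC_INDIVIDUALS = ("AltaiNea", "VindijaNea", "ChagyrskayaNea", "Denisovan")
NEANDERTHALS = frozenset(ARCHAIC_INDIVIDUALS[:3])

SHARING_CLASSES = (
    "Denisovan_private",
    "Altai_private",
    "Vindija_private",
    "Chagyrskaya_private",
    "Neanderthal_shared",
    "all_shared",
    "other",
)

_PRIVATE = {
    "AltaiNea": "Altai_private",
    "VindijaNea": "Vindija_private",
    "ChagyrskayaNea": "Chagyrskaya_private",
    "Denisovan": "Denisovan_private",
}


@dataclass(frozen=True)
class SpliceDeltaRecord:
    """One variant with its max splice-delta and carrier information."""

    variant_id: str
    max_delta: float
    carriers: frozenset
    in_modern_panel: bool
    gene_id: str
    is_tag_snp: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_delta <= 1.0):
            raise ValueError(f"max_delta must lie in [0, 1], got {self.max_delta}")
        unknown = set(self.carriers) - set(ARCHAIC_INDIVIDUALS)
        if unknown:
            raise ValueError(f"unknown carriers {sorted(unknown)}")


@dataclass(frozen=True)
class SavCall:
    variant_id: str
    gene_id: str
    max_delta: float
    sharing_class: str


def classify_sharing(carriers: Iterable[str]) -> str:
    """Cross-individual sharing class of a SAV.

    All four carriers -> all_shared; exactly the three Neanderthals ->
    Neanderthal_shared; a single carrier -> the corresponding private
    class; any other combination -> other.
    """
    carriers = frozenset(carriers)
    if not carriers:
        raise ValueError("carriers must be non-empty")
    unknown = carriers - set(ARCHAIC_INDIVIDUALS)
    if unknown:
        raise ValueError(f"unknown carriers {sorted(unknown)}")
    if carriers == set(ARCHAIC_INDIVIDUALS):
        return "all_shared"
    if carriers == NEANDERTHALS:
        return "Neanderthal_shared"
    if len(carriers) == 1:
        return _PRIVATE[next(iter(carriers))]
    return "other"


def call_savs(
    records: Sequence[SpliceDeltaRecord], delta_threshold: float = 0.2
) -> list[SavCall]:
    """Call archaic-specific splice-altering variants.

    A record is called iff max_delta > delta_threshold (strict) and the
    variant is absent from the modern panel.
    """
    calls = []
    for r in records:
        if r.max_delta > delta_threshold and not r.in_modern_panel:
            calls.append(
                SavCall(r.variant_id, r.gene_id, r.max_delta, classify_sharing(r.carriers))
            )
    return calls


def _observed_gene_count(
    deltas: np.ndarray,
    archaic_specific: np.ndarray,
    circadian_gene_code: np.ndarray,
    n_circadian: int,
    delta_threshold: float,
) -> int:
    sel = archaic_specific & (deltas > delta_threshold) & (circadian_gene_code >= 0)
    if not sel.any():
        return 0
    hit = np.bincount(circadian_gene_code[sel], minlength=n_circadian) > 0
    return int(hit.sum())


def sav_gene_enrichment(
    records: Sequence[SpliceDeltaRecord],
    circadian_genes: Iterable[str],
    delta_threshold: float = 0.2,
    n_iter: int = 10_000,
    seed: int = 0,
    shuffle_scope: str = "all",
    tag_only: bool = False,
    check_conservation: bool = False,
) -> PermutationResult:
    """Shuffle-null enrichment of circadian genes among SAV-containing genes.

    The observed statistic is the number of circadian genes containing at
    least one archaic-specific variant with delta above threshold. Each
    null iteration permutes the max-delta column over the variant table —
    over all variants (``shuffle_scope="all"``, default) or over
    archaic-specific variants only (``"archaic_specific"``) — keeping
    gene assignments and archaic-specific flags fixed, and recounts.
    ``tag_only`` restricts the whole analysis to tag-SNP records.
    """
    if shuffle_scope not in ("all", "archaic_specific"):
        raise ValueError(f"unknown shuffle_scope {shuffle_scope!r}")
    if tag_only:
        records = [r for r in records if r.is_tag_snp]
    circadian = sorted(set(circadian_genes))
    circ_index = {g: i for i, g in enumerate(circadian)}
    deltas = np.array([r.max_delta for r in records], dtype=float)
    archaic_specific = np.array([not r.in_modern_panel for r in records], dtype=bool)
    circ_code = np.array(
        [circ_index.get(r.gene_id, -1) for r in records], dtype=np.int64
    )
    if shuffle_scope == "archaic_specific":
        keep = archaic_specific
        deltas, circ_code = deltas[keep], circ_code[keep]
        archaic_specific = archaic_specific[keep]
    if not ((deltas > delta_threshold) & archaic_specific).any():
        res = permutation_enrichment(0.0, lambda rng: 0.0, n_iter=1, seed=seed)
        res.flags = res.flags + ("no_variants_above_threshold",)
        res.enrichment_defined = False
        return res
    observed = _observed_gene_count(
        deltas, archaic_specific, circ_code, len(circadian), delta_threshold
    )
    delta_multiset = np.sort(deltas)

    def null_stat(rng: np.random.Generator) -> float:
        shuffled = rng.permutation(deltas)
        if check_conservation and not np.array_equal(np.sort(shuffled), delta_multiset):
            raise AssertionError("shuffle altered the delta multiset")
        return _observed_gene_count(
            shuffled, archaic_specific, circ_code, len(circadian), delta_threshold
        )

    return permutation_enrichment(observed, null_stat, n_iter=n_iter, seed=seed)
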