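"""Functional effects of introgressed variants: consensus sets, eQTL
enrichment and pleiotropy.

Introgression calls come from up to six published maps; consensus sets
are anchored on the Sprime map (the base set), optionally requiring
support from at least one other map or from all six. eQTL enrichment is
counted at the (variant, gene, tissue) tuple level by default, which is
the unit at which tissue-resolved eQTL catalogs report associations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .stats import (
    ContingencyTable2x2,
    EnrichmentResult,
    MannWhitneyResult,
    bonferroni_threshold,
    fisher_exact,
    mann_whitney,
)

__all__ = [
    "INTROGRESSION_MAPS",
    "SPRIME",
    "build_consensus_sets",
    "enrichment_from_totals",
    "eqtl_enrichment",
    "pleiotropy_tests",
]

SPRIME = "sprime"
#: the Sprime base map plus five other published introgression maps
INTROGRESSION_MAPS = (
    SPRIME,
    "vernot2016",
    "sankararaman2014",
    "steinruecken2018",
    "skov2020",
    "schaefer2021",
)


def build_consensus_sets(
    calls: Mapping[str, Iterable[str]],
    map_names: Sequence[str] = INTROGRESSION_MAPS,
    sprime_label: str = SPRIME,
) -> dict[str, set[str]]:
    """Consensus introgression sets from per-variant map membership.

    ``calls`` maps variant id to the introgression maps supporting it.
    Returns ``base`` (Sprime members), ``base_plus_one`` (Sprime plus at
    least one other map) and ``all_maps`` (supported by every map in
    ``map_names``).
    """
    all_names = set(map_names)
    if sprime_label not in all_names:
        raise ValueError(f"{sprime_label!r} must be among map_names")
    base: set[str] = set()
    base_plus_one: set[str] = set()
    all_maps: set[str] = set()
    for variant, maps in calls.items():
        maps = set(maps)
        if not maps:
            raise ValueError(f"variant {variant} has empty map support")
        unknown = maps - all_names
        if unknown:
            raise ValueError(f"variant {variant}: unknown maps {sorted(unknown)}")
        if sprime_label in maps:
            base.add(variant)
            if maps - {sprime_label}:
                base_plus_one.add(variant)
        if maps == all_names:
            all_maps.add(variant)
    return {"base": base, "base_plus_one": base_plus_one, "all_maps": all_maps}


def enrichment_from_totals(
    total: int, n_condition: int, n_feature: int, n_both: int
) -> EnrichmentResult:
    """2x2 enrichment reconstructed from marginal totals.

    ``total`` observations of which ``n_condition`` satisfy the row
    condition (e.g. introgressed), ``n_feature`` the column feature
    (e.g. circadian-gene eQTL), ``n_both`` both. Used e.g. to recompute
    the introgressed-x-circadian eQTL odds ratio from published tuple
    counts.
    """
    a = n_both
    b = n_condition - n_both
    c = n_feature - n_both
    d = total - n_condition - n_feature + n_both
    return fisher_exact(ContingencyTable2x2(a, b, c, d))


def _dedup_tuples(eqtls: pd.DataFrame) -> pd.DataFrame:
    return eqtls.drop_duplicates(subset=["variant", "gene", "tissue"])


def eqtl_enrichment(
    eqtls: pd.DataFrame,
    introgressed_set: Iterable[str],
    circadian_genes: Iterable[str],
    scope: str = "overall",
    alpha: float = 0.05,
    n_tissues_for_bonferroni: int = 49,
    counting: str = "tuple",
) -> EnrichmentResult | dict[str, EnrichmentResult]:
    """Enrichment of circadian-gene eQTL among introgressed eQTL.

    ``eqtls`` has columns variant, gene, tissue; tuples are deduplicated.
    The 2x2 is (introgressed vs not) x (circadian-gene vs not), counted
    per tuple by default or per distinct variant with
    ``counting="variant"``. ``scope="per_tissue"`` returns one result per
    tissue with significance tiers against alpha and the Bonferroni
    threshold alpha / n_tissues_for_bonferroni; a tissue with no
    circadian introgressed tuples is still emitted, flagged.
    """
    if scope not in ("overall", "per_tissue"):
        raise ValueError(f"unknown scope {scope!r}")
    if counting not in ("tuple", "variant"):
        raise ValueError(f"unknown counting {counting!r}")
    introgressed_set = set(introgressed_set)
    circadian_genes = set(circadian_genes)
    df = _dedup_tuples(eqtls)

    def one_table(sub: pd.DataFrame) -> EnrichmentResult:
        if counting == "variant":
            intro = sub.groupby("variant")["gene"].apply(
                lambda g: bool(set(g) & circadian_genes)
            )
            is_intro = pd.Series(intro.index.isin(introgressed_set), index=intro.index)
            is_circ = intro
        else:
            is_intro = sub["variant"].isin(introgressed_set)
            is_circ = sub["gene"].isin(circadian_genes)
        a = int((is_intro & is_circ).sum())
        b = int((is_intro & ~is_circ).sum())
        c = int((~is_intro & is_circ).sum())
        d = int((~is_intro & ~is_circ).sum())
        res = fisher_exact(ContingencyTable2x2(a, b, c, d))
        if a == 0:
            res.flags = res.flags + ("no_circadian_introgressed_tuples",)
        return res

    corrected = bonferroni_threshold(alpha, n_tissues_for_bonferroni).value
    if scope == "overall":
        res = one_table(df)
        res.significance_tier = res.tier_against(alpha, corrected)
        return res
    out: dict[str, EnrichmentResult] = {}
    for tissue, sub in df.groupby("tissue"):
        res = one_table(sub)
        res.label = str(tissue)
        res.significance_tier = res.tier_against(alpha, corrected)
        out[str(tissue)] = res
    return out


@dataclass
class PleiotropyResult:
    fisher: EnrichmentResult
    mann_whitney: MannWhitneyResult
    circadian_trait_counts: list[int]
    noncircadian_trait_counts: list[int]


def pleiotropy_tests(
    circadian_variants: Iterable[str],
    noncircadian_variants: Iterable[str],
    associations: pd.DataFrame,
    gw_threshold: float = 5e-8,
) -> PleiotropyResult:
    """Pleiotropy of introgressed circadian vs noncircadian variants.

    ``associations`` has columns variant, trait, p. A variant is
    "associated" when it has at least one association at genome-wide
    significance (p <= gw_threshold, boundary inclusive). The Fisher test
    compares the associated/not ratio between the two variant sets; the
    Mann-Whitney test compares unique-trait counts among associated
    variants only.
    """
    circ = set(circadian_variants)
    noncirc = set(noncircadian_variants)
    if not circ or not noncirc:
        raise ValueError("both variant partitions must be non-empty")
    if circ & noncirc:
        raise ValueError("variant partitions must be disjoint")
    sig = associations[associations["p"] <= gw_threshold]
    traits_per_variant = sig.groupby("variant")["trait"].nunique()

    def split(variants: set[str]) -> tuple[int, list[int]]:
        counts = [
            int(traits_per_variant[v]) for v in variants if v in traits_per_variant.index
        ]
        return len(counts), counts

    n_circ_assoc, circ_counts = split(circ)
    n_non_assoc, non_counts = split(noncirc)
    table = ContingencyTable2x2(
        a=n_circ_assoc,
        b=len(circ) - n_circ_assoc,
        c=n_non_assoc,
        d=len(noncirc) - n_non_assoc,
    )
    fisher = fisher_exact(table)
    if circ_counts and non_counts:
        mw = mann_whitney(circ_counts, non_counts)
    else:
        mw = MannWhitneyResult(
            u_statistic=float("nan"),
            p_value=1.0,
            n_x=len(circ_counts),
            n_y=len(non_counts),
            degenerate=True,
        )
    return PleiotropyResult(
        fisher=fisher,
        mann_whitney=mw,
        circadian_trait_counts=circ_counts,
        noncircadian_trait_counts=non_counts,
    )
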