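"""Circadian gene-set curation.

The circadian gene set is assembled from five evidence sources — an
expert-curated list plus four annotation databases (a Gene Ontology
circadian-rhythm term, the Circadian Gene Database, GWAS-catalog
chronotype/circadian hits, and a WikiPathways curated set) — under a
confidence hierarchy: expert membership, or three of the four database
sources, gives high confidence; exactly two database sources gives
medium; one gives low. Low-confidence genes are excluded from the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["SOURCES", "GeneEvidence", "assign_confidence", "curate_gene_set"]

#: the expert list plus the four database sources
SOURCES = ("expert", "GO_circadian", "CGDB", "GWAS_catalog", "WikiPathways")
_DATABASE_SOURCES = frozenset(SOURCES[1:])

#: evidence-TSV column name per source
SOURCE_COLUMNS = {
    "expert": "expert",
    "GO_circadian": "go",
    "CGDB": "cgdb",
    "GWAS_catalog": "gwas_catalog",
    "WikiPathways": "wikipathways",
}


@dataclass(frozen=True)
class GeneEvidence:
    gene_id: str
    sources: frozenset

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError(f"gene {self.gene_id}: evidence sources must be non-empty")
        unknown = set(self.sources) - set(SOURCES)
        if unknown:
            raise ValueError(f"gene {self.gene_id}: unknown sources {sorted(unknown)}")


def assign_confidence(evidence: GeneEvidence) -> str:
    """Confidence tier from the evidence sources alone.

    Expert membership dominates: an expert-annotated gene is high
    regardless of database support. Otherwise the tier counts database
    sources: >=3 high, ==2 medium, ==1 low.
    """
    n_db = len(set(evidence.sources) & _DATABASE_SOURCES)
    if "expert" in evidence.sources or n_db >= 3:
        return "high"
    if n_db == 2:
        return "medium"
    return "low"


def curate_gene_set(evidence_table: pd.DataFrame) -> pd.DataFrame:
    """Apply the confidence hierarchy and drop low-confidence genes.

    ``evidence_table`` has one row per gene with columns ``gene_id`` and
    the 0/1 source flags ``expert, go, cgdb, gwas_catalog, wikipathways``
    (GO relationship expansion is assumed already folded into the ``go``
    flag). Returns the high+medium rows with a ``tier`` column, in
    gene_id order; duplicate gene_ids are an error.
    """
    if evidence_table["gene_id"].duplicated().any():
        dups = evidence_table.loc[evidence_table["gene_id"].duplicated(), "gene_id"]
        raise ValueError(f"duplicate gene_id rows: {sorted(set(dups))}")
    tiers = []
    for _, row in evidence_table.iterrows():
        sources = frozenset(
            src for src, col in SOURCE_COLUMNS.items() if int(row[col]) == 1
        )
        tiers.append(assign_confidence(GeneEvidence(str(row["gene_id"]), sources)))
    out = evidence_table.copy()
    out["tier"] = tiers
    out = out[out["tier"].isin(["high", "medium"])]
    return out.sort_values("gene_id").reset_index(drop=True)
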