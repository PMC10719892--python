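"""Readers and writers for the pipeline's file dialects.

Genes travel as a GFF-lite TSV (gene_id, symbol, chrom, start, end,
strand, tss), regulatory elements as BED4, variants as sites-only VCF or
an equivalent TSV, and everything else as headered TSV. All writers use
repr-roundtrip float formatting so that rerunning a stage with the same
seed produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .lineage import GenotypeSummary
from .regions import GeneModel, GenomicInterval, RegulatoryElement, VariantSite
from .splicing import SpliceDeltaRecord

__all__ = [
    "read_genes_tsv",
    "write_genes_tsv",
    "read_bed4",
    "write_bed4",
    "read_variants",
    "read_genotype_summaries",
    "read_splice_records",
    "write_tsv",
    "write_json",
    "file_sha256",
]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    genes = []
    for _, row in df.iterrows():
        genes.append(
            GeneModel(
                gene_id=str(row["gene_id"]),
                symbol=str(row["symbol"]),
                body=GenomicInterval(
                    str(row["chrom"]), int(row["start"]), int(row["end"]), str(row["strand"])
                ),
                tss=int(row["tss"]),
                strand=str(row["strand"]),
            )
        )
    return genes


def write_genes_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "symbol": [g.symbol for g in genes],
            "chrom": [g.body.chrom for g in genes],
            "start": [g.body.start for g in genes],
            "end": [g.body.end for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
        }
    )
    write_tsv(df, path)


def read_bed4(path: str | Path) -> list[RegulatoryElement]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "name"])
    return [
        RegulatoryElement(
            element_id=str(row["name"]),
            span=GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"])),
        )
        for _, row in df.iterrows()
    ]


def write_bed4(elements: Sequence[RegulatoryElement], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [e.span.chrom for e in elements],
            "start": [e.span.start for e in elements],
            "end": [e.span.end for e in elements],
            "name": [e.element_id for e in elements],
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def _read_variants_vcf(path: Path) -> list[VariantSite]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue  # restrict to biallelic sites
            aa = rec.info.get("AA") if "AA" in rec.info else None
            if isinstance(aa, tuple):
                aa = aa[0]
            out.append(
                VariantSite.from_vcf(
                    rec.chrom, rec.pos, rec.ref, rec.alts[0], ancestral=aa
                )
            )
    return out


def read_variants(path: str | Path) -> list[VariantSite]:
    """Variant sites from a sites-only VCF or the TSV dialect.

    The TSV dialect has columns chrom, pos (1-based), ref, alt and
    optionally ancestral.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz"):
        return _read_variants_vcf(path)
    df = pd.read_csv(path, sep="\t")
    has_anc = "ancestral" in df.columns
    return [
        VariantSite.from_vcf(
            str(row["chrom"]),
            int(row["pos"]),
            str(row["ref"]),
            str(row["alt"]),
            ancestral=str(row["ancestral"]) if has_anc and pd.notna(row["ancestral"]) else None,
        )
        for _, row in df.iterrows()
    ]


def read_genotype_summaries(
    source: str | Path | pd.DataFrame,
) -> list[GenotypeSummary]:
    """Joint genotype summaries from the panel TSV.

    Expects the dialect written by the synthetic generator: variant,
    chrom, pos (1-based), ref, alt, ancestral, AF_<pop> columns, AF_ALL,
    and dosage_<archaic> columns (empty cell = missing genotype).
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    pop_names = [c[3:] for c in df.columns if c.startswith("AF_") and c != "AF_ALL"]
    archaic_names = [c[len("dosage_"):] for c in df.columns if c.startswith("dosage_")]
    cols = ["chrom", "pos", "ref", "alt", "ancestral", "AF_ALL"]
    cols += [f"AF_{p}" for p in pop_names] + [f"dosage_{a}" for a in archaic_names]
    out = []
    for row in df[cols].itertuples(index=False, name=None):
        chrom, pos, ref, alt, ancestral, af_all = row[:6]
        freqs = row[6 : 6 + len(pop_names)]
        dosages = row[6 + len(pop_names) :]
        variant = VariantSite.from_vcf(
            str(chrom),
            int(pos),
            str(ref),
            str(alt),
            ancestral=str(ancestral) if pd.notna(ancestral) else None,
        )
        out.append(
            GenotypeSummary(
                variant=variant,
                derived_freq_overall=float(af_all),
                derived_freq_by_pop=dict(zip(pop_names, map(float, freqs))),
                archaic_dosages={
                    a: (int(d) if pd.notna(d) else None)
                    for a, d in zip(archaic_names, dosages)
                },
            )
        )
    return out


def read_splice_records(source: str | Path | pd.DataFrame) -> list[SpliceDeltaRecord]:
    """Splice-delta records from the TSV dialect (carriers comma-joined)."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    out = []
    for _, row in df.iterrows():
        carriers = frozenset(
            c for c in str(row["carriers"]).split(",") if c and c != "nan"
        )
        out.append(
            SpliceDeltaRecord(
                variant_id=str(row["variant"]),
                max_delta=float(row["max_delta"]),
                carriers=carriers,
                in_modern_panel=bool(row["in_modern_panel"]),
                gene_id=str(row["gene_id"]),
                is_tag_snp=bool(row.get("is_tag_snp", False)),
            )
        )
    return out
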