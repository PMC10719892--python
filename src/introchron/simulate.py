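"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the statistical structure of the study's real
inputs — a joint modern + archaic genotype panel, per-variant splice
deltas, imputed regulation matrices, tissue-resolved eQTL tables with
introgression-map membership, and LD-blocked GWAS summary statistics
with population frequencies — at roughly 1/100 of genome scale, with
plantable effect sizes so every downstream statistic can be tested by
parameter recovery. They emulate statistical structure only: there is no
coalescent or demographic realism.

Every generator is a pure function of a :class:`SimulationConfig`; one
global seed fans out into independent, stably-keyed streams per
generator, so outputs are byte-identical across reruns and insensitive
to which generators are invoked. Truth labels are always emitted
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chronotype import POPULATION_LATITUDES
from .introgression import INTROGRESSION_MAPS, SPRIME
from .regions import GeneModel, GenomicInterval, RegulatoryElement
from .regulation import RegulationMatrix
from .splicing import ARCHAIC_INDIVIDUALS

__all__ = [
    "SimulationConfig",
    "synthetic_gene_annotation",
    "generate_genotype_panel",
    "generate_splice_deltas",
    "generate_regulation_matrix",
    "generate_eqtl_and_maps",
    "generate_gwas_and_frequencies",
    "generate_gene_evidence",
    "generate_trait_associations",
    "generate_adaptive_regions",
]

# fixed stream keys: one independent generator per data product
_STREAMS = {
    "genome": 11,
    "genotypes": 23,
    "splice": 37,
    "regulation": 41,
    "eqtl": 53,
    "gwas": 67,
    "evidence": 71,
    "traits": 79,
    "adaptive": 83,
}

_BASES = np.array(["A", "C", "G", "T"])


def _rng(config: "SimulationConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STREAMS[stream]]))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale conditions plus plantable effect sizes.

    Counts mirror the study design (2,504 modern individuals, 4 archaic
    genomes, 246 circadian genes, 49 tissues); variant-level products are
    generated at ~1/100 of genome scale so the full pipeline runs in
    minutes. Planted odds ratios / offsets / biases default to the null.
    """

    seed: int = 0
    # panel composition
    n_modern: int = 2504
    populations: tuple[tuple[str, float], ...] = tuple(POPULATION_LATITUDES.items())
    archaics: tuple[str, ...] = ARCHAIC_INDIVIDUALS
    # gene annotation
    n_genes: int = 2000
    n_circadian: int = 246
    n_tissues: int = 49
    n_elements_per_gene: float = 2.0
    # genotype panel
    n_variants: int = 40_000
    frac_human_specific: float = 0.002
    frac_archaic_specific: float = 0.0075
    lineage_region_or: float = 1.0
    background_in_region_p: float = 0.05
    # splice deltas
    n_splice_variants: int = 16_000
    frac_archaic_specific_splice: float = 0.3
    splice_delta_exceed_p: float = 0.002
    sav_circadian_excess: float = 1.0
    # regulation matrix
    n_regulation_genes: int = 120
    max_tissues_per_regulation_gene: int = 5
    n_dr_planted: int = 0
    dr_z: float = 6.0
    # eQTL + introgression maps
    n_eqtl_tuples: int = 100_000
    eqtl_circadian_p: float = 0.021
    eqtl_introgressed_p: float = 0.028
    eqtl_or: float = 1.0
    map_concordance: float = 0.6
    # GWAS + geography
    n_gwas_variants: int = 2000
    ld_block_size: int = 5
    n_signif_blocks: int = 40
    morning_bias: float = 0.5
    near_circadian_p: float = 0.3
    n_cline_variants: int = 5
    cline_slope: float = 0.004
    cline_noise: float = 0.01

    def __post_init__(self) -> None:
        if self.n_modern < 1 or self.n_genes < 1 or self.n_variants < 1:
            raise ValueError("counts must be >= 1")
        if self.n_circadian > self.n_genes:
            raise ValueError("n_circadian cannot exceed n_genes")
        if self.lineage_region_or <= 0 or self.eqtl_or <= 0:
            raise ValueError("planted odds ratios must be > 0")
        for p in (
            self.frac_human_specific,
            self.frac_archaic_specific,
            self.background_in_region_p,
            self.eqtl_circadian_p,
            self.eqtl_introgressed_p,
            self.map_concordance,
            self.morning_bias,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def population_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.populations)

    @property
    def latitude_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.populations, columns=["population", "latitude"])


# --------------------------------------------------------------------------
# shared synthetic gene annotation


def synthetic_gene_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[str], list[RegulatoryElement]]:
    """Deterministic synthetic gene models, circadian subset, and cCRE-like
    elements near genes.

    Genes are tiled over 22 chromosomes with random body lengths
    (20-100 kb) and intergenic gaps; the circadian subset is a random
    draw of ``n_circadian`` gene ids; each gene gets a Poisson number of
    flanking elements within a few hundred kb.
    """
    rng = _rng(config, "genome")
    genes: list[GeneModel] = []
    elements: list[RegulatoryElement] = []
    n_chrom = 22
    per_chrom = -(-config.n_genes // n_chrom)
    gid = 0
    for c in range(1, n_chrom + 1):
        cursor = 100_000
        for _ in range(per_chrom):
            if gid >= config.n_genes:
                break
            length = int(rng.integers(20_000, 100_000))
            gap = int(rng.integers(100_000, 300_000))
            start = cursor
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end
            gene_id = f"G{gid:05d}"
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    symbol=gene_id,
                    body=GenomicInterval(f"chr{c}", start, end, strand),
                    tss=tss,
                    strand=strand,
                )
            )
            n_el = rng.poisson(config.n_elements_per_gene)
            for k in range(n_el):
                offset = int(rng.integers(-500_000, 500_000))
                el_start = max(0, start + offset)
                elements.append(
                    RegulatoryElement(
                        element_id=f"E{gid:05d}_{k}",
                        span=GenomicInterval(f"chr{c}", el_start, el_start + 300),
                        element_class="cCRE",
                    )
                )
            cursor = end + gap
            gid += 1
    circadian = sorted(
        rng.choice([g.gene_id for g in genes], size=config.n_circadian, replace=False)
    )
    return genes, circadian, elements


def _planted_in_region_p(or_planted: float, p_background: float) -> float:
    odds_bg = p_background / (1 - p_background)
    odds = or_planted * odds_bg
    p = odds / (1 + odds)
    if not (0.0 < p < 1.0):
        raise ValueError(
            f"planted OR {or_planted} infeasible for background rate {p_background}"
        )
    return p


# --------------------------------------------------------------------------
# genotype panel


def generate_genotype_panel(
    config: SimulationConfig,
    genes: list[GeneModel] | None = None,
    circadian: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """VCF-like joint genotype summary table plus per-variant truth labels.

    Each site carries per-population derived-allele frequencies and
    per-archaic derived dosages consistent with its true lineage class
    (human_specific / archaic_specific / neither). Fixed (lineage-
    specific) sites are placed inside circadian gene bodies at a rate
    realizing ``lineage_region_or`` against the ``neither`` background
    rate ``background_in_region_p``.
    """
    if genes is None or circadian is None:
        genes, circadian, _ = synthetic_gene_annotation(config)
    rng = _rng(config, "genotypes")
    circ_bodies = [g.body for g in genes if g.gene_id in set(circadian)]
    chroms = sorted({g.body.chrom for g in genes}, key=lambda c: int(c[3:]))
    chrom_span = {c: max(g.body.end for g in genes if g.body.chrom == c) + 200_000 for c in chroms}

    p_fixed = _planted_in_region_p(config.lineage_region_or, config.background_in_region_p)
    n = config.n_variants
    lineage = rng.choice(
        ["human_specific", "archaic_specific", "neither"],
        size=n,
        p=[
            config.frac_human_specific,
            config.frac_archaic_specific,
            1 - config.frac_human_specific - config.frac_archaic_specific,
        ],
    )
    in_region = np.where(
        lineage == "neither",
        rng.random(n) < config.background_in_region_p,
        rng.random(n) < p_fixed,
    )

    bodies_by_chrom: dict[str, list] = {}
    for body in circ_bodies:
        bodies_by_chrom.setdefault(body.chrom, []).append((body.start, body.end))

    chrom_col = np.empty(n, dtype=object)
    pos_col = np.empty(n, dtype=np.int64)
    body_idx = rng.integers(0, len(circ_bodies), size=n)
    pos_frac = rng.random(n)
    for i in range(n):
        if in_region[i]:
            body = circ_bodies[body_idx[i]]
            chrom_col[i] = body.chrom
            pos_col[i] = body.start + int(pos_frac[i] * body.length)
        else:
            # rejection-sample outside circadian bodies so the planted
            # in-region odds ratio is exact, not diluted by chance hits
            while True:
                c = chroms[int(rng.integers(0, len(chroms)))]
                p = int(rng.random() * chrom_span[c])
                if not any(s <= p < e for s, e in bodies_by_chrom.get(c, ())):
                    break
            chrom_col[i] = c
            pos_col[i] = p

    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    pops = config.population_names
    n_arch = len(config.archaics)
    freq = np.empty((n, len(pops)))
    dosages = np.empty((n, n_arch), dtype=np.int64)
    base_freq = rng.beta(0.5, 2.0, size=n)
    pop_jitter = rng.normal(0, 0.03, size=(n, len(pops)))
    het_draws = rng.random(size=(n, n_arch))
    for i in range(n):
        if lineage[i] == "human_specific":
            freq[i, :] = 1.0
            dosages[i, :] = 0
        elif lineage[i] == "archaic_specific":
            freq[i, :] = 0.0
            dosages[i, :] = 2
        else:
            freq[i, :] = np.clip(base_freq[i] + pop_jitter[i], 0.0, 1.0)
            # keep "neither" sites away from the fixed/rare boundaries
            freq[i, :] = np.clip(freq[i, :], 0.001, 0.999)
            dosages[i, :] = (het_draws[i] < base_freq[i]).astype(np.int64) + (
                rng.random(n_arch) < base_freq[i]
            ).astype(np.int64)

    sites = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos": pos_col + 1,  # 1-based, VCF-style, in the emitted table
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "ancestral": _BASES[ref_idx],  # derived allele is always alt here
        }
    )
    for j, pop in enumerate(pops):
        sites[f"AF_{pop}"] = freq[:, j]
    sites["AF_ALL"] = freq.mean(axis=1)
    # overall frequency must agree with fixation status exactly
    sites.loc[lineage == "human_specific", "AF_ALL"] = 1.0
    sites.loc[lineage == "archaic_specific", "AF_ALL"] = 0.0
    for j, arch in enumerate(config.archaics):
        sites[f"dosage_{arch}"] = dosages[:, j]
    sites.insert(0, "variant", [f"v{i:06d}" for i in range(n)])
    truth = pd.DataFrame(
        {
            "variant": sites["variant"],
            "lineage_truth": lineage,
            "in_circadian_body": in_region,
        }
    )
    return sites, truth


# --------------------------------------------------------------------------
# splice deltas


def generate_splice_deltas(
    config: SimulationConfig,
    genes: list[GeneModel] | None = None,
    circadian: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variant max splice-delta table with carriers and gene assignment.

    Deltas are mostly tiny (Beta(0.2, 8)); a fraction
    ``splice_delta_exceed_p`` of archaic-specific variants is pushed
    above the 0.2 calling threshold. ``sav_circadian_excess`` multiplies
    the probability that such a high-delta archaic-specific variant is
    assigned to a circadian gene, planting gene-level enrichment.
    """
    if genes is None or circadian is None:
        genes, circadian, _ = synthetic_gene_annotation(config)
    rng = _rng(config, "splice")
    n = config.n_splice_variants
    gene_ids = [g.gene_id for g in genes]
    circ_set = sorted(set(circadian))
    noncirc = sorted(set(gene_ids) - set(circ_set))
    archaic_specific = rng.random(n) < config.frac_archaic_specific_splice
    deltas = rng.beta(0.2, 8.0, size=n) * 0.2  # all below threshold
    high = archaic_specific & (rng.random(n) < config.splice_delta_exceed_p)
    deltas[high] = 0.2 + rng.random(high.sum()) * 0.8

    p_circ_base = len(circ_set) / len(gene_ids)
    p_circ_high = min(1.0, p_circ_base * config.sav_circadian_excess)
    gene_col = np.empty(n, dtype=object)
    to_circ = np.where(high, rng.random(n) < p_circ_high, rng.random(n) < p_circ_base)
    circ_pick = rng.integers(0, len(circ_set), size=n)
    noncirc_pick = rng.integers(0, len(noncirc), size=n)
    for i in range(n):
        gene_col[i] = circ_set[circ_pick[i]] if to_circ[i] else noncirc[noncirc_pick[i]]

    carrier_mask = rng.random((n, len(ARCHAIC_INDIVIDUALS))) < 0.5
    # ensure every archaic-specific variant has at least one carrier
    none = ~carrier_mask.any(axis=1)
    carrier_mask[none, rng.integers(0, len(ARCHAIC_INDIVIDUALS), size=int(none.sum()))] = True
    carriers = [
        ",".join(a for a, m in zip(ARCHAIC_INDIVIDUALS, row) if m) for row in carrier_mask
    ]
    return pd.DataFrame(
        {
            "variant": [f"s{i:06d}" for i in range(n)],
            "max_delta": deltas,
            "carriers": carriers,
            "in_modern_panel": ~archaic_specific,
            "gene_id": gene_col,
            "is_tag_snp": rng.random(n) < 0.1,
        }
    )


# --------------------------------------------------------------------------
# regulation matrix


def generate_regulation_matrix(
    config: SimulationConfig,
    genes: list[GeneModel] | None = None,
) -> tuple[RegulationMatrix, pd.DataFrame]:
    """Imputed-regulation matrix with planted divergently regulated genes.

    Modern-panel values are standard normal per modeled (gene, tissue);
    archaic values are drawn from the same distribution except for the
    ``n_dr_planted`` truth-DR genes, whose archaic values sit at
    ``dr_z`` standard deviations in every modeled tissue and archaic.
    Tissue coverage per gene is uniform on
    [1, max_tissues_per_regulation_gene].
    """
    if genes is None:
        genes, _, _ = synthetic_gene_annotation(config)
    rng = _rng(config, "regulation")
    model_genes = [g.gene_id for g in genes[: config.n_regulation_genes]]
    planted = sorted(
        rng.choice(model_genes, size=min(config.n_dr_planted, len(model_genes)), replace=False)
    )
    planted_set = set(planted)
    tissues = [f"T{t:02d}" for t in range(config.n_tissues)]
    # predictions come from 3 archaics in this product (no Chagyrskaya model)
    archaic_ids = tuple(a for a in config.archaics if a != "ChagyrskayaNea")
    modern: dict[tuple[str, str], np.ndarray] = {}
    archaic: dict[tuple[str, str, str], float] = {}
    signs = {g: (1.0 if rng.random() < 0.5 else -1.0) for g in model_genes}
    for g in model_genes:
        k = int(rng.integers(1, config.max_tissues_per_regulation_gene + 1))
        modeled = rng.choice(tissues, size=k, replace=False)
        for t in sorted(modeled):
            modern[(g, t)] = rng.normal(0.0, 1.0, size=config.n_modern)
            for a in archaic_ids:
                if g in planted_set:
                    archaic[(g, t, a)] = signs[g] * config.dr_z + rng.normal(0, 0.1)
                else:
                    archaic[(g, t, a)] = float(rng.normal(0.0, 1.0))
    truth = pd.DataFrame({"gene": planted, "planted_z": [config.dr_z] * len(planted)})
    return RegulationMatrix(modern=modern, archaic=archaic), truth


# --------------------------------------------------------------------------
# eQTL tuples + introgression maps


def generate_eqtl_and_maps(
    config: SimulationConfig,
    genes: list[GeneModel] | None = None,
    circadian: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, set[str]], pd.DataFrame]:
    """eQTL (variant, gene, tissue) tuples and per-variant map membership.

    Each tuple is circadian with probability ``eqtl_circadian_p``; its
    introgression status follows ``eqtl_introgressed_p`` on the
    noncircadian side with the odds multiplied by ``eqtl_or`` on the
    circadian side. Introgressed variants are always in the Sprime map
    and in each of the five other maps independently with probability
    ``map_concordance``.
    """
    if genes is None or circadian is None:
        genes, circadian, _ = synthetic_gene_annotation(config)
    rng = _rng(config, "eqtl")
    n = config.n_eqtl_tuples
    circ_set = sorted(set(circadian))
    noncirc = sorted({g.gene_id for g in genes} - set(circ_set))
    is_circ = rng.random(n) < config.eqtl_circadian_p
    p_intro_circ = _planted_in_region_p(config.eqtl_or, config.eqtl_introgressed_p)
    is_intro = np.where(
        is_circ,
        rng.random(n) < p_intro_circ,
        rng.random(n) < config.eqtl_introgressed_p,
    )
    gene_col = np.where(
        is_circ,
        np.array(circ_set)[rng.integers(0, len(circ_set), size=n)],
        np.array(noncirc)[rng.integers(0, len(noncirc), size=n)],
    )
    tissue_col = np.array([f"T{t:02d}" for t in rng.integers(0, config.n_tissues, size=n)])
    variant_col = np.array([f"e{i:06d}" for i in range(n)])
    eqtls = pd.DataFrame({"variant": variant_col, "gene": gene_col, "tissue": tissue_col})
    others = [m for m in INTROGRESSION_MAPS if m != SPRIME]
    calls: dict[str, set[str]] = {}
    support = rng.random((n, len(others))) < config.map_concordance
    for i in np.flatnonzero(is_intro):
        maps = {SPRIME} | {m for m, s in zip(others, support[i]) if s}
        calls[variant_col[i]] = maps
    truth = pd.DataFrame(
        {"variant": variant_col, "circadian_truth": is_circ, "introgressed_truth": is_intro}
    )
    return eqtls, calls, truth


# --------------------------------------------------------------------------
# GWAS summary stats, LD, population frequencies


def generate_gwas_and_frequencies(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """LD-blocked chronotype GWAS + population frequency tables.

    Variants are tiled in LD blocks of ``ld_block_size``; the first
    ``n_signif_blocks`` blocks are genome-wide significant with a shared
    effect sign that is morningness-increasing (positive) with
    probability ``morning_bias``. ``n_cline_variants`` significant
    variants get population frequencies linear in latitude with slope
    ``cline_slope`` plus noise; all other variants get
    latitude-independent frequencies.

    Returns (associations, ld_pairs, frequencies, truth).
    """
    rng = _rng(config, "gwas")
    n = config.n_gwas_variants
    block = np.arange(n) // config.ld_block_size
    n_blocks = int(block.max()) + 1
    if config.n_signif_blocks > n_blocks:
        raise ValueError("n_signif_blocks exceeds the number of LD blocks")
    pos = 1_000_000 + np.arange(n) * 10_000
    chrom = np.full(n, "chr2", dtype=object)
    variant = np.array([f"g{i:06d}" for i in range(n)])

    signif_block = block < config.n_signif_blocks
    block_sign = np.where(
        rng.random(n_blocks) < config.morning_bias, 1.0, -1.0
    )
    p_vals = np.where(
        signif_block,
        10.0 ** -(8.0 + 7.0 * rng.random(n)),
        10.0 ** -(rng.random(n) * 6.0),
    )
    # non-significant variants stay above the genome-wide threshold
    p_vals[~signif_block] = np.clip(p_vals[~signif_block], 1e-7, 1.0)
    beta_mag = np.abs(rng.normal(0.0, 0.05, size=n)) + 0.01
    sign = np.where(
        signif_block, block_sign[block], np.where(rng.random(n) < 0.5, 1.0, -1.0)
    )
    beta = beta_mag * sign
    near_circ_block = rng.random(n_blocks) < config.near_circadian_p
    associations = pd.DataFrame(
        {
            "variant": variant,
            "chrom": chrom,
            "pos": pos,
            "beta": beta,
            "p": p_vals,
            "near_circadian": near_circ_block[block],
        }
    )

    ld_rows = []
    for b in range(n_blocks):
        members = np.flatnonzero(block == b)
        for ii in range(len(members)):
            for jj in range(ii + 1, len(members)):
                ld_rows.append(
                    (
                        variant[members[ii]],
                        variant[members[jj]],
                        float(rng.uniform(0.7, 0.95)),
                    )
                )
        if b + 1 < n_blocks:  # weak cross-block LD for adjacent blocks
            a = variant[members[-1]]
            nxt = variant[np.flatnonzero(block == b + 1)[0]]
            ld_rows.append((a, nxt, float(rng.uniform(0.0, 0.2))))
    ld_pairs = pd.DataFrame(ld_rows, columns=["variant_a", "variant_b", "r2"])

    lat = config.latitude_table
    signif_idx = np.flatnonzero(signif_block)
    cline_ids = list(variant[signif_idx[: config.n_cline_variants]])
    freq_rows = []
    base = rng.uniform(0.05, 0.6, size=n)
    for i in range(n):
        for _, row in lat.iterrows():
            if variant[i] in cline_ids:
                f = 0.05 + config.cline_slope * row["latitude"] + rng.normal(
                    0, config.cline_noise
                )
            else:
                f = base[i] + rng.normal(0, 0.02)
            freq_rows.append(
                (variant[i], row["population"], float(np.clip(f, 0.0, 1.0)), row["latitude"])
            )
    frequencies = pd.DataFrame(
        freq_rows, columns=["variant", "population", "frequency", "latitude"]
    )
    truth = pd.DataFrame(
        {
            "variant": variant,
            "block": block,
            "signif_truth": signif_block,
            "sign_truth": sign,
            "near_circadian_truth": near_circ_block[block],
            "cline_truth": [v in cline_ids for v in variant],
        }
    )
    return associations, ld_pairs, frequencies, truth

# --------------------------------------------------------------------------
# gene evidence, trait associations, adaptive regions


def generate_gene_evidence(
    config: SimulationConfig,
    genes: list[GeneModel] | None = None,
    circadian: list[str] | None = None,
) -> pd.DataFrame:
    """Evidence table whose curated gene set is exactly the circadian subset.

    Circadian genes get a source pattern guaranteeing a high or medium
    confidence tier (expert flag, or 2-4 database sources); every other
    gene gets at most one database source and so falls in the excluded
    low tier.
    """
    if genes is None or circadian is None:
        genes, circadian, _ = synthetic_gene_annotation(config)
    rng = _rng(config, "evidence")
    circ = set(circadian)
    db_cols = ["go", "cgdb", "gwas_catalog", "wikipathways"]
    rows = []
    for g in genes:
        flags = dict.fromkeys(["expert", *db_cols], 0)
        if g.gene_id in circ:
            if rng.random() < 0.4:
                flags["expert"] = 1
                for c in db_cols:
                    flags[c] = int(rng.random() < 0.5)
            else:
                k = int(rng.integers(2, 5))
                for c in rng.choice(db_cols, size=k, replace=False):
                    flags[c] = 1
        else:
            if rng.random() < 0.3:  # low-confidence decoys
                flags[str(rng.choice(db_cols))] = 1
            else:
                continue  # no circadian evidence at all -> not in the table
        rows.append({"gene_id": g.gene_id, "symbol": g.symbol, **flags})
    return pd.DataFrame(rows, columns=["gene_id", "symbol", "expert", *db_cols])


def generate_trait_associations(
    config: SimulationConfig,
    variant_ids: list[str],
    assoc_rate: float = 0.05,
    mean_traits: float = 2.0,
) -> pd.DataFrame:
    """Open-Targets-like (variant, trait, p) association table.

    Each variant has at least one genome-wide-significant association
    with probability ``assoc_rate``; associated variants carry a
    zero-truncated Poisson number of distinct traits. No pleiotropy
    signal is planted: both variant partitions draw from the same law.
    """
    rng = _rng(config, "traits")
    rows = []
    for v in variant_ids:
        if rng.random() >= assoc_rate:
            continue
        n_traits = 1 + rng.poisson(mean_traits - 1)
        traits = rng.choice(200, size=min(n_traits, 200), replace=False)
        for t in traits:
            p = 10.0 ** -(8.0 + 6.0 * rng.random())  # genome-wide significant
            rows.append((v, f"trait_{t:03d}", p))
        if rng.random() < 0.5:  # sub-threshold associations also occur
            rows.append((v, f"trait_{int(rng.integers(200, 300)):03d}", 10.0 ** -rng.uniform(1, 7)))
    return pd.DataFrame(rows, columns=["variant", "trait", "p"])


def generate_adaptive_regions(
    config: SimulationConfig,
    genes: list[GeneModel] | None = None,
    circadian: list[str] | None = None,
    n_regions_per_method: int = 8,
) -> pd.DataFrame:
    """Adaptive-introgression candidate regions for the three methods.

    Half of each method's regions cover a circadian gene body, half are
    placed off-gene; scored methods draw scores uniformly so some
    regions fall below their calling threshold.
    """
    if genes is None or circadian is None:
        genes, circadian, _ = synthetic_gene_annotation(config)
    rng = _rng(config, "adaptive")
    circ_genes = [g for g in genes if g.gene_id in set(circadian)]
    rows = []
    for method in ("outlier_stats", "cnn_method", "extra_trees_method"):
        for k in range(n_regions_per_method):
            if k % 2 == 0:
                g = circ_genes[int(rng.integers(0, len(circ_genes)))]
                start = max(0, g.body.start - int(rng.integers(0, 10_000)))
                end = g.body.end + int(rng.integers(0, 10_000))
                chrom = g.body.chrom
            else:
                chrom = f"chr{int(rng.integers(1, 23))}"
                start = int(rng.integers(0, 5_000_000))
                end = start + int(rng.integers(10_000, 50_000))
            score = float(rng.random()) if method != "outlier_stats" else 1.0
            rows.append((method, chrom, start, end, score))
    return pd.DataFrame(rows, columns=["method", "chrom", "start", "end", "score"])
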