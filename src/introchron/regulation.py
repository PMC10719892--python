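"""Divergent regulation (DR) between archaic hominins and modern humans.

Works on matrices of imputed, normalized gene-regulation values (from
pretrained per-tissue prediction models applied to modern-panel and
archaic genotypes; model training is upstream and out of scope). The
core statistic is an empirical divergence p: the fraction of modern
individuals whose predicted regulation is farther from the panel median
than the archaic individual's. A gene/tissue pair is divergently
regulated (DR) in an archaic when that fraction is exactly zero — the
archaic lies strictly outside the whole modern distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import PermutationResult, permutation_enrichment

__all__ = [
    "RegulationMatrix",
    "DivergenceResult",
    "empirical_divergence",
    "percentile_report",
    "dr_sharing",
    "tissue_matched_enrichment",
    "DivergenceSummary",
    "summarize_divergence",
]


@dataclass
class RegulationMatrix:
    """Normalized imputed regulation over modern panel + archaic individuals.

    ``modern`` maps (gene, tissue) to the vector of modern-panel values;
    ``archaic`` maps (gene, tissue, archaic_id) to the single archaic
    value. Only (gene, tissue) pairs present in ``modern`` are modeled.
    """

    modern: dict[tuple[str, str], np.ndarray]
    archaic: dict[tuple[str, str, str], float]

    def __post_init__(self) -> None:
        for key in self.archaic:
            if key[:2] not in self.modern:
                raise ValueError(
                    f"archaic value for unmodeled gene/tissue pair {key[:2]}"
                )

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.modern}

    @property
    def archaic_ids(self) -> set[str]:
        return {a for _, _, a in self.archaic}

    def tissue_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g, _ in self.modern:
            counts[g] = counts.get(g, 0) + 1
        return counts

    def divergence_table(self) -> pd.DataFrame:
        """Empirical divergence for every (gene, tissue, archaic) triple."""
        rows = []
        for (gene, tissue, archaic_id), value in sorted(self.archaic.items()):
            res = empirical_divergence(
                self.modern[(gene, tissue)],
                value,
                gene=gene,
                tissue=tissue,
                archaic_id=archaic_id,
            )
            rows.append(
                {
                    "gene": gene,
                    "tissue": tissue,
                    "archaic_id": archaic_id,
                    "empirical_p": res.empirical_p,
                    "dr": res.dr_flag,
                    "degenerate": res.degenerate,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["gene", "tissue", "archaic_id", "empirical_p", "dr", "degenerate"],
        )

    def dr_calls(self) -> dict[str, set[tuple[str, str]]]:
        """Per-archaic DR (gene, tissue) pairs."""
        table = self.divergence_table()
        out: dict[str, set[tuple[str, str]]] = {a: set() for a in self.archaic_ids}
        for _, row in table[table["dr"]].iterrows():
            out[row["archaic_id"]].add((row["gene"], row["tissue"]))
        return out

    def dr_genes(self) -> dict[str, set[str]]:
        """Per-archaic genes DR in at least one modeled tissue."""
        return {a: {g for g, _ in pairs} for a, pairs in self.dr_calls().items()}

    def to_long_frame(self, modern_prefix: str = "HG") -> pd.DataFrame:
        """Long (individual, panel, gene, tissue, value) frame for serialization."""
        rows = []
        for (gene, tissue), values in sorted(self.modern.items()):
            for i, v in enumerate(values):
                rows.append((f"{modern_prefix}{i:05d}", "modern", gene, tissue, v))
        for (gene, tissue, archaic_id), v in sorted(self.archaic.items()):
            rows.append((archaic_id, "archaic", gene, tissue, v))
        return pd.DataFrame(
            rows, columns=["individual", "panel", "gene", "tissue", "value"]
        )

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "RegulationMatrix":
        modern: dict[tuple[str, str], np.ndarray] = {}
        archaic: dict[tuple[str, str, str], float] = {}
        mod = df[df["panel"] == "modern"]
        for (gene, tissue), sub in mod.groupby(["gene", "tissue"], sort=True):
            ordered = sub.sort_values("individual")
            modern[(str(gene), str(tissue))] = ordered["value"].to_numpy(dtype=float)
        for _, row in df[df["panel"] == "archaic"].iterrows():
            archaic[(str(row["gene"]), str(row["tissue"]), str(row["individual"]))] = float(
                row["value"]
            )
        return cls(modern=modern, archaic=archaic)


@dataclass(frozen=True)
class DivergenceResult:
    """Empirical divergence of one archaic value vs the modern panel."""

    empirical_p: float
    dr_flag: bool
    n_more_extreme: int
    n_humans: int
    archaic_distance: float
    degenerate: bool = False
    gene: str | None = None
    tissue: str | None = None
    archaic_id: str | None = None


def empirical_divergence(
    human_values: Sequence[float],
    archaic_value: float,
    gene: str | None = None,
    tissue: str | None = None,
    archaic_id: str | None = None,
) -> DivergenceResult:
    """Empirical divergence p of an archaic regulation value.

    Distances are measured from the modern-panel median (midpoint
    convention for even N); "more extreme" is strict — a human exactly
    as far from the median as the archaic does not count against it.
    dr_flag is p == 0, except in the degenerate all-equal case where the
    call is suppressed and flagged.
    """
    x = np.asarray(human_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 human values")
    med = float(np.median(x))
    d_archaic = abs(float(archaic_value) - med)
    n_more_extreme = int(np.count_nonzero(np.abs(x - med) > d_archaic))
    empirical_p = n_more_extreme / x.size
    degenerate = d_archaic == 0 and np.all(x == x[0])
    dr_flag = empirical_p == 0.0 and not degenerate
    return DivergenceResult(
        empirical_p=empirical_p,
        dr_flag=dr_flag,
        n_more_extreme=n_more_extreme,
        n_humans=int(x.size),
        archaic_distance=d_archaic,
        degenerate=bool(degenerate),
        gene=gene,
        tissue=tissue,
        archaic_id=archaic_id,
    )


def percentile_report(n_less_extreme: int, n_total: int) -> float:
    """Percentage of the panel below the archaic, to 2 decimals (half-even)."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_less_extreme <= n_total):
        raise ValueError("n_less_extreme must lie in [0, n_total]")
    pct = Decimal(100 * n_less_extreme) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def dr_sharing(
    calls_per_archaic: Mapping[str, Iterable[tuple[str, str]]]
) -> tuple[pd.DataFrame, dict[frozenset, int], dict[frozenset, int]]:
    """Cross-archaic sharing of DR gene/tissue pairs.

    ``calls_per_archaic`` maps archaic id to its DR (gene, tissue) pairs.
    Returns a per-pair table with the exact subset of archaics calling
    each pair DR, plus exact-combination counts at the pair level and at
    the unique-gene level (a gene's combination is the union of archaics
    calling any of its tissues DR).
    """
    sets = {a: set(pairs) for a, pairs in calls_per_archaic.items()}
    all_pairs = sorted(set().union(*sets.values())) if sets else []
    rows = []
    for gene, tissue in all_pairs:
        members = frozenset(a for a, s in sets.items() if (gene, tissue) in s)
        rows.append({"gene": gene, "tissue": tissue, "archaics": members})
    table = pd.DataFrame(rows, columns=["gene", "tissue", "archaics"])
    pair_counts: dict[frozenset, int] = {}
    for members in table["archaics"]:
        pair_counts[members] = pair_counts.get(members, 0) + 1
    gene_members: dict[str, set] = {}
    for _, row in table.iterrows():
        gene_members.setdefault(row["gene"], set()).update(row["archaics"])
    gene_counts: dict[frozenset, int] = {}
    for members in gene_members.values():
        key = frozenset(members)
        gene_counts[key] = gene_counts.get(key, 0) + 1
    return table, pair_counts, gene_counts


def genes_dr_in_all(calls_per_archaic: Mapping[str, Iterable[tuple[str, str]]]) -> set[str]:
    """Genes called DR (in any tissue) by every archaic individual."""
    per_archaic_genes = [
        {gene for gene, _ in pairs} for pairs in calls_per_archaic.values()
    ]
    if not per_archaic_genes:
        return set()
    return set.intersection(*per_archaic_genes)


def tissue_matched_enrichment(
    circadian_genes: Iterable[str],
    universe_tissue_counts: Mapping[str, int],
    dr_genes: Iterable[str],
    n_iter: int = 1_000_000,
    seed: int = 0,
    binning: str = "exact",
    n_quantile_bins: int = 5,
) -> PermutationResult:
    """Permutation enrichment of DR status among circadian genes.

    Each iteration draws a random gene set of the same size as the
    circadian set whose tissue-count histogram matches the circadian
    set's histogram exactly (sampling without replacement within
    tissue-count bins); the statistic is the overlap with the DR set.
    ``binning="exact"`` uses one bin per distinct modeled-tissue count;
    ``"quantile"`` coarsens to ``n_quantile_bins`` quantile bins for
    small universes.
    """
    if binning not in ("exact", "quantile"):
        raise ValueError(f"unknown binning {binning!r}")
    universe = sorted(universe_tissue_counts)
    circ = sorted(set(circadian_genes))
    missing = set(circ) - set(universe)
    if missing:
        raise ValueError(f"circadian genes absent from universe: {sorted(missing)[:5]}")
    counts = np.array([universe_tissue_counts[g] for g in universe], dtype=float)
    if binning == "exact":
        bin_of = counts.astype(np.int64)
    else:
        edges = np.quantile(counts, np.linspace(0, 1, n_quantile_bins + 1)[1:-1])
        bin_of = np.searchsorted(edges, counts, side="right")
    gene_index = {g: i for i, g in enumerate(universe)}
    dr_mask = np.zeros(len(universe), dtype=bool)
    for g in dr_genes:
        if g in gene_index:
            dr_mask[gene_index[g]] = True
    circ_idx = np.array([gene_index[g] for g in circ], dtype=np.int64)
    observed = int(dr_mask[circ_idx].sum())

    # required draw per bin = circadian histogram over that bin
    bin_labels, bin_pos = np.unique(bin_of, return_inverse=True)
    members_per_bin = [np.flatnonzero(bin_pos == i) for i in range(len(bin_labels))]
    need_per_bin = np.bincount(bin_pos[circ_idx], minlength=len(bin_labels))
    for i, need in enumerate(need_per_bin):
        if need > len(members_per_bin[i]):
            raise ValueError(
                f"tissue-count bin {bin_labels[i]!r} has {len(members_per_bin[i])} "
                f"universe genes but the circadian set needs {need}"
            )
    active = [
        (members_per_bin[i], int(need))
        for i, need in enumerate(need_per_bin)
        if need > 0
    ]

    def null_stat(rng: np.random.Generator) -> float:
        overlap = 0
        for members, need in active:
            draw = rng.choice(members, size=need, replace=False)
            overlap += int(dr_mask[draw].sum())
        return overlap

    return permutation_enrichment(observed, null_stat, n_iter=n_iter, seed=seed)


@dataclass(frozen=True)
class DivergenceSummary:
    sav_pct: float
    dr_pct: float
    combined_pct: float


def _pct1(n: int, total: int) -> float:
    pct = Decimal(100 * n) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


def summarize_divergence(
    n_sav_genes: int, n_dr_genes: int, n_total: int
) -> DivergenceSummary:
    """Proportions of circadian genes with splice or regulatory divergence.

    Percentages to 1 decimal; the combined figure is computed from the
    summed counts (assumed disjoint gene sets), not from the rounded
    parts.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if n_sav_genes < 0 or n_dr_genes < 0:
        raise ValueError("counts must be >= 0")
    return DivergenceSummary(
        sav_pct=_pct1(n_sav_genes, n_total),
        dr_pct=_pct1(n_dr_genes, n_total),
        combined_pct=_pct1(n_sav_genes + n_dr_genes, n_total),
    )
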