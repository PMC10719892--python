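# Methods

This note documents the models and conventions behind each stage of the
pipeline, the parameters that matter, what the synthetic-data generators
do and do not emulate, and the numerical choices made where the design
was genuinely open.

## Coordinate model and region annotation

All coordinates are 0-based half-open internally; VCF-style positions
are converted on read (1-based → 0-based) and BED spans are consumed
natively, so a single convention rules out off-by-one drift. A gene is
collapsed to one interval (min start / max end over transcripts) with a
TSS anchor; the TSS is only required to lie within the body span, since
collapsed multi-transcript genes can have interior TSSs.

Promoters are the strand-oriented window from 5,000 bp upstream to
1,000 bp downstream of the TSS, clipped at coordinate 0. Distal
regulatory elements (cCRE-like spans) are assigned to a gene when the
gap between closest interval edges is ≤ 1 Mb (0 if overlapping),
boundary inclusive; one element may flank several genes.

Variants receive exactly one region class under the fixed precedence
**gene_body > promoter > distal_regulatory > none**. The three classes
are reported as disjoint counts, and the precedence makes that
deterministic — a variant inside a circadian gene body counts as
gene_body even when it also sits in a promoter window or a flanking
element. Variants on chromosomes absent from the annotation are classed
`none` and logged. Interval intersection uses an interval tree; a
brute-force linear scan is the test oracle.

## Circadian gene curation

Five evidence sources feed the gene set: an expert-curated list plus
four databases (a GO circadian-rhythm term with its relationship
closure, the Circadian Gene Database, GWAS-catalog chronotype hits, and
a WikiPathways set). Expert membership, or at least three of the four
database sources, gives *high* confidence; exactly two gives *medium*;
one gives *low*, and low-confidence genes are excluded. GO relationship
expansion is treated as input preparation: the evidence file's GO flag
is assumed already resolved. The tier function is monotone (adding a
source never lowers the tier), which the suite checks property-wise.

## Lineage-specific variants

A site must be polarized (known ancestral allele) or it is an error.
"Fixed in the archaic lineage" is read as homozygous derived (dosage 2)
in every archaic individual; heterozygous or missing archaic genotypes
disqualify the site (class `neither`) — upstream coverage/quality
filtering is expected to have happened before input. The rare-frequency
bound for archaic-specific sites (≤ 10⁻⁵) applies per population,
boundary inclusive. Only biallelic sites are processed.

Region enrichment builds, per lineage and region class, the 2×2 of
(fixed vs lineage-derived-non-fixed) × (in-class vs not) and reports the
sample cross-product odds ratio with a two-sided P.

## Statistical kernel conventions

* **Odds ratio** — always the sample cross-product ratio (a·d)/(b·c),
  not the conditional MLE; this is the convention under which the
  published eQTL tuple margins reproduce an OR of 1.45. Zero-margin
  tables are flagged with P = 1; zero cells report OR 0 or ∞ with an
  `or_undefined` flag.
* **Fisher's exact test** — exact hypergeometric P for table totals up
  to 10⁵ (scipy backend; the test suite checks it against a full
  enumeration oracle on totals ≤ 50), a chi-square approximation above
  that, with the method recorded in the result. Extreme P values are
  additionally reported in log10 space so that values far below float
  underflow remain comparable. A companion note: the source protocol
  names both a chi-squared and Fisher's exact test for the eQTL
  analysis; Fisher is this package's default and the large-table
  chi-square path covers the other reading.
* **Mann–Whitney U** — two-sided with tie correction; exact enumeration
  for small tie-free samples, normal approximation otherwise; all-tied
  input is degenerate with P = 1.
* **Permutation framework** — `empirical_p = (1 + #{null ≥ observed}) /
  (n_iter + 1)`. The plus-one convention deviates from the naive ratio
  by O(1/n_iter) and guarantees a nonzero P; enrichment is
  observed/mean(null), undefined (flagged) when the null mean is 0.
  Results are a pure function of the seed.
* **Bonferroni** — α/m at full precision plus a 3-significant-figure
  form (0.05/49 → 0.00102).

## Splice divergence

The per-variant `max_delta` is the maximum of the four splice-delta
scores computed upstream; this package never runs the predictor. A SAV
requires `max_delta > 0.2` (strict) *and* absence from the modern panel.
Sharing classes over the four archaic carriers (three Neanderthals + one
Denisovan): all four → `all_shared`; exactly the Neanderthals →
`Neanderthal_shared`; singletons → the matching `_private` class;
anything else → `other`. These classes partition the call set.

The shuffle null permutes the delta column across the variant table
while gene assignments and archaic-specific flags stay fixed, preserving
per-gene variant counts and the delta multiset (assertable in a debug
mode). Whether the shuffle ranges over all variants or only
archaic-specific ones is a switch; the default is all variants, matching
the scale at which the null was originally defined. A tag-SNP flag
supports the tag-SNP subset analysis.

## Regulation divergence

Inputs are normalized imputed-regulation values from pretrained
per-tissue models applied to the modern panel and to three archaic
individuals (Altai, Vindija, Denisovan — no models exist for the
Chagyrskaya Neanderthal); model training and imputation are out of
scope. The empirical divergence P counts modern individuals *strictly*
farther from the panel median than the archaic value; ties count as
not-more-extreme. DR ⇔ P = 0, i.e. the archaic is more extreme than
every human — the strictness makes these two readings coincide. The
median uses the midpoint convention for even N. The degenerate all-equal
case (P = 0 but no divergence) is flagged and the DR call suppressed. A
gene is DR when any modeled tissue is DR.

The tissue-matched permutation draws random gene sets of the circadian
set's size whose modeled-tissue-count histogram matches the circadian
set's exactly (sampling without replacement within tissue-count bins;
one bin per distinct count, with a quantile-binning option for small
universes); the statistic is the overlap with the DR gene set.

Percentile reports and proportion summaries round half-even to 2 and 1
decimals respectively; combined proportions are computed from summed
counts, not from rounded parts.

## Introgression function

Consensus sets from per-variant map membership: `base` = Sprime members;
`base_plus_one` = Sprime plus ≥ 1 of the five other maps; `all_maps` =
supported by all six. The containment chain all_maps ⊆ base_plus_one ⊆
base is a tested invariant.

eQTL enrichment counts (variant, gene, tissue) tuples — the unit at
which tissue-resolved eQTL catalogs report associations and the unit
under which the published margins reproduce OR 1.45; variant-level
counting is available behind a flag. Per-tissue results carry a
three-tier significance label (ns / nominal at 0.05 / corrected at
0.05/49); a tissue with no circadian introgressed tuples is still
emitted, flagged. Pleiotropy uses genome-wide significance P ≤ 5×10⁻⁸
(inclusive): Fisher on (circadian vs non-circadian) × (any association
vs none), Mann–Whitney on unique-trait counts among associated variants.

## Chronotype and geography

LD clumping is greedy: the unassigned variant with the smallest P (ties
by chromosome, then position) becomes an index and absorbs unassigned
variants within the window (default ±250 kb, the conventional clumping
default) at R² > 0.5 (strict). Missing LD entries are treated as R² = 0
and logged. Clumps partition the input.

The morningness sign convention is explicit configuration: with the
morning phenotype coded as the positive GWAS outcome, positive beta on
the effect allele increases morningness. The cumulative curve at rank k
is the fraction of the k smallest-P index effects that increase
morningness; at the last rank it equals the overall fraction
(telescoping identity, tested).

Latitudinal clines regress frequency on latitude per variant and pass at
|R| ≥ 0.65 and P ≤ p_max. The default p_max is 0.5 as quoted in the
source protocol; this is almost certainly a typo for the conventional
0.05, so it is implemented as quoted but exposed prominently as
configuration rather than silently corrected. Population latitudes ship
with the package (diaspora populations anchored to ancestral locales,
CEU to Amsterdam).

Adaptive-introgression support: a variant supports a (gene, method) pair
when it falls in a region meeting the method's threshold ("meets" = ≥;
CNN 0.5, extra-trees 0.9, both configurable per method since the
original attribution of the two values is ambiguous; the outlier-
statistics method publishes unscored candidate regions, all of which
count).

## Synthetic data

The generators emulate the statistical structure of the study inputs at
study-scale panel composition (2,504 modern individuals across 10
Eurasian populations with real latitudes, 4 named archaics, 246
circadian genes among 2,000, 49 tissues) and ~1/100 genome scale for
variant-level products (40,000 panel sites, 16,000 splice records,
100,000 eQTL tuples by default) so the full pipeline runs in minutes.
One global seed fans out into independent, stably-keyed substreams per
product, so outputs are byte-identical across reruns and insensitive to
which generators are invoked; truth labels are always emitted.

Plantable parameters and their defaults: lineage-region OR 1 (null),
fractions of human-/archaic-specific sites 0.2%/0.75% (the study-scale
rates), SAV circadian excess 1, DR offsets off (z = 6 when planted),
eQTL OR 1 over circadian rate 2.1% and introgression rate 2.8% (the
study's tuple-level marginals), map concordance 0.6, morningness bias
0.5, cline slope 0.004/degree with σ = 0.01 noise. Planted odds ratios
are realized exactly in odds space; background panel variants are
rejection-sampled strictly outside circadian gene bodies so the planted
in-region OR is exact in annotation terms rather than diluted by chance
overlaps.

What the generators do *not* emulate: coalescent/demographic structure,
LD between panel sites, allele-frequency spectra under drift or
selection, shared variants across data products, or realistic gene
lengths and clustering. Passing recovery tests therefore demonstrates
that each statistic recovers what was planted under its own sampling
assumptions — not that the pipeline is robust to the correlation
structure of real genomes.

## Numerical choices and degenerate inputs

Tie-breaks and degeneracies are stated in their home sections above; in
addition: empty inputs yield empty outputs (not errors) wherever a
stage can meaningfully be empty (flanking maps, direction curves);
zero-length intervals contain no position; constant-frequency cline
input is a degenerate fail with a flag; writers use repr-stable float
formatting (`%.10g`) so determinism is byte-level.

## Problem sizes used in checks

The test suite runs recovery suites at 50 seeds each (pooled 2×2 tables
for the lineage OR; 100,000-tuple tables for the eQTL OR; panel size
2,504 for DR recall). The acceptance script uses 20 replicates per
statistic, a size at which every recovered value is stable to well
within the asserted bands across seeds. The tissue-matched permutation
defaults to 10⁶ iterations in configuration, matching the analysis
protocol; tests and the acceptance script pass smaller iteration counts
explicitly.

## Known limitations

* No liftOver, isoform modeling, genotype calling, LD computation from
  genotypes, or retrieval from external association databases; all such
  steps are upstream input preparation.
* Multi-allelic sites are skipped (logged), matching the biallelic
  restriction of the classification rules.
* The large-table chi-square path of the Fisher interface is an
  approximation; its P can differ from an exact computation in the far
  tail (the OR is unaffected).
* Gene-level DR calls depend on the "any modeled tissue" rule; analyses
  that need tissue-specific DR should consume the per-pair table.
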