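# Methods

This note documents the models, parameter choices and numerical
conventions behind `organgrn`, and what the synthetic-data validation
does and does not establish.

## Coordinates and gene models

All internal coordinates are 0-based, half-open (BED semantics); GFF3
(1-based inclusive) is converted at the I/O boundary, and the round trip
is the identity. Gene models are gene-span level: the TSS is the
strand-aware 5′ end of the annotated span, and no exon arithmetic is
performed — gene lengths for TPM/FPKM come from an explicit length
column, because counts are assumed pre-summarised to gene level.

Gene-model merging is coordinate-conditional: a secondary gene is added
only if its span shares no base with any primary span on the same
contig, strand-ignorant. Strand-ignorant overlap is the conservative
reading — it avoids admitting a second annotation of the same locus on
the opposite strand. Merging is idempotent by construction.

Closest-gene assignment uses edge-to-edge distance (0 for any overlap;
abutting features have distance 0) and returns **all** tied genes, so no
candidate target is lost to an arbitrary tie-break. The TSS-window
assignment mode instead requires the interval midpoint to fall within a
strand-oriented window around the TSS, −2000 bp upstream to +500 bp
downstream by default — the convention used when assigning in-vitro
TF-binding peaks to genes.

Promoters are the 2 kb upstream of the TSS, truncated at contig
boundaries, reverse-complemented for minus-strand genes so that the last
base always abuts the TSS. Promoters shorter than 50 bases are excluded
from motif scanning (a scan window must fit with margin); zero-length
promoters are dropped with a warning.

## Expression filters

TPM divides each count by gene length, then normalises each sample to
1e6 (columns of the output sum to 1e6 exactly, up to float error, except
all-zero samples, which stay zero with a warning). FPKM is
1e9·count/(length·library size). No between-sample normalisation (TMM,
quantile) is applied — the inference step uses rank-based trees and the
co-expression step uses correlations, both insensitive to monotone
per-sample scaling.

A gene is *expressed* in an organ when it reaches ≥ 5 TPM in at least
10% of that organ's samples. The 10% is per organ and uses ceiling
rounding (10% of 14 samples → 2), so "at least 10%" is literal for small
organs. Row z-scores use the population (n) standard deviation —
display semantics for heatmaps — and constant rows map to zero with a
warning.

## Network inference

For each target gene, the unit-variance-scaled expression profile is
regressed on all TF profiles (the target's own profile excluded when the
target is itself a TF) by a random forest: 2000 trees by default,
bootstrap resampling, and ⌈√p⌉ randomly drawn candidate predictors per
split (`k_rule="all"` is exposed for comparison). The weight of TF→g is
the mean over trees of the total variance reduction attributed to that
TF's splits, **not** normalised per tree — with a unit-variance response
these weights sum to roughly the fraction of variance the forest
explains, making them comparable across targets; a sanity band of
[0.5, 1.5] on the per-target weight sum is asserted on simulated data.
Raw counts are accepted directly as input (tree ensembles are invariant
to monotone per-feature transforms); TPM or any abundance unit works
equally.

Determinism: a single global seed derives one independent seed per
target (seed + CRC32 of the gene id, mod 2³¹), so results are identical
regardless of target scheduling and a single-target re-run reproduces
the corresponding rows of a full run. The global edge ordering breaks
weight ties by (regulator id, target id). Thresholding keeps the first
⌈k/100·N⌉ records of that deterministic order.

Constant-expression targets are skipped with a warning; constant genes
remain usable as (uninformative) predictors.

## Co-expression aggregation

Per study, genes below 0.5 FPKM in every sample of the study are
removed, Pearson correlations are computed, and each gene's partners are
ranked 1..n−1 by descending correlation (ties broken by partner id so
ranks are a deterministic permutation). HRR(A,B) = max(rank(A,B),
rank(B,A)); a pair is retained when either directed rank is within the
top 1% of that gene's ranks (cutoff ⌈0.01·(n−1)⌉, minimum 1 — per-gene,
which keeps the cut scale-free). Aggregation counts, per pair, the
number of studies retaining it; the noise filter then keeps a pair if
its frequency reaches the top-1% frequency threshold of **either**
endpoint (OR semantics — AND would asymmetrically discard pairs adjacent
to hubs), with ≥ at the quantile boundary. Directed TF→target evidence
pairs are expanded from the undirected network; TF–TF pairs contribute
both directions.

## Motif scanning and exact p-values

PFMs become log₂-odds PWMs with probability
(count + pseudocount·bg)/(total + pseudocount), pseudocount 0.01,
uniform background by default (estimable from the scanned set). All
scoring happens on an ε-discretised lattice (ε = 1e-3 bits): the exact
null distribution of the W-mer score under the background is computed by
dynamic programming over this lattice, and scanning, thresholds and
reported hit p-values use the same lattice, so they are mutually
consistent and exact. `score_pvalue` for arbitrary float scores applies
a conservative half-width guard band (any word whose true score exceeds
the query maps above the guarded index). Both strands are scanned;
windows containing N are skipped rather than scored with background
odds, avoiding threshold-sensitive artifacts at masked bases. The
default hit threshold is p ≤ 1e-4 (the common motif-scanner default;
configurable). Note that a motif of width W cannot produce hits when
4⁻ᵂ exceeds the threshold (W ≤ 6 at 1e-4).

Multiple motifs of one TF are OR-combined into a single boolean evidence
pair per (TF, gene).

## Evidence overlay

The inferred topology is fixed: co-expression, promoter-motif and
open-chromatin-motif pairs are mapped onto existing edges as boolean
flags (evidence count 1–4), never adding or removing edges — asserted as
an invariant. Summaries report the evidence-count histogram, per-layer
support rates, and the cross-organ edge-overlap distribution.

## Benchmarking

Gold standards union per-TF target sets across experiments and keep TFs
with strictly more than `min_targets` targets (1000 at compendium scale;
scaled down in simulations via the configuration). Fisher tests are
two-sided exact (direction is carried by the log₂ odds ratio), with a
Haldane–Anscombe 0.5 correction when a cell is zero; BH adjustment is
applied across whatever batch one call supplies. The universe for
edge-level tests is {shared TFs} × {genes present in both networks},
mirroring the shared-regulator restriction applied to AUROC/AUPR; this
choice is recorded in every report. Overlap percentages round
half-away-from-zero.

AUROC is the Mann–Whitney rank statistic (tied weights contribute ½);
AUPR integrates the precision–recall sweep stepwise with tied weights
processed as one block. Both are cross-checked in the tests against
brute-force pair counting and (for AUPR without ties) average precision.
The permutation null shuffles edge weights over the fixed edge set;
observed metrics are called significant above the 97.5th null
percentile, with percentile-based 2.5–97.5 bands reported. Fewer than 20
permutations triggers an instability warning.

## Hubs, conservation, enrichment

IVI components on the directed graph: degree centrality (in + out),
neighborhood connectivity (mean undirected-neighbor degree),
betweenness, ClusterRank 10^(−cc)·Σ_out-neighbors(out-degree + 1), and
collective influence (k−1)·Σ_{distance ℓ}(k−1) with ℓ = 2 on the
undirected projection. Each component is min–max normalised (a constant
component contributes zero); hubness = DC′+NC′, spreading = BC′+CR′+CI′,
and IVI = 1 + 99·minmax(hubness × spreading) ∈ [1, 100]. The component
definitions mix directed fan-out (ClusterRank) with undirected
path/ball quantities (betweenness, collective influence) because
regulatory reach is directional while influence propagation in the
underlying contact structure is not; the five components are exposed in
the output table so alternative combinations can be evaluated. The
combination formula is this package's construction — the component list
is standard, but published combinations differ in normalisation details.

Target conservation of a TF present in ≥ 2 organ networks is
100·|intersection of its target sets| / |union|: the union denominator
is the only one for which 100% is equivalent to identical sets. TFs in a
single organ are reported with undefined conservation and excluded from
the ordinary-least-squares fit of conservation on mean out-degree.

Over-representation uses the upper-tail hypergeometric p for each
annotation term with at least one hit in the gene set, BH-adjusted
across tested terms, flagged at adjusted p < 0.05.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not tomato biology:

- **Truth network.** Out-degrees are log-normal (σ = 0.5) with mean
  `mean_outdegree` (default 8), giving a heavy-tailed hub structure;
  targets are drawn uniformly among non-TF genes, so the response model
  is acyclic and every edge is expressed in the data. Effect sizes are
  signed, with |effect| ≥ 0.5 + |N(0, effect_sd)| — bounded away from
  zero because an edge whose effect is ≈ 0 would be a truth label
  without an actual dependency. A configurable share of edges (default
  25%, mirroring predominantly organ-specific regulation) is active in
  all organs; the rest are active in exactly one.
- **Expression.** TF profiles are log-normal(0, 1) per sample. A
  regulated target is softplus(basal + Σ effect·TF) + N(0, noise_sd).
  The basal drive (default 3.0) keeps repression inside the responsive
  region of the softplus: without it, any net-repressed target saturates
  at zero and repressive edges leave no statistical trace, making the
  ground truth unfaithful. A regulated gene whose regulators are all
  inactive in an organ is silent there apart from leaky noise, so
  organ-specific targets drop out of that organ's expressed set.
  Unregulated genes carry independent log-normal baseline variation. Samples are split into study blocks
  with per-study, per-gene log-normal scale factors (σ = 0.2), giving
  the cross-study aggregation genuine heterogeneity. Counts are
  gamma-Poisson (negative binomial) with a single global dispersion
  (0.1) and mean proportional to abundance × gene length.
- **Sequence layer.** Synthetic PFMs have one dominant base per column
  (~1.5 bits), widths 8–12 — wide enough that a perfect site clears
  p ≤ 1e-4. For each true edge, with probability q (default 0.8) the
  regulator's best word is written at a uniform position and strand of
  the target promoter; promoters are i.i.d. background otherwise. A
  one-contig genome lays out [spacer][promoter][gene body] per gene so
  promoter extraction from the genome reproduces the planted promoters;
  open-chromatin intervals cover each planted site with probability
  `ocs_cover_rate` (default 0.6).
- **Gold standards.** Each organ-active true edge is kept with
  probability `gold_sensitivity` (default 0.9); false pairs are added at
  `gold_fp_rate` (default 0.1) of the kept count; TFs must exceed
  `gold_min_targets` (default 5, the compendium-scale rule scaled down).

Everything is bit-reproducible under a fixed seed (every stage derives
its stream from seed + a stage label) and differs across seeds.

**What passing tests show — and do not.** Recovery of this generator's
truth (AUROC ≥ 0.85 at 20 TFs / 100 genes / 200 samples / noise 0.1 /
raw counts) demonstrates that the inference, thresholding, evidence and
benchmarking machinery is correct and sensitive under a known monotone
dependency structure with study heterogeneity and count noise. It does
not demonstrate performance on real compendia, where regulation is
combinatorial and confounded, effect structure is unknown, and gold
standards are biased samples; the generator has no batch effects beyond
study scale factors, no shared co-factors, and no indirect-edge
structure beyond what the acyclic truth induces.

## Problem sizes and runtime choices

The validation suite runs the full recovery scenario at 20 TFs, 100
genes and 200 samples with 500 trees (weights are slightly noisier than
at the 2000-tree default but the ranking statistics are stable), and
smaller fixtures (8 TFs, 40 genes, 60 samples, 30–100 trees) for
contract, determinism and invariance checks. The permutation null uses
200–500 shuffles in tests and the acceptance script; 1000 remains the
library default.

## Degenerate inputs and tie-breaks (summary)

- Constant genes: dropped from correlation ranking and from inference
  responses, with warnings.
- All-zero samples: zero TPM/FPKM columns, with warnings.
- Equal edge weights: ordered by (regulator, target) ids.
- Equal correlations: partner-id tie-break before ranking.
- Equidistant genes in closest-assignment: all returned.
- Empty gold standards or degenerate label sets: explicit errors naming
  the condition.
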