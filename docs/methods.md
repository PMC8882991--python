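# Methods

This note documents the models, procedures, parameter choices and known
limitations of `farmnet`. The package analyses ASV count tables from a
multi-niche farm design — seven niches (bulk soil, ryegrass and white
clover roots and leaves, rumen, faeces), three soil-nitrogen treatments
(0 / 150 / 300 kg N ha⁻¹ yr⁻¹) and three amplicon subpopulations (16S,
18S, ITS) — and ships a ground-truthed generator for that design.

## Preprocessing

**Rarefaction.** Each sample is subsampled *without replacement* to an
even depth D (multivariate hypergeometric draw), so every retained row
sums exactly to D and no per-ASV count can increase. Samples with fewer
than D reads are dropped and logged, never up-sampled. The seed is an
explicit argument; there is no hidden global RNG state. Reference depths
for real libraries are 10000 / 25000 / 10000 reads (16S / 18S / ITS); the
synthetic preset uses 1000 (see *Problem sizes*).

**Singletons** are ASVs whose total count across all samples of the
current table is ≤ 1 — the dataset-total convention common in
phyloseq-style workflows. The order of operations is rarefy → remove
singletons (configurable); with the other order a singleton definition on
raw counts would refer to library sizes the analysis never sees again.

**Chloroplast removal** is a case-insensitive lineage substring match,
applied by default to 16S tables only (chloroplast 16S reads are plant
contamination; 18S/ITS assignments do not carry the same artefact).

## Community statistics

**Kruskal–Wallis** uses average ranks and the standard tie correction
`1 − Σ(t³−t)/(n³−n)`; the p-value comes from the χ² approximation with
g−1 degrees of freedom. Across the per-niche treatment panels the
p-values are BH-adjusted (configurable).

**Bray–Curtis** is computed through the L1 identity
`Σ min(x,y) = (Σx + Σy − Σ|x−y|)/2`, giving values in [0,1]; zero-sum
samples are rejected by name.

**NMDS** minimises Kruskal stress-1
`sqrt(Σ(d̂−d*)² / Σd̂²)` by alternating isotonic regression (PAVA) of the
embedded distances on the dissimilarity order with a Guttman-transform
update. The first start is the classical-scaling (PCoA) configuration —
in practice this start nearly always wins and makes results stable —
followed by random starts (default 20, k=2, tol 1e-7 on stress change,
max 300 iterations). Non-convergence is reported as a flag, not an
exception, and the per-iteration stress trace is kept on the result.

**ANOSIM / PERMANOVA** are rank- and squared-dissimilarity-based
one-factor tests with label-permutation p-values using the add-one
estimator `(b+1)/(m+1)` and 999 permutations by default. For n ≤ 10 an
exhaustive mode enumerates every distinct label arrangement and returns
the exact permutation p-value. The PERMANOVA partition satisfies
`SS_between + SS_within = SS_total` to numerical precision; with zero
within-group dissimilarity pseudo-F is reported as infinity.

## Differential abundance

Rarefaction leaves all libraries at the same size, so TMM-style
normalisation is unnecessary and treatment groups can be compared through
their summed counts: a sum of n i.i.d. NB(μ, φ) variables is
NB(nμ, φ/n). The test conditions on the two-group total s and computes
the two-sided p-value by probability-mass ordering — the sum of the
conditional probabilities of every split of s no more probable than the
observed one. At φ = 0 this reduces exactly to the two-sided binomial
test with success probability n_A/(n_A+n_B). log₂ fold changes shrink
both group means by a prior count (default 0.5) to avoid infinities when
one group is all zeros.

The common dispersion φ (variance = μ + φμ²) is a 20 %-trimmed mean of
per-ASV method-of-moments estimates `max(0, (s² − x̄)/x̄²)` computed
within groups and averaged. This deliberately replaces the
quantile-adjusted conditional maximum likelihood machinery of count-table
packages: with equal library sizes the simple pooled estimator is
adequate, validated here by simulation (Poisson data yield φ̂ < 0.05;
planted φ = 0.4 is recovered within [0.25, 0.55]); exact agreement with
any specific external implementation is not a goal. The conditional test
is conservative, not anti-conservative: over 2000 simulated null ASVs the
rejection rate at α = 0.05 is ≈ 0.04–0.05.

An ASV is **N-responsive** when |log₂FC| ≥ 2 (boundary inclusive) and the
BH-adjusted p (family = all ASVs of one niche × contrast) is < 0.05.
Contrasts are N0 vs N150 and N0 vs N300; the study-wide N-responsive set
is the union over niches and contrasts. ASVs with zero total count in
both groups are excluded and counted.

A structural note on threshold-boundary effects: when a planted effect is
exactly four-fold, its true log₂ fold change equals the calling threshold
2, so any unbiased estimator lands above the threshold only about half
the time — the sensitivity of the joint rule is capped near 0.5
regardless of sample size, and slightly below it with prior-count
shrinkage. Effects clear of the boundary (e.g. six-fold) are recovered
with high sensitivity; a dedicated test demonstrates both behaviours.

## Co-occurrence networks

Per niche, the candidate pool keeps ASVs that (1) are present in at least
60 % of the niche's samples (evaluated within the niche across all
treatments; boundary inclusive) and (2) are N-responsive anywhere in the
study or among the top 200 ASVs by total count over the whole
amplicon-level table. Per niche × treatment context, tie-aware Spearman
correlations (average ranks, then Pearson) are computed for all pool
pairs; two-sided p-values use the t approximation
`t = r·sqrt((n−2)/(1−r²))`, with perfectly monotone pairs snapped to
r = ±1 and p = 0. Edges require |r| ≥ 0.8 **and** p ≤ 0.05 (raw p by
default; BH mode available). Nodes are exactly the endpoints of surviving
edges; an empty edge list is a valid empty network with edges-per-node
defined as 0. Contexts with fewer than `min_n = 4` samples yield a logged
empty network: below four paired observations the t approximation is
meaningless.

Small contexts deserve a warning that the package makes loudly: with 3–4
samples, the joint threshold admits only tie-free, perfectly concordant
pairs, which occur by chance at a rate of about 1/12 per pair. Networks
built on such contexts therefore carry a substantial chance-edge
background, and their absolute edge counts should not be
over-interpreted; contrasts between treatments of the same niche (same
pool, same n) remain meaningful.

Layouts use seeded Fruchterman–Reingold (networkx `spring_layout`) and
are for export only — no statistic depends on coordinates.

## Occupancy–frequency analysis

The occupancy of an ASV in a niche is the number of samples where it has
a positive count; the curve maps each occupancy level k to the number of
ASVs at exactly k. The **core–satellite classification** is an
operational heuristic of this package (the pattern has no canonical
test): a curve is `core_satellite` when the satellite mode at k = 1 is
the global maximum and the maximum over the core bins (k ≥ 0.9·n) reaches
at least twice the interior minimum (floored at one ASV, so an empty
interior bin cannot promote an arbitrary core count); a satellite peak
with no core mode is `satellite_only`; an everywhere-equal curve is
`uniform`; anything else `indeterminate`. Both factors are configurable
and the full decision trace is returned.

## Synthetic communities

The generator emulates the study design so that every stage can be scored
without any sequencing data. Defaults mirror the study: per-niche sample
counts 52 (rumen), 62 (faecal), 11 (soil), 12/9 (ryegrass root/leaf),
11/12 (clover root/leaf), split as evenly as possible over three
treatments; three amplicon-like tables are generated independently.

**Marginals and correlation.** Per niche, base ASV means are log-normal
(μ_log, σ_log, defaults 1.0 and 1.5); counts are NB quantiles (dispersion
φ, default 0.3) of a Gaussian copula, so marginals are exactly NB while
within-block latent correlation is `ρ_block · γ(treatment)`. Blocks are
equicorrelated via a shared factor; overlapping blocks in one niche are
rejected. Copula rank correlation follows
`ρ_s ≈ (6/π)·asin(ρ/2)` for continuous marginals; NB discreteness
attenuates this slightly (negligible for means ≥ 20), and binomial
thinning by rarefaction attenuates it further — both effects are
accepted and sized in the tests. The ground-truth edge set for a context
lists exactly the within-block pairs whose post-attenuation expected
Spearman clears the declared detectability bound (default 0.8, aligned
with the edge threshold).

Three deliberate design choices depart from the most naive formulation,
all to keep planted signals orthogonal:

1. **Treatment-balanced presence.** Occupancy structure is a property of
   a niche, not a treatment: each ASV's number of occupied samples is
   drawn once per niche and spread as evenly as possible across
   treatments (random within a treatment). Fully independent per-sample
   zeroing would routinely fabricate treatment-level abundance shifts in
   the 3–4-sample niches and contaminate the differential-abundance
   stage with effects nobody planted.
2. **Centred block factors.** The copula's shared factor is centred
   within each treatment group, so planted *correlation* does not
   double as a planted group-mean *shift*. The within-group pairwise
   correlation changes only from ρ to ρ(1−1/m)/(1−ρ/m) (≈ 0.947 for
   ρ = 0.96, m = 4), which stays above the detectability bound.
3. **Abundance–occupancy coupling.** Presence probability is floored for
   abundant taxa (ramp from mean 6 to 15 toward presence 0.85),
   reflecting the ubiquitous positive abundance–occupancy relationship;
   without it, a high-count taxon occupying one sample of one treatment
   mimics a strong treatment response.

**Occupancy modes.** In `core_satellite` mode ASVs are classed by
abundance rank: 88 % satellites with Beta(0.3, 6.0) presence (right-
skewed, modal occupancy 1), a middle class at presence 0.9–1.0, and a 5 %
always-present core with means floored at 50. In `flat` mode all ASVs
share presence 0.5 over a narrow abundance distribution, which produces
an interior occupancy mode and should *not* classify as core–satellite.

**Library sizes** are intentionally unequal (log-normal factor,
σ = 0.3) and the generator never pre-equalises depths — the pipeline's
rarefaction stage does real work on synthetic data. Rarefaction of a
sample whose reads are dominated by a strongly co-fluctuating block
partially cancels that co-fluctuation (compositional closure); the
study-mimic preset compensates with larger blocks rather than pretending
the effect away.

**Study-mimic preset.** `preset_study_mimic()` plants the qualitative
phenomena the pipeline should expose end-to-end: three 16-ASV bulk-soil
blocks (ρ = 0.96) fully attenuated under both nitrogen treatments
(γ_N150 = γ_N300 = 0) — the soil-network collapse; treatment-varying
animal-niche blocks (faecal densest under medium nitrogen); weak stable
plant-niche blocks (ρ = 0.5, below the edge threshold); and 40
differential ASVs planted only in rumen and faeces (six-fold up or
down). Block taxa get an abundance floor of 150 so they stay inside the
study-wide top-200 pool criterion and remain tie-free at the soil
niche's small n after rarefaction; preset abundances (μ_log = 1.6,
library σ = 0.25) put library sizes at ~2500–4000 reads so a depth-1000
rarefaction subsamples every sample instead of discarding the small
niches.

## Problem sizes and determinism

Synthetic analyses run at desk scale: 169 samples per amplicon, ~420
ASVs, rarefaction depth 1000, 199–999 permutations. These sizes keep a
full three-amplicon pipeline run under a few seconds while leaving every
statistic in its intended regime. A single pipeline seed derives
per-stage seeds by SHA-256 hashing of the stage name, so any stage can be
reproduced in isolation; reruns with the same config and seed are
byte-identical, verified via the SHA-256 output manifest in the run
report.

## What passing tests do and do not show

The generator produces NB counts with planted, *block-structured* rank
correlation and clean niche separation. Real amplicon data add
compositional closure at the sequencing step, taxon-specific dispersion,
phylogenetic correlation, batch effects and contamination — none of which
are modelled. Passing recovery tests therefore demonstrates that the
pipeline's statistics are implemented correctly and respond to planted
signal as designed, not that the thresholds used here are optimal for any
particular real dataset. The correlation-network stage in particular
inherits the known fragility of threshold-based co-occurrence inference
at small sample sizes, which the package reports rather than hides.
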