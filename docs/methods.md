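# Methods

This note documents the models behind `xomap`, the defaults and why they
were chosen, what the simulator does and does not emulate, and the
numerical decisions a maintainer would want recorded.

## Coordinate conventions

All in-memory coordinates are 0-based half-open. Serialized tables
(genotype matrices, marker tables, CO tables) are 1-based inclusive, the
common convention for genomics TSVs; BED input is 0-based half-open per its
standard. Converting out and back is the identity, and the round trip is
tested.

## Crossover calling

A BC1 genotype at an informative marker takes one of two legal states —
homozygous for the recurrent parent (HOM) or heterozygous (HET) — plus
missing. Markers are informative exactly when both parents are homozygous
for different alleles; heterozygous, missing, or identically homozygous
parental sites are dropped.

**Window smoothing.** Windows of `window_size` (default 50 kb) advance by
`step_size` (default 25 kb) from position 0; the number of windows is
`floor((L − window)/step) + 1`. A window is assigned the strict-majority
state of its non-missing calls when at least `min_markers_per_window`
(default 2) are present; ties and thin windows stay unassigned. The
majority rule makes single miscalled markers invisible to the caller while
staying conservative near data gaps.

**Breakpoints.** Unassigned windows are bridged: only transitions between
consecutive *assigned* states produce a CO. The event is bounded by the
last marker supporting the left state before the transition and the first
marker supporting the right state at or after the start of the right-hand
window run; the integer midpoint of these bounds is the event position used
by all downstream statistics. Marker-level bounds are the tightest
defensible interval; window edges would inflate the uncertainty by up to a
full window.

**Double-CO support rule.** The genotype segment between two consecutive
COs must span at least `min_double_co_support` (default 500 kb), measured
between midpoints. A shorter internal segment is treated as an artifact
(e.g. a clustered run of genotyping errors surviving the majority rule) and
*both* flanking COs are removed. Removal iterates from the shortest
offending segment so the outcome is independent of scan order, and the
filter is idempotent and monotone in the threshold (property-tested).
Terminal segments are exempt — a single CO near a chromosome end is not a
double CO. Whether one or both events should be removed is not externally
constrained; removing both is the conservative choice because a short
interstitial segment leaves no evidence for either exchange.

## Simulator

The simulator models the diploid-like bivalent case the caller assumes: one
bivalent per chromosome, no multivalents, no homoeologous exchange, no
meiotic drive, no aneuploidy.

**Placement models.** Poisson: CO count ~ Poisson(λ_c), positions i.i.d.
uniform. Gamma: a renewal process on the physical axis with shape ν and
scale L/(ν·λ_c), started at stationarity — the first event's delay is
U·X̃ with U ~ Uniform(0,1) and X̃ the length-biased gap, which for a
gamma(ν) gap is gamma(ν+1). The equilibrium start removes edge bias, so the
expected count is exactly λ_c for every ν, and ν = 1 reduces to the Poisson
process (verified by a χ² goodness-of-fit test at 50,000 draws). Interarrival
regularity grows with ν: the inter-CO distance coefficient of variation is
1 at ν = 1 (exponential) and decreases with ν (tested).

`obligate_co` redraws zero-CO outcomes so every bivalent has at least one
CO; it is off by default because λ_c = 2 already makes zero-CO bivalents
uncommon and the obligate-CO mechanism is biologically distinct from simple
conditioning. Two COs falling in the same or adjacent base pair after
integer flooring are redrawn (physically meaningless; probability ~1e-7
per meiocyte).

**Chromatids and thinning.** Each CO is independently assigned one
chromatid of each homolog, uniformly (no chromatid interference). A gamete
takes one of the four chromatids uniformly per chromosome and inherits
exactly the COs whose pair includes it — each CO with probability 1/2 —
so the per-gamete mean CO count is half the per-meiocyte mean for every
placement model. This thinning contract is tested at 100,000 meiocytes.
Note the thinning also dilutes interference: gamete-level CoC under a
gamma(ν) bivalent process is attenuated relative to the bivalent-level
process, but remains far below 1 at short distances for ν ≥ 5.

**Genetic-to-physical map.** Proportional by default. A per-chromosome
rate-map hook (`rate_map`, bin edges + multipliers) warps positions from
the uniform genetic axis by inverse-CDF interpolation for users who want
recombination-rate heterogeneity; it defaults to off and is not used by any
shipped analysis.

**Genotype emission.** Markers on parent-2 ancestry are HET, on parent-1
ancestry HOM (backcross to parent 1). Each call is independently set
missing with probability `missing_rate`, otherwise flipped between the two
legal states with probability `genotyping_error`. No HOM-for-parent-2
errors are generated: the caller could not interpret them, and in practice
such calls are filtered before CO analysis.

**Defaults as study conditions.** The default genome holds four
chromosomes named A04/A07/A08/A10 (23, 26, 22, 19 Mb) — the
high-marker-density subset of a rapeseed A subgenome on which desk-scale CO
analysis is well posed — with mid-chromosome placeholder centromeres used
only for plotting. λ_c defaults to 2 COs per bivalent, matching an
average of ≤ 2 COs per meiosis per chromosome in such data. Marker density
defaults to 200 informative markers/Mb (~1 per 5 kb): resequencing of a
polymorphic cross yields markers at this scale, and a 50-kb window with a
2-marker minimum presupposes several markers per window. Genotyping error
0.2 % and missingness 1 % are typical for filtered short-read genotypes.
Group sizes in the example experiment configuration follow the four
backcross populations of the motivating design (100 and 98 wild-type, 47
and 47 mutant gametes).

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: non-uniform recombination landscapes
(centromeric suppression, telomeric peaks), segregation distortion,
marker-density heterogeneity along a chromosome, correlated (clustered)
genotyping errors, gene-conversion tracts, and homoeologous exchanges
between subgenomes. Caller fidelity on real allotetraploid data therefore
needs confirmation against cytology, as the window parameters trade
resolution against robustness in a density-dependent way.

## Coincidence analysis

Chromosomes are tiled from 0 by `interval_size` (default 2 Mb; the trailing
partial tile is dropped). Incidence is boolean per gamete and interval
(≥ 1 CO by midpoint), so observed and expected are probabilities and CoC is
the classical coincidence ratio; expected frequencies are products of the
same population's marginal incidences (no external genetic map). Pairs with
zero expected frequency are reported as undefined, never imputed or zeroed.

Curves pool pairs by interval-midpoint distance. Two estimators are
reported: `mean_coc`, the average of per-pair ratios, and `pooled_coc`, the
ratio of the summed observed to summed expected frequencies. The pooled
ratio is strongly preferred at realistic population sizes: a single
interval pair at 5000 gametes carries only ~30 expected double crossovers
(Monte-Carlo SE ≈ 18 % of the ratio), while pooling the short/medium/long
thirds of a 25-Mb chromosome gives each bin several hundred expected counts
(SE ≈ 4 %). The shipped no-interference check and the acceptance script use
those three distance bins for exactly this power reason; the
interference-signal check uses the adjacent-interval (2 Mb) bin, where
suppression is strongest and the effect dwarfs the noise.

## Population statistics

Per-gamete counts include zero-CO gametes (a gamete is a sampled unit);
dispersion is the sample standard deviation (n − 1). Landscape windows are
closed-open, 1 Mb advancing by 50 kb by default; a CO on a boundary belongs
to the right window, and summing a non-overlapping 1-Mb tiling times the
gamete count reproduces the total CO count exactly (conservation test).
Group comparisons use the two-sided Mann-Whitney U test with tie
correction, via scipy.

## Expression screen

TPM divides each gene's count by its length in kb and scales each sample to
10⁶; an all-zero sample yields zeros with a warning rather than NaN.
Replicate QC computes Pearson R² on log2(TPM+1) between replicate pairs
within each stage. Stage means over replicates are the per-gene expression
level; the coefficient of variation (sample SD / mean across stages) ranks
genes, zero-mean genes excluded, and the top 15,000 (default) enter
clustering.

Fuzzy c-means runs on z-scored stage means with c = 10 and fuzzifier
m = 1.25 by default: z-scoring makes clustering shape-based rather than
level-based, and a low fuzzifier keeps memberships crisp for
well-separated temporal patterns. Updates are the standard alternating
memberships (u ∝ (1/d²)^{1/(m−1)}, normalised) and membership^m-weighted
centers; a gene coinciding with a center receives full membership (the
limit rule), and iteration stops when the objective changes by < 1e-9 or
after 300 iterations. The objective is non-increasing, memberships sum to
1 per gene, and the result is a pure function of the seed (all tested).
Centers are initialised from c distinct data rows drawn with the seeded
generator.

The co-expression network places an undirected edge where |r| > 0.95 and
the t-transform p-value (n − 2 degrees of freedom over the stage-profile
length) is < 0.05; correlations are computed on the stage-mean profiles
(8 observations by default), so with 8 stages the p-value threshold is the
binding constraint only for |r| slightly above the r threshold. The
vectorised all-pairs computation is oracle-tested against
`scipy.stats.pearsonr`. Candidates are nodes with degree in a configurable
band (default 50–206, a moderate-to-high connectivity band), copy number
≤ 4, and absence from a user-supplied known-function exclusion list —
"unknown function" is operationalised as an explicit list because
annotation lookups are out of scope. Copy numbers are an input table;
homology collapsing across subgenomes is not implemented.

The planted-profile generator used for validation draws per-gene lognormal
baselines, multiplies a fold-induction at each group's peak stage (half
carrying into the following stage), and applies multiplicative lognormal
replicate noise. It validates shape recovery, not count statistics: real
RNA-seq overdispersion, library-size variation and batch effects are not
modelled.

## Problem sizes

The test suite and acceptance script run the analyses at the scale a
single-CPU desk replication supports: 100,000 meiocytes for the thinning
contract, 5000 gametes on one 25-Mb chromosome for the coincidence
experiments, 80–100 gametes at 200 markers/Mb for caller fidelity, and a
few hundred planted genes for the screen. These sizes put Monte-Carlo
error well inside every asserted tolerance (see the power notes above).

## Known limitations

- The caller reports no confidence measure per CO; bounds are nearest
  informative markers, which understate uncertainty in sparse regions.
- COs within ~one window of a chromosome end can be uncallable (no
  assigned window beyond them); terminal recovery is therefore slightly
  below 1 even error-free.
- The 500-kb rule removes genuine close double crossovers by construction;
  with strong interference this costs little, but under independence it
  biases per-gamete counts down by a few percent.
- CoC is undefined for intervals with zero marginal frequency; curves on
  small populations can therefore omit distal bins.
- No genetic-map (cM) construction, segregation-distortion testing, HMM
  genotype smoothing, or gene-conversion detection.
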