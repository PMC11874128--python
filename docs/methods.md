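# Methods

`runscape` analyses diploid SNP-array genotypes from one or more livestock
populations: quality control, detection of runs of homozygosity (ROH) and
runs of heterozygosity (ROHet), genomic inbreeding coefficients, run-hotspot
islands, diversity/structure summaries, and across-population comparisons.
A gene-drop simulator with exact ground truth backs every stage with
recoverable expectations. This note records the models, the parameter
choices that matter, and the numerical and design decisions behind them.

## Data model

Genotypes are stored as A2-allele dosages (0/1/2) in an `int8` matrix with a
reserved missing sentinel; every statistic masks missing calls explicitly.
Analyses are restricted to autosomes 1–29 (the caprine karyotype);
chromosome labels outside that range are dropped with a logged count.
Allele orientation is irrelevant to every statistic in the package (runs,
inbreeding, IBS, PCA are all invariant under per-marker dosage flips
`g -> 2 - g`), so for text PLINK input without an allele declaration the
first allele observed in file order is taken as A2 and the assignment is
recorded; binary input uses the BIM declaration. Binary I/O follows the
PLINK 1.9 two-bit encoding (00 hom A1, 01 missing, 10 het, 11 hom A2,
SNP-major, low bits first).

## Quality control

Two tracks, as is standard when the same chip serves both
relationship/structure estimation and run detection:

| filter | strict | lenient | default |
|---|---|---|---|
| per-marker quality score (if present) | yes | yes | ≥ 0.60 |
| marker call rate | yes | yes | ≥ 0.90 |
| sample call rate | yes | yes | ≥ 0.90 |
| minor allele frequency | yes | no | ≥ 0.05 |
| HWE exact-test p | yes | no | > 1e-5 |

MAF and HWE pruning are disabled on the lenient (run-detection) track
because they would preferentially delete the low-diversity stretches that
ROH are made of. Filters run in the fixed order above; sample call rate is
computed after marker removal. One consequence worth knowing: a second QC
pass can, in contrived boundary cases (a marker exactly at the call-rate
threshold whose rate shifts when a sample is removed), prune further — in
practice, at realistic missingness (≲ 2%), QC is idempotent and is tested
as such.

The Hardy–Weinberg test is the exact conditional test: the heterozygote
count given the allele counts, two-sided by summing all configurations no
more likely than the observed one, no mid-p correction. Probabilities are
computed from log-gamma closed forms; ties at the observed probability are
included with a 1e-9 relative slack to absorb float rounding. Monomorphic
markers return p = 1 by convention.

## Run detection

### ROH (scanning-window method)

Defaults mirror the standard PLINK flags: windows of 50 SNPs slide one SNP
at a time; a window is a *hit* if it holds ≤ 1 heterozygous and ≤ 1 missing
call; a SNP is eligible if ≥ 5% of the windows overlapping it are hits;
maximal eligible stretches are split at inter-marker gaps > 500 kb and
trimmed so terminal SNPs are homozygous; a run must contain ≥ 50 SNPs, span
≥ 1 Mb, average ≤ 100 kb per SNP (run-average density, the flag semantics),
and — by default (`run_het_mode="strict"`) — carry at most 1 heterozygote in
total; `"permissive"` drops the run-level budget, leaving heterozygotes
limited only per window.

Formally, the caller emits the *maximal passing intervals*, chosen greedily
from the left (smallest start, then longest, then continue after its end).
In all ordinary data this is identical to the step list above; the greedy
rule exists to make the output well defined in the degenerate case where a
single eligible block holds more heterozygotes than the run-level budget,
in which several overlapping maximal intervals would otherwise qualify.
The greedy set is non-overlapping and deterministic, and it is exactly what
the brute-force oracle in the test suite enumerates.

A chromosome with fewer markers than one window yields no calls (logged).

### ROHet (consecutive-marker method)

A ROHet is a maximal stretch with heterozygous terminal markers absorbing at
most 2 missing and 3 homozygous calls, with ≥ 15 markers (all markers in
the span count) and ≥ 500 kb. The same greedy maximal-interval selection
applies. There is no gap or density rule; the criteria are absolute budgets,
as in the consecutive method of the detectRUNS family.

### Length classes

ROH: 1–2, 2–4, 4–8, > 8 Mb. ROHet: 0.5–1, 1–1.5, 1.5–2, > 2 Mb. Bins are
half-open `[lo, hi)`: a run of exactly 2.0 Mb is "2–4 Mb". Run coordinates
are first/last member marker positions (1-based inclusive);
`length = end − start + 1` — marker data carry no information beyond the
flanking markers.

## Inbreeding coefficients

* **F_ROH** = Σ run lengths / `L_TOTAL`, where `L_TOTAL` is the summed
  per-chromosome extent (last − first marker + 1) of the marker map in
  force. It is always recomputed from that map — published per-dataset
  constants are reproduced only when the same map is supplied. Class-wise
  components sum to the total by construction (asserted to 1e-12).
* **F_G** = `G_ii − 1` with VanRaden method 1:
  `G = ZZ′ / (2 Σ p(1−p))`, `Z` the dosage matrix column-centred by `2p`,
  frequencies from the analysed cohort (pooled across populations by
  default, matching a single joint run; per-population frequencies are a
  caller choice by subsetting). Missing dosages are imputed to `2p`
  (contributing zero after centring). Monomorphic markers are excluded from
  the scale. An uncentred variant (`centered=False`) reproduces the literal
  `ZZ′` reading for comparison only — without centring `G_ii − 1` loses its
  inbreeding interpretation, which is why centring is the default.
* **F_exH** = `(Obs − Exp) / (N − Exp)` per sample over its called
  autosomal genotypes, with the bias-corrected expected homozygosity
  `Exp_j = 1 − 2 p_j (1 − p_j) · n_j/(n_j − 1)` summed over the sample's
  called markers (markers with fewer than two called samples are excluded).
  The method-of-moments completion with the small-sample factor is the
  conventional estimator; a bare verbal definition of "expected homozygous
  genotypes" does not pin one down.
* **Heterozygosity coefficient** from ROHet: Σ ROHet length / `L_TOTAL` by
  default; an alternative definition (fraction of map markers inside the
  sample's ROHet) is available behind `definition="snp_fraction"`. The two
  agree in ranking on data with appreciable ROHet burden; neither is
  privileged because published magnitudes for this quantity are not
  self-consistent enough to certify a formula.

Pearson correlations among all coefficients (with two-sided t-based
p-values) are computed on the per-sample table; under recent inbreeding the
correlation of total F_ROH with the long-segment class exceeds that with
the short-segment class, and the package's simulations reproduce that
ordering.

## Hotspot islands

For one population and run kind, the incidence track gives per marker
`n_in_run / n_genotyped` — the denominator is the samples *called* at the
marker, not the population size. Thresholds:

* `absolute` — a fixed fraction (0.50 is the conventional ROH rule);
* `top_quantile` — the inclusive upper empirical quantile of the incidence
  distribution at a tail mass (0.005 for ROH, 0.001 for ROHet are the
  conventional tails). The inclusive ("higher") quantile is used so the
  resolved threshold is always an observed incidence value and the selected
  markers are exactly the top tail plus ties; a linearly interpolated
  quantile would fall between order statistics and select one marker too
  many on spiky tracks.
* `combined` (ROH default) — the larger of the two resolved cutoffs, i.e.
  an absolute floor under the quantile rule.

Ties at the threshold are included (≥). Hotspot markers within 500 kb (the
ROH gap constant, configurable) merge into islands; island bounds are
first/last member marker positions, and both peak and mean incidence are
reported since published tables do not say which one they print.
Cross-population overlaps are exact bp-interval intersections reported per
carrier set; annotation accepts BED (0-based half-open, converted) or GFF3
(1-based inclusive) and reports ≥ 1 bp overlaps with lengths.

## Diversity and structure

Ho is the mean across markers of the heterozygote fraction among called
samples; He the mean of `2p(1−p)` (unbiased variant multiplies by
`n/(n−1)`); PN the fraction of polymorphic markers. Genetic distance is
`1 − IBS` (mean shared-allele fraction over mutually called markers,
pairwise deletion); a Hamming variant (fraction of differing genotype
codes) is available. A pair sharing no called marker is an error, not a
NaN. PCA is the SVD of the `2p`-centred (optionally standardized) dosage
matrix with mean imputation; variance percentages are relative to total
variance. Neighbor-joining is the Saitou–Nei algorithm with deterministic
tie-breaking (lowest index pair) and negative branch lengths clamped to
zero with the deficit moved to the sibling branch (logged); on additive
matrices no clamping triggers and the tree reproduces the input path metric
exactly. Trees are exported as Newick; a population-level tree is built
from mean between-population distances.

## Group comparisons

Per length class, per-sample run counts (zero-run samples included as
zeros) are compared across populations by one-way ANOVA with all-pairs
Tukey HSD (Tukey–Kramer standard errors for unbalanced groups; studentized
range quantiles computed numerically by scipy). Significance letters use
the insert-and-absorb compact-letter-display algorithm with groups ordered
by decreasing mean; groups sharing a letter are not significantly different
at α. Counts are not normal, so a rank-based fallback (Kruskal–Wallis plus
pairwise Mann–Whitney with Bonferroni) is offered behind
`method="kruskal"`; the ANOVA route is primary because per-animal counts
are the response the field's tables imply. Degenerate inputs (zero
within-group variance) are resolved directly: identical means share one
letter (p = 1), distinct means are separated (p = 0). The family-wise error
of the Tukey route is calibrated by simulation in the acceptance checks.

ROH-vs-ROHet burden correlations are per-population Pearson tests on
per-sample summed run length (or counts).

## The synthetic-data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream guarantee is demonstrated.

* **Pedigree**: per population, unrelated founders mate in disjoint
  couples for a configurable number of generations; the final generation
  may include offspring of full-sib pairs (F = 0.25 against unrelated
  grandparents) alongside outbred children of non-sib couples (F = 0).
  Pedigree F comes from the tabular kinship recurrence; Wright's path
  counting is the independent oracle in tests.
* **Genome**: 5 chromosomes × 50 Mb with 1,000 markers each by default —
  a deliberately scaled-down caprine 50–70k array (≈ 50 kb spacing).
  Marker positions are uniform random without replacement. Recombination
  is Haldane (Poisson crossover count at 1 cM/Mb, uniform positions, no
  interference) — interference is irrelevant at array resolution.
* **Founder frequencies**: Beta(0.5, 0.5) truncated to [0.05, 0.95] (by
  resampling, not clipping), then diverged per population by a
  Balding–Nichols draw at Fst 0.1 — the standard single-parameter
  divergence model, giving realistic between-breed structure for PCA/tree
  checks.
* **Truth**: every transmitted segment carries its founder-haplotype label,
  so autozygous (IBD) segments are exact interval intersections of the two
  haplotype ancestries; segments under 10 kb (far below marker resolution)
  are not recorded. Realized IBD genome fraction is an unbiased draw around
  pedigree F.
* **Planted islands**: for `round(f·n)` carriers (chosen by the seeded
  generator), genotypes in the interval are overwritten — a single shared
  homozygous haplotype (`roh`) or all-heterozygous calls (`rohet`). Plant
  islands on the analysis cohort: planting before subsetting dilutes the
  realized carrier fraction.
* **Missingness**: uniform at 0.5% by default, applied last.

What the generator does **not** emulate: genotyping error, mutation,
ascertainment bias of array content, realistic LD decay or recombination
maps, sex chromosomes, and farm/family stratification beyond the explicit
pedigree. Passing the recovery tests therefore demonstrates correctness of
the algorithms under these idealized conditions, not robustness to
array-specific artefacts.

Problem sizes used by the test suite and the acceptance script — chosen as
the smallest sizes at which the quantities of interest are statistically
stable: the inbreeding-recovery simulation uses 200 analysed samples
(100 outbred / 100 full-sib) over 5 × 50 Mb chromosomes with 2,000 markers
per chromosome (25 kb spacing; at 50 kb spacing a 50-SNP run cannot be
shorter than ~2.45 Mb and the 1–2 Mb class would be structurally empty);
island recovery uses 100 replicates of 30 samples on one 50 Mb chromosome
with a 5 Mb island at carrier fraction 0.6; caller-oracle equivalence uses
500 random single-sample instances of ≤ 200 markers; Tukey calibration
uses 2,000 five-group null simulations.

## Numerical conventions

* Missing sentinel is a reserved code; it never enters arithmetic.
* HWE tie inclusion uses 1e-9 relative slack (see above).
* Eligibility fractions compare `hits/total ≥ threshold` on exact integer
  counts, so caller and oracle agree bit-for-bit.
* F_ROH class components are asserted to sum to the total within 1e-12.
* GRM symmetry is validated to 1e-10; distance-matrix symmetry to 1e-12.
* All randomness flows from explicit integer seeds; identical seeds give
  bit-identical datasets and pipeline outputs (checksummed in the run
  manifest, timestamps excluded).

## Known limitations

* The ROH caller is window/threshold-based; it does not implement
  likelihood or HMM callers and will differ from them near run boundaries.
* PLINK version differences in run-level heterozygote handling are real;
  both interpretations are exposed (`run_het_mode`), strict being default.
* F_exH depends on the frequency reference (pooled vs per-population);
  pooled is the default and the choice materially affects admixed cohorts.
* The simulator's idealizations listed above bound what the recovery tests
  can show about real array data.
* QC idempotency has the boundary caveat described under Quality control.
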