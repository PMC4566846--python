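# Methods

`magicpop` models an eight-founder MAGIC (multi-parent advanced
generation intercross) maize population: a funnel crossing design that
combines founders A–H through two-way, four-way, and eight-way hybrids
and then inbreeds by single seed descent (SSD) to F6.  The package
simulates that process forward with full knowledge of each line's
founder mosaic, reconstructs mosaics from SNP-array genotypes with a
hidden Markov model (HMM), and maps QTL on the reconstructed
founder-probability matrices.  This note records the models, their
assumptions, the defaults, and the design choices made where the
problem was genuinely open.

## Breeding-design model

**Funnel structure.** Two-way hybrids form a half-diallel (28 crosses
of 8 founders); four-way hybrids cross disjoint two-ways (210 crosses)
and are pooled by the four founder labels they carry (70 pools, e.g.
pool ABCD = {AB×CD, AC×BD, AD×BC}); eight-way hybrids cross each pool
with its complement (35 funnels).  Pooling is modelled as a uniform
choice among a pool's three component crosses per seed — the field
protocol pooled balanced seed amounts, so equal weights are the
faithful reading.

**Substitution rule.** The B96×HP301 (C×F) two-way failed in the
field; every four-way cross with it as a parent is replaced by the
B73×CML91 (B×I) two-way, introducing a ninth founder.  Applying this
rule wherever C and F share a pool, exact rational enumeration over
the 70 pools gives expected genome contributions of 1/7 for B73, 1/56
for CML91, 3/28 each for B96 and HP301, and 1/8 for the rest — the
values the population was designed to realize.  The simulator applies
the same rule, so Monte-Carlo founder shares converge to these
rationals.

**Meiosis.** Crossovers per chromosome are Poisson with mean equal to
the chromosome's genetic length in Morgans, placed uniformly on the cM
scale and mapped to bp through the marker map; there is no
interference.  This makes the Haldane map function the internally
consistent cM→recombination-fraction conversion, which is the package
default (a `linear` d/100 mode exists for comparison).

**Expectations.** For a genome of L = 19.96 Morgans, the expected
recombination-event count of a RIL lineage is 4L ≈ 79.8: one effective
round each from the two intercross generations and the first selfing,
plus one more round accumulated over SSD as heterozygosity halves each
generation (the geometric series 1 + 1/2 + … → 1 below the inbred
limit; at F6 the realized factor is 2 + 1.9375 = 3.94, slightly under
4).  Residual heterozygosity at F_k is 0.5^(k−1), 3.125% at F6.  A
population of n lines supports n(n−1)/2 distinct recombinant inbred
intercross F1s (1,337,430 for n = 1,636).

**Synthetic marker panel.** The default array-like panel has 5,000
biallelic markers on 10 chromosomes with maize-like relative physical
sizes (total ≈ 2,055 Mb) and a total map of 1,996 cM, cM linear in bp
per chromosome.  Founder alleles at each marker are drawn by choosing
k ~ Uniform{1..7} founders to carry the alternate homozygote, giving
the k/8 minor-allele-frequency spectrum characteristic of arrays
ascertained on polymorphic sites.  Genotyping applies a symmetric call
error (default 1%) and missingness (default 15%, matching an ~85% call
rate).  What this panel does **not** emulate: long identical-by-state
(IBS) tracts between related founders (synthetic founder alleles are
independent across markers), array ascertainment bias toward
particular founder pairs, and heterozygosity inflation from poor
hybridization.  Tests passing on this panel therefore demonstrate
correctness of the machinery, not the exact error rates expected on
real arrays, where founder IBS makes reconstruction strictly harder.

## Mosaic reconstruction (HMM + EM)

Hidden states are the G homozygous founder genotypes (G = 8, or 9 for
lines flagged as carrying the substitution donor; the donor state is
allowed only for those lines).  Observed symbols are the calls
{0, 1, 2}; missing calls are emitted uniformly by all states and carry
no information.  Observed heterozygous calls are treated as emission
noise against homozygous states — at F6 only ~3% of the genome is
heterozygous by descent and phasing it is out of scope.

**Emissions.** Initialized from founder calls: mass on the founder's
homozygous symbol, split 0.5/0.5 for a heterozygous founder call; a
smoothing constant (default 0.01) is added to near-zero entries and
the distribution renormalized, which caps the per-marker evidence and
absorbs genotyping error.  EM re-estimates each marker×state emission
from posterior-weighted symbol counts pooled across lines (pooling
stabilizes estimates when few lines visit a state at a marker);
smoothing is re-applied each M-step by default (flag to disable).
Iteration stops when the total log-likelihood changes by less than
1/1000 of its initial magnitude.

**Transitions.** Between adjacent markers at recombination fraction r,
the probability that the founder state changes is R = r(4−r)/(1+2r),
the two-locus founder non-identity of an eight-way selfing RIL at the
inbred limit; the test suite verifies this against an independently
coded funnel-plus-selfing Markov-chain recursion.  R(0.5) = 7/8:
unlinked loci share a founder with probability 1/8.  The change mass
is split equally over the G−1 alternative founders (funnels are
exchangeable across lines, so the marginal kernel is uniform).  A
`damping` factor on r (default 1.0) is exposed for users who want a
stickier or looser chain.

**Inference.** Scaled forward–backward per chromosome (uniform 1/G
prior at each chromosome start) gives exact posteriors and the
log-likelihood from the scale factors; the implementation is
vectorized across lines.

**Junction counting.** Two estimators are provided.  The hard count
(`count_junctions`) masks markers whose maximum posterior is below
`min_prob` (default 0.8) and counts argmax changes between consecutive
confident markers.  The expected count (`expected_junctions` on each
reconstruction) sums the posterior probability of a state change over
marker intervals; it is exactly calibrated when the data come from the
model's own chain.  On funnel mosaics at 5,000-marker density both
undercount — the hard count by ~20%, the expected count by ~15% —
because short segments often contain no informative marker (founders
agree at ~57% of markers) and because the true switch process is
locally near-two-state (selfing-phase junctions alternate between the
two resident haplotypes) while the model's uniform 1/(G−1) prior
under-weights exactly those invisible excursions.  This is a
resolution limit of array-density data under an exchangeable-kernel
HMM, not an implementation artifact; denser markers close the gap.

## QTL mapping

**Linkage scan.** The phenotype is regressed on the G founder-
probability columns of each marker with a polygenic random effect
whose covariance is σ²_g K; K is the mean inner product of posterior
vectors over markers, computed leave-one-chromosome-out (LOCO) so the
tested chromosome does not absorb its own QTL.  Nine-state posteriors
are reduced to eight by dropping the rare donor column and
renormalizing (its coefficient is otherwise unstable).  Variance
components are estimated once per (trait, LOCO chromosome) by REML on
the eigendecomposition of K and then fixed across markers
(EMMAX-style); each marker is a generalized least-squares fit on the
rotated data, LOD = (n/2)·log10(RSS₀/RSS₁).  Because the founder
columns sum to one, the intercept is implicit and founder effects are
reported as deviations from their mean.

**Thresholds and peaks.** Significance comes from permutations of the
raw trait: the 99th percentile of per-permutation genome-wide maximum
LOD is the strong threshold (genome-wide P < 0.01), the 37th the
suggestive one (P < 0.63).  Variance components are re-estimated per
permutation by default (flag to freeze).  Peaks above the suggestive
threshold get −2 LOD support intervals; local maxima on a chromosome
are split into separate peaks only when ≥ 50 consecutive markers
between them drop below the suggestive threshold.  A covariate scan
conditions both models on the founder columns of a chosen marker.

**Association scan.** Founder variant alleles (from a VCF of inbred
founders) are transferred to lines as expected dosages through the
posterior vector at the nearest array marker (posteriors are
piecewise-constant between informative markers, so nearest-marker
transfer is the natural rule; ties break left).  The continuous dosage
is the regression covariate; rounding to a 0/1 founder-allele
indicator is reserved for the interval LD profile, where founders are
inbred and the diploid coding collapses to haploid.  The region-wide
threshold is the 90th percentile of 500 permuted maximum LODs.

## Phenotype simulation and power study

Twenty QTL (two per chromosome, effect of QTL i equal to 0.9^i, minor
allele contributed by a random set of 1–4 founders per QTL) define a
genetic value per line through the condensed genotype
f = 2·Σ_{s∈F} P(s) − 1.  The genetic value is standardized to unit
variance and Gaussian noise added so it explains h² ∈ {0.4, 0.7} of
the phenotypic variance.  Realized per-QTL explained variance is
recorded and used to bin power in 2-percentage-point bins.

Mapping is forward stepwise selection of founder-posterior
regressions: scan all markers given the current model, take the
highest-LOD marker, test it with a 7-df likelihood-ratio χ², and stop
when it fails the entry rule.  Two entry rules are exposed.  The
nominal rule (P ≤ 0.01 on the χ²) never terminates on a genome-wide
panel — the null maximum over thousands of correlated tests almost
surely exceeds a fixed nominal cutoff — which inflates both power and
false discovery far beyond the published study.  The default is
therefore a genome-wide calibrated rule: markers enter while the
maximum LOD exceeds the 99th percentile of the null maximum-LOD
distribution (estimated from 200 standard-normal traits, which are
exchangeable with permutations under the null), i.e. the same
genome-wide P < 0.01 convention the permutation thresholds use.  The
kinship random effect is omitted in the power study (lines are drawn
at random, minimizing structure; a per-run mixed model would dominate
the compute budget at hundreds of runs).

Detection matches each selected marker to at most one simulated QTL
within ±5 Mb on the same chromosome, nearest first, boundary
inclusive; power is the detected fraction of simulated QTL and FDR the
unmatched fraction of selected markers (0 when nothing is selected).
Study cells average 4 MAF settings × runs (25–50 per MAF at desk
scale; the published grid used 100).  At desk scale (5,000 markers,
~525–560 lines) the study reproduces the published pattern: ≥90% power
for QTL explaining ~8% of variance at n = 500, h² = 0.7; ~85% at ~12%
with n = 300; overall power in the mid-40s% at (500, 0.7) and ~18% at
(500, 0.4), bracketing the published 41% and 22.1% from opposite
sides within Monte-Carlo and procedure uncertainty.

## Diversity and LD statistics

Marker QC keeps polymorphic markers with call rate strictly above 80%.
MAF uses only markers homozygous and called in every founder; with
nine founders the founder MAF maxes at 4/9.  Observed call-level
heterozygosity is the fraction of `1` calls; note it underestimates
heterozygosity-by-descent by the marker informativeness factor (~0.43
on the synthetic panel), since a het segment shows a het call only
where the two resident founders differ.

r² is the squared Pearson correlation of allele dosages over
pairwise-complete lines (heterozygous calls count dosage 1; markers
with zero variance are excluded from averages).  LD decay bins all
pairs within 10 Mb per chromosome into 100-kb distance bins.  The
halving distance is the first bin at or below the baseline-adjusted
half of the first bin's mean, where the baseline is the mean r² of the
farthest fifth of bins — a family-structured RIL panel has a
relatedness floor well above zero, and the unadjusted half is never
reached on strongly structured subsets.  Local LD averages each
marker's r² with neighbours within ±1 Mb and smooths with a
100-marker sliding window advancing one marker at a time (25th/75th
percentile bands use the same windows).  LD pruning walks each
chromosome left to right dropping markers with r² > 0.4 against any
retained marker within 500 kb; the result is idempotent.

## Numerical and engineering choices

- Recombination fractions are clamped to [1e−12, 0.499] so HMM
  transitions stay non-degenerate and loci remain formally linked.
- The stepwise engine residualizes per-marker 7×7 Gram blocks by
  sweeping each accepted marker out of the normal equations, so a step
  costs one cross-product pass plus batched small solves; a tiny ridge
  (1e−9·trace) guards near-collinear markers and markers with no
  residual variance are barred from entry.  Forward selection was
  verified to match a direct least-squares implementation exactly.
- Mixed-model REML optimizes log δ = log(σ²_e/σ²_g) on [−10, 10] by
  bounded scalar minimization; kinship eigenvalues are floored at
  1e−9.
- Posterior arrays use float32 in the power study (memory ~½, BLAS
  ~2×); all reductions accumulate in float64.
- One master seed drives every stage; per-stage seeds derive from
  SHA-256 of (master, stage name, index), all below 2^31.

## Problem sizes used by the bundled studies

The acceptance computation simulates 560 lines × 5,000 markers,
reconstructs them with at most 8 EM iterations, and runs 50 power
replicates per MAF setting per scenario cell; the test suite uses a
1,500-marker / 140-line fixture for unit-level checks and rebuilds the
full 5,000-marker population only for the study-scale assertions.
These sizes are the package's desk-scale defaults; all of them scale
up linearly through the public APIs.

## Known limitations

- Synthetic founders lack IBS structure, so reconstruction accuracy on
  real arrays will be lower than the synthetic-panel figures.
- Junction counts are biased low at array density (see above); treat
  them as lower bounds unless markers are dense relative to segment
  lengths.
- The power study's entry threshold is estimated once per sample size
  from a representative subset; per-run thresholds would add ~1–2 s per
  run for little change.
- Residual heterozygous segments are not phased, and the HMM has no
  heterozygous hidden states.
- The pipeline's scan stage assumes one phenotype row per genotyped
  line; incomplete phenotype tables must be subset upstream.
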