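# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the procedure was genuinely open.

## Cross simulation

A simulated genetic map is a set of chromosomes (default 22, matching the
karyotype of the study species) with marker positions in centimorgans. F2
meioses are generated as the union of two independent gametes; a gamete is a
Markov chain over the chromosome's marker loci whose switch probability in
each interval is the map function's recombination fraction for that gap
(Kosambi `r = tanh(2d)/2` with d in Morgans, or Haldane). No crossover
interference is modelled beyond what the map function implies pairwise; this
matches the mapping function used downstream without carrying an
interference model the analyses never exploit. Single-marker genotypes
segregate 1:2:1 and pairwise recombination fractions reproduce `r(d)` within
Monte-Carlo error (both property-tested).

Trait architectures assign each QTL an additive effect `a` (half the
homozygote difference; +a for AA, d for AB, −a for BB, with A the CAL-line
allele) and optional pairwise epistasis terms on centred genotype codes.
Parental panels are simulated as fully inbred lines — all AA or all BB at
every QTL — because the marker-selection step downstream assumes near-fixed
parental pools. A "complementary" architecture requires mixed-sign additive
effects, the dispersed-antagonistic-loci configuration expected to produce
transgression through segregation variance; the property suite verifies that
this configuration inflates the F2 transgressive fraction above the
mean±2SD null level (~4.55%).

Sand images are single-channel brightness arrays (the downstream measurement
is a brightness cut, so colour carries no information): a beige field
(default N(180, 12²)) with disturbance disks repainted from the dark
bottom-layer distribution (N(40, 12²)). Disks are added until the repainted
area reaches the target fraction, the last disk trimmed pixel-by-pixel, so
the realized fraction — returned exactly as repainted pixels over total
pixels — matches the target at integer-pixel resolution. Default geometry is
160×120 px with disk radii ~N(6, 2²); these are arbitrary image-plumbing
scales, not measurements.

The VCF writer renders the cross as VCFv4.2 text (1 cM ≡ 10 kb, an arbitrary
physical scale chosen so that adjacent markers never violate the 200 bp
spacing filter), with parental panels of 6 and 5 samples fixed for reference
and alternate alleles, and can inject records violating each filter rule for
targeted tests. Clean records draw depth as 10 + Poisson(mean − 10) so the
genotype-depth mask never fires on them.

## Variant filtering and recoding

Filters apply in a fixed order: site quality ≥ 30; per-genotype masking
(GQ < 30 or DP < 10 → missing); drop indels, sites within 10 bp of an indel
start (inclusive), multiallelic and monomorphic sites; drop sites with > 50%
missing genotypes; drop sites with mean called-genotype depth > 88
(paralog-enriched); drop sites whose minor allele occurs fewer than 3 times;
thin to one site per 200 bp keeping the first by position. A site failing
several rules is attributed to the first failing rule, so exclusion counts
plus retained count always equal the input count, and the filter is
idempotent on its own output. Monomorphic/minor-allele counts are evaluated
after genotype masking, since masked genotypes cannot support alleles;
whether the original pipeline ordered these two steps this way is not
documented, so the choice here is declared rather than inferred.

Reciprocally fixed markers require all non-missing panel-A genotypes
homozygous for one allele and all panel-B genotypes homozygous for the
other, with at most 3 of 6 (A) and 2 of 5 (B) panel members missing. F2
genotypes are recoded by counting parent-A alleles (AA = 2, AB = 1, BB = 0
copies); on simulator output with no injected violations the recoded matrix
equals the simulated truth exactly (tested).

## Linkage grouping and mapping

Marker QC drops markers with segregation-distortion χ² p < .01 against 1:2:1
(computed on non-missing counts) or > 20% missing data, then individuals
with > 30% missing data. Pairwise independence is measured by the
likelihood-ratio G statistic on the 3×3 genotype table, reported as
LOD = G/(2 ln 10) — the standard likelihood-ratio LOD; grouping is the
single-linkage transitive closure at LOD ≥ 7.0, which recovers simulated
chromosome partitions whenever within-chromosome LODs exceed the threshold.

Recombination fractions between marker pairs are maximum-likelihood
estimates from an EM over the two-locus F2 genotype classes: each class
contributes a known expected number of recombinant gametes, with the double
heterozygote a phase mixture contributing `2r²/((1−r)² + r²)`. Estimates are
clamped at 0.4999 to keep Kosambi distances finite. Map positions accumulate
adjacent-pair Kosambi distances; ordering is either the supplied true order
(simulated crosses) or a greedy nearest-neighbour seriation on pairwise r̂.
Multipoint regression ordering, ripple steps, "jump" and nearest-neighbour-
fit exclusions, and the strongest-cross-link heuristic of the proprietary
mapping software in this field are not reimplemented — they are unpublished
heuristics; the simplified ordering is recorded on the resulting map object.
Adjacent-pair (rather than multipoint) distances slightly inflate map length
when marker data are noisy; estimated chromosome lengths stay within 15% of
truth at n = 1,000 on dense simulated maps (tested).

## Genotype probabilities and QTL scans

Conditional genotype probabilities come from a forward–backward pass per
individual per linkage group, on a grid holding every marker plus
pseudomarkers at a fixed step (default 1 cM) anchored at the group's first
marker. The hidden state is the true genotype; interval transitions are
built from two independent gamete chains with r from the map function;
typed markers emit the observation with probability 1 − ε (ε/2 for each
wrong genotype, default ε = 0.05), and missing observations are
uninformative. Because the Kosambi function is not additive over
subdivided intervals, pseudomarkers participate in the chain exactly as
uninformative markers do; the test-suite oracle therefore enumerates hidden
paths over the same grid. Probabilities at ε = 0 are degenerate at typed
markers and rows always sum to one.

The normal-model scan maximises, at each grid position, the mixture
likelihood `Σ_g p_ig N(y_i; μ_g + x_iβ(_g), σ²)` by EM, with the genotype
probabilities as mixing weights. Initialisation uses the null-model fit
(marginal mean/SD, or the covariate regression when covariates are present),
which makes the EM likelihood start at the null likelihood and increase
monotonically, so LOD = (ℓ̂₁ − ℓ̂₀)/ln 10 is nonnegative by construction.
Convergence is |Δlog-lik| < 1e−8 (1e−6 inside permutation loops) with at
most 1,000 iterations; non-converged positions are flagged on the curve and
the last iterate reported. With no covariates the EM runs vectorised across
all grid positions. Additive covariates shift the mean; interactive
covariates give genotype-specific slopes, and the corresponding null keeps
only the covariate main effect (standard single-QTL-scan semantics). The
scan is invariant to affine transformation of the phenotype and reduces, at
a fully typed marker with ε → 0, to `(n/2) log₁₀(RSS₀/RSS₁)` from the
genotype-means regression (both tested; the latter to 1e−6).

The nonparametric scan ranks the phenotype (mid-ranks for ties) and forms a
Kruskal–Wallis statistic with the genotype probabilities as fractional group
memberships, including the standard tie correction; LOD = H/(2 ln 10), and
at a fully typed marker it equals the classical Kruskal–Wallis statistic.
Covariates are not supported in the nonparametric model, matching the tool
conventions in this field; this is a documented limitation.

Genome-wide significance: the phenotype (jointly with its covariate rows) is
permuted against the genotypes; thresholds are empirical (1 − α) quantiles
of the per-permutation maximum LOD at α = .05 and .10, and the genome-wide
p-value of a peak is the add-one tail proportion. Credible intervals treat
10^LOD (normalised within the peak's linkage group) as a posterior, grow the
interval from the peak towards the larger neighbouring mass until it holds
95%, then widen the endpoints to the nearest flanking true markers. Effect
size is PVE = 100(1 − 10^(−2·LOD/n)) with n the number of phenotyped
individuals in that scan.

## Behaviour scoring

Turned-over area is the percentage of pixels at or below the brightness
threshold (default 80), which is monotone nondecreasing in the threshold.
The before-trial percentage is subtracted first (floored at zero with a
warning), then the scrape-effect factor e ∈ {0, .1, .25, .5, .75, .9} is
applied as multiplication by (1 − e): e is read as the fraction of blackened
area attributable to scraping, so (1 − e) retains the strike-attributable
fraction. The alternative literal reading, multiplication by 1/e, would
inflate rather than remove the scraping contribution and is rejected; the
correction can be disabled (`mode="off"`). Subtraction-before-correction
follows the stated order of operations. Efficiency is area per strike
+ 0.001 (so zero areas survive log₁₀), undefined for zero-strike trials;
trials with zero strikes and a hiding or interaction score of 5 are excluded
entirely. Female groups are scored with the summed strikes of the three
group members and the mean of their standard lengths. Latency, scraping
counts and group aggression scores are carried in the data model but drive
no statistic.

## Morphometrics

The 13-landmark schema uses ids {1–7, 10–15} with 11–14 as semilandmarks
equally spaced on the dorsal head curve 10→15. Coordinates follow the
mathematical convention (y up); TPS files digitised in image convention can
be flipped on read, which the signed mouth-angle convention (upturned mouth
= larger angle) requires to be explicit. Jaw standardisation rotates
landmark 4 about landmark 3 so the jaw-opening angle equals its
cross-specimen mean, preserving jaw length — removing variation from mouths
fixed open to different degrees.

GPA centres each configuration, scales to unit centroid size, rotates to the
evolving consensus (SVD rotation, reflections excluded), and iterates to
1e−10. Semilandmark sliding minimises thin-plate-spline bending energy
against the consensus: the bending-energy matrix is the upper-left block of
the inverted TPS system for the consensus, tangents are estimated from each
semilandmark's neighbours on the curve, and one Gauss–Seidel pass per outer
iteration (five outer iterations) moves each semilandmark by the
energy-minimising step along its tangent — each step can only decrease the
energy, which the suite asserts per pass. Allometry-free shapes are
per-coordinate regression residuals on log₁₀ SL added back to the consensus;
the allometry report carries a Procrustes-ANOVA-style F and a
residual-randomisation permutation p (999 permutations by default — the
randomisation scheme and count are not externally fixed, so they are
declared here). Specimen sets with distinct allometries (e.g. much larger
museum specimens) can be regressed separately via the `groups` argument.
PCA axes come from the SVD of the centred aligned coordinates with a
deterministic sign convention (largest-magnitude loading positive);
comparisons with external axis orientations are meaningful only up to sign.
Projection aligns a new specimen to the consensus by ordinary Procrustes
(no consensus update, no sliding) and multiplies the centred coordinates by
the axes; projecting an in-space specimen of a plain GPA space returns its
own scores to machine precision.

## Transgression statistics

The conservative thresholds attach 2·SD to the parent contributing the
extreme mean — that parent's own sample SD (n−1 denominator), per the
defining sentence's structure; smaller parental samples therefore widen the
thresholds, which is the intended conservatism. Values exactly on a
threshold are not transgressive (strict inequality). The permutation test
enumerates all C(n₁+n₂, n₁) relabelings when that count is at most 10⁶ and
otherwise uses the add-one Monte-Carlo estimator, which cannot return zero;
the statistic is the difference in means, two-sided. Size correction
regresses log₁₀ trait on log₁₀ SL pooled across classes when the
class×slope interaction F-test is nonsignificant after Benjamini–Hochberg
adjustment across traits, per-class otherwise; both modes can also be
forced, since behavioural efficiency is corrected within class while
morphological traits use the pooled fit when slopes are homogeneous.

## Pipeline, seeds and problem sizes

The `run` pipeline derives one child seed per stage from the master seed via
a seed sequence and records them, with all parameters, in the manifest, so a
rerun with the same seed is byte-identical (tested). Default synthetic
sizes mirror the study where stated — ~113 F2 individuals, parental panels
of 6 and 5, 22 linkage groups in the full-size map, scoring thresholds and
QC cut-offs at the study values. The acceptance suite's stochastic checks
use deliberately scaled-down configurations — a 3-chromosome genome with
markers every 10 cM, a 5 cM scan step, 200 permutations, and 100–200
replicates — chosen so the whole suite completes in a few minutes while the
binomial error of the assessed rates stays well inside the asserted bands.

## What the generators do not emulate

Synthetic data are idealised: no read-level sequencing error model (depth
and quality fields are plumbing, not an error process), no crossover
interference, no family structure within the F2 (the study's families are
pooled in all analyses), no linked-marker ascertainment bias, no camera
geometry or lighting gradients in the sand images, and landmark noise is
isotropic Gaussian rather than digitisation error. Passing tests therefore
demonstrate correctness of the estimators under their stated models, not
robustness to every artefact of real field data.

## Known limitations

Greedy seriation can misorder tightly linked markers at small n; the
adjacent-pair map inflates slightly under genotyping noise; the EM scan
models a single QTL (no composite interval mapping or epistasis scans); the
X chromosome is not treated specially; and the nonparametric scan ignores
covariates.
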