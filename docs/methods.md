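# Methods

## Scope and model

`tsaorta` analyses exome-sequenced Turner syndrome cohorts for the joint
contribution of *TIMP1* dosage (X chromosome) and *TIMP3* variation
(chromosome 22) to bicuspid aortic valve (BAV) and thoracic aortic dilation
(TAD). It operates downstream of read alignment and variant calling: its
inputs are genotype/allele-depth VCFs, phenotype tables and variant
annotations (gene assignment, CADD PHRED, reference allele frequency).
CADD computation, expression-database queries and raw-read processing are
out of scope; annotation values are consumed as inputs.

## Second-sex-chromosome status from allele balance

On a single X chromosome every variant is hemizygous, so exome alternate
allele frequencies (AAF) at X variants cluster at 0 and 1. A retained second
X adds a heterozygous band at 0.5; XY material is heterozygous only in the
pseudoautosomal region (PAR1, X:60001–2699520, hg19) and contributes reads
on Y. In a 45,X/46,XX mosaic with 45,X cell fraction *f*, a site
heterozygous on the two X haplotypes has expected ALT fraction

- `u = 1/(2−f)` when ALT is on the X retained in every cell,
- `l = (1−f)/(2−f)` when ALT is on the X missing from the 45,X line,

so the single 0.5 band splits into two bands that are mirror images about
0.5 (`u + l = 1`). The classifier reports MONOSOMY_X when the
intermediate-AAF mass outside the PAR falls below 5% and no Y evidence
exists; XY_MATERIAL when more than 10% of Y target sites have depth ≥ 5
(the Y mosaic *level* is deliberately not quantified — allele balance does
not support it); XX versus XX_MOSAIC by the estimated band displacement
(mosaic when the implied 45,X fraction exceeds 0.15). Triple-X mosaics and
structural second-X chromosomes cannot be separated from ordinary mosaicism
on allele balance alone; those categories exist in the status enum and are
assigned through the clinical-karyotype override, which always takes
precedence over the molecular call when a clinical karyotype is supplied.

### Mosaic-fraction estimation

The default estimator exploits the mirror symmetry: ALT counts at
intermediate sites follow the two-component mixture
`0.5·Binom(d, u) + 0.5·Binom(d, 1−u)` with a single free displacement
parameter, fitted by bounded one-dimensional maximum likelihood over
`u ∈ [0.5, 0.999)` on sites with AAF in (0.02, 0.98). Both band centres are
then inverted analytically (`f = 2 − 1/u`; `f = (1−2l)/(1−l)`; the two
inversions coincide under the symmetry) and the result is clamped to [0, 1].
The likelihood was chosen over hard assignment of sites to bands because at
low mosaicism (f ≈ 0.1 the bands sit at 0.474/0.526 while binomial noise at
depth 70 has SD ≈ 0.06) band overlap biases window medians upward by ~0.07;
the mixture fit stays within ~0.05 down to f = 0.1, which is the
information limit at ~60 informative sites. Two alternatives are retained:
`method="median"` (per-window medians, windows (0.5, 0.90) and (0.10, 0.5),
exact on noise-free profiles and used for the algebraic round-trip tests)
and a linear-trend surrogate that fits straight lines through the model's
anchor points, provided for comparison only since a line approximates the
curved inversion with visible interior error.

Sites with AAF in (0.10, 0.90) count as "informative"; estimates from fewer
than 10 informative sites are returned undefined rather than extrapolated.
Note the band centres leave this window above f ≈ 0.87 (u > 0.9), so the
exact-inversion property holds on the window's interior; the mixture window
(0.02, 0.98) keeps the estimator usable up to f ≈ 0.95.

## ISCN karyotypes and locus copy number

The parser covers the slash-separated clinical dialect seen in Turner
syndrome reports: cell lines with optional `[NN%]` fractions, intact X/Y
content, and the structural terms i(Xq), psu idic(Xq..), ring(X) (plain,
banded, or annotated "small"), del(Xp..)/del(Xq..) with one or two
breakpoints, +mar and add(autosome). Idiosyncrasies of real reports are
tolerated (missing commas, stray spaces, an omitted intact X recovered from
the chromosome count, percentage columns summing to 99–101%). Unparseable
tokens raise an error naming the token; nothing is guessed silently.

Copy number of an Xp locus is the fraction-weighted sum over cell lines of
the chromosomes carrying the locus. Carriage rules: intact X carries;
i(Xq) does not (no p arm); del(Xq..) does; whole-arm del(Xp) does not; a
banded del(Xp A B) carries unless the locus lies inside the deleted
segment (decided against an approximate hg19 Xp cytoband table); plain
ring(X) carries, a "small" ring or a banded ring whose segment excludes the
locus does not; markers, autosomal additions and Y carry nothing. A
pseudodicentric idic(Xq..) is counted as a single carrier, following the
convention of clinical copy-number tables. Results are rounded to one
decimal, matching clinical precision, and dichotomized at 1.1 copies
(≤ 1.1 → "1 copy"), the threshold that best reconciles mosaic calls near
0.9 45,X fraction with the copy-number groups used in risk tables.

When a string reports no cell-line fractions the mixture proportions are
unknown. Fractions are assigned an equal split for bookkeeping, but the
copy number is taken as the midpoint of the extreme cell lines — identical
to the equal split for two-line mosaics, and the bounds-midpoint choice for
the rare three-line strings, again matching how unquantified mosaics are
tallied clinically.

## Aortic phenotyping

Body surface area uses the Haycock formula
`BSA = 0.024265 · height^0.3964 · weight^0.5378` (height cm, weight kg).
Expected diameters come from Turner-specific regressions,
`(expected)² = (a + b·BSA + c·BSA²)²` with (1.035, 0.589, −0.129) for the
aortic root and (0.942, 0.593, −0.122) for the ascending aorta; the square
root leaves |polynomial|, which is positive throughout the physiologic BSA
range (0, 2.3], so the absolute value never activates there (a flag can
disable it). The z-score is `(√actual − √expected)/√MSE` on the √cm scale.
The regression MSEs are not shipped with this package; the default of 0.01
is an explicit placeholder and must be replaced with the published values
for absolute z-scores on real measurements — all structural properties
(round trips, monotonicity, classification logic) are MSE-independent.

TAD is defined as any available z-score ≥ 1.9 after half-up rounding to one
decimal ("rounded to tenths" as the threshold itself is printed with one
decimal), so 1.85 qualifies and 1.84 does not. Subjects with neither vessel
measured raise an exclusion signal rather than returning a boolean. Any
aortic risk = BAV or coarctation or TAD. Missing data policy throughout:
each analysis drops subjects missing the needed fields and reports its own
N; nothing is imputed (except PCA-internal mean imputation, below).

## Variant QC

The filter chain removes variants with genotyping rate below 99%, subjects
with more than 5% missing genotypes, and markers failing the exact
Hardy–Weinberg test at 1×10⁻⁶. The HWE test conditions on allele counts and
sums probabilities of heterozygote counts no more probable than observed,
computed by the stable log-recurrence (verified against brute-force
enumeration). Every stage reports input/removed/retained so the identity
`input − removed = retained` is auditable end to end.

For PCA, common variants (MAF > 5%) are LD-pruned greedily: within each
50 kb physical window, the later variant of any pair with genotype r² > 0.2
is dropped (lower position wins ties), stepping five variants at a time.
Genotype columns are mean-centred, scaled by √(2p(1−p)), and missing calls
mean-imputed for the decomposition only. Subject eigenvectors come from an
SVD; signs are fixed by making the largest-magnitude loading positive so
results are deterministic. Outlier removal iterates: subjects with
EV1 < −0.3 and EV2 > 0.3 (a joint quadrant cut; both cuts are configuration
and are sign-convention dependent) are removed and the PCA recomputed until
no outliers remain or the iteration cap is hit, with the removed ids
recorded per round.

## Gene-based association

Variants map into every overlapping gene interval (a variant may belong to
several genes). The null model is a logistic regression of the outcome on
covariates (typically EV1–EV3, optionally an aortic z-score); residuals are
`y − p̂`. For a gene with genotype matrix G (missing calls imputed to twice
the sample allele frequency) and weights `w_j = Beta(MAF_j; 1, 25)`:

    Q_ρ = (1−ρ)·Σ_j w_j²(g_jᵀr)² + ρ·(Σ_j w_j g_jᵀr)²

over the grid ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}. ρ = 0 is the
pure variance-component kernel statistic, ρ = 1 the pure burden statistic.
Calibration is by permutation: the residual vector is permuted jointly for
all ρ, per-ρ p-values are computed for the observation and for every
permutation, and the omnibus p-value is the permutation tail probability of
the minimum per-ρ p (`p = (1 + #{perm ≤ obs})/(B+1)`, so `p ≥ 1/(B+1)` by
construction). Permutation was chosen over moment-matching/Davies-type
analytic approximations because it is exact at cohort scale (n ≈ 188),
assumption-free, and cheap with vectorized score computation. Monomorphic
genes return p = 1 with a note; separated or constant-outcome null fits
raise a typed error so callers can skip the gene with a reason.

Whether a continuous aortic z-score enters as a covariate of the
dichotomous-BAV model or as a second outcome is genuinely ambiguous in
practice; this package implements the covariate reading as the default and
leaves the choice to the caller, asserting neither as canonical.

The exome-wide threshold is Bonferroni `α/n_genes` (0.05/19,392 =
2.578×10⁻⁶ at the conventional exome gene count). Q-Q data pair sorted
observed p-values with `(i−0.5)/n` expected quantiles.

## Candidate ranking and variant annotation

An Xp gene qualifies as a hemizygosity-sensitive aortopathy candidate when
it is not a pseudogene, has no Y homologue, and is expressed in the aorta;
qualifying genes rank with known aortic-valve-development genes first, then
by descending aortic expression (median RPKM), with a lexicographic
tie-break for determinism. XCI status is carried as metadata and not used
as a sort key by default (escape status varies across the informative
ranks); `require_escape=True` restricts to Variable-escape genes. The
packaged 16-gene annotation table reflects the published candidate set led
by *TIMP1* (expression 423.6, valve-development role known).

Variants are flagged likely-deleterious at CADD PHRED ≥ 15 (inclusive).
Case/control allele tests count ALT alleles over 2N chromosomes per group
and use a Pearson chi-squared on the 2×2 allele table.

## Risk models

2×2 tables are oriented so OR > 1 means exposure enriched among affected.
The point estimate is the cross-product ratio with a Woolf (log-scale) 95%
interval; any zero cell triggers the Haldane–Anscombe +0.5 correction with
a surfaced flag, and a zero diagonal is reported undefined (as clinical
tables print "-"). Association p-values use chi-squared with Yates
correction when every expected cell count (row·column/total) is ≥ 5,
otherwise a two-sided Fisher exact test. Continuous attributes use the
pooled-variance two-sample t-test. A single-binary-predictor logistic
regression reproduces the cross-product OR (verified to 1e-5) with a Wald
interval; Wald and Woolf intervals differ legitimately, so table
reproduction targets point estimates. Display rounding is two decimals for
ORs and percentages.

The combinatorial analysis crosses rs11547635 carriage with the TIMP1
copy-number group into four groups, with no-SNP/>1-copy as reference;
groups below a minimum size (default 5) or with a zero diagonal get no
estimate. For the BAV-with-TAD outcome, subjects without any aortic
measurement are excluded. Where a published table's group total must be
recovered from an affected count and a printed percentage,
`reconstruct_total` inverts the percentage (e.g. 20 affected at 80.00% →
N = 25).

## Synthetic cohorts

The generator's defaults are the published cohort conditions: the
188-subject clinical karyotype spectrum (with per-class copy numbers),
*TIMP3* genotypes in Hardy–Weinberg at control allele frequencies
(rs11547635 at 0.035), mean exome depth 71 (Poisson; negative-binomial
overdispersion is available but off by default), heights
N(142.6, 15.6²) cm and weights N(55.8, 20.1²) kg truncated at physiologic
bounds, and aortic-measurement availability of 113/188 (root) and 106/188
(ascending). BAV risk follows
`logit(p) = logit(6/33) + log(3.97)·[1 copy] + log(4.50)·[carrier] +
log(1.0)·[both]`; this trio reproduces the four published combinatorial
group prevalences (18.18%, 46.88%, 50.00%, 80.00%). Latent z-scores are
Normal with BAV-dependent shift (root +0.98, ascending +1.44) and
published group SDs; diameters are the exact inverse of the z-score
equation so re-scoring recovers the latent z to 1e-9. X-site classes
default to (hom-REF 0.45, het 0.30, hom-ALT 0.25), chosen to produce the
three visible allele-balance bands; the real site composition of an exome
capture is not published. Het-site phase (which haplotype carries ALT) is
Bernoulli(0.5) per site. Ancillary phenotypes (lymphedema, webbed neck,
coarctation, ...) are drawn at cohort marginal prevalences independent of
genotype, which makes null-bias tests of the risk tables possible. All
randomness derives from one seed through named substreams, so stages can be
regenerated independently and identical seeds give byte-identical outputs.

What the generator does **not** emulate: read-level error and mapping
artifacts (hom sites have exactly 0/1 allele balance), LD between panel
variants, autosomal structural rearrangements, relatedness, and
correlation between morphometrics and karyotype class. Passing tests on
synthetic cohorts therefore demonstrate the correctness and calibration of
the statistical machinery under the stated generative model, not
performance on raw sequencing artifacts.

## Numerical choices and problem sizes

Band-window boundaries place sites at exactly 0.5 in both bands (each then
implies f = 0). Copy numbers are rounded half-up with a 1e-12 guard against
float representation. The acceptance checks run at desk scale chosen to
keep the full suite under a minute apart from the calibration studies:
mosaicism recovery at 9 × 50 replicates (200 sites, depth 70), type-I-error
calibration at 500 null genes × 999 permutations (n = 188), and effect
recovery at 200 cohorts of n = 5,000. Exome-scale inputs (~195k variants)
are supported by the same code paths; the LD-pruning and HWE loops are the
only stages whose cost grows noticeably, both linear in variant count.

## Known limitations

- Absolute z-scores require the unpublished regression MSEs; the 0.01
  placeholder preserves structure only.
- The mosaic-fraction estimator assumes the 45,X/46,XX two-band model;
  45,X/47,XXX and structural-X mosaics violate it and rely on the clinical
  karyotype override.
- Y mosaicism is detected, never quantified.
- The ISCN parser covers the clinical dialect above, not full ISCN.
- PCA outlier cuts are sign-convention dependent; the defaults assume the
  fixed-sign convention described here.
- Copy numbers for karyotypes without printed cell-line fractions are
  bounds-midpoints, not measurements.
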