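# Methods

## Data model

Genotypes are biallelic SNP calls coded by allele-B count (0 = AA,
1 = AB, 2 = BB, −1 = missing) in a samples × markers matrix with a marker
map (id, chromosome, bp position, alleles) and per-sample breed, sex and
case/control phenotype. PLINK text PED/MAP is the interchange format;
phenotype codes 1/2 are control/case, 0 and −9 missing. The writer emits a
BIM-style 6-column map (both alleles included) so a write→read round trip
preserves the coding exactly; plain 3/4-column MAPs are read with a
deterministic fallback — allele A is the first allele symbol encountered
in file order. Merging cohorts intersects marker sets, flips
complement-coded markers into the first cohort's orientation, and errors
on genuinely different allele pairs.

## Association scan and IUT meta-analysis

The per-breed test is the Pearson 1-df chi-square on the 2×2
case/control × allele-count table, no continuity correction, no
covariates. Markers with a zero row or column margin (monomorphic, or an
empty class) are *invalid*: retained in output, excluded from p-value
summaries, and — crucially — excluded from the count of valid tests that
sets downstream thresholds.

For each breed subset S (|S| ≥ 2) a marker is a valid IUT test iff every
member's test is valid. Two combined statistics are computed per marker:

* `max_p` — the intersection-union omnibus p-value, max over members;
  it rejects only when every component rejects.
* `fisher_p` — Fisher's combined probability, −2 Σ ln pᵢ referred to
  χ²(2|S|); the breeds are treated as independent cohorts.

Significance is called on `fisher_p` at the per-set Bonferroni threshold
α / n_valid(S) with α = 0.05, using ≤ (a marker exactly at threshold is
significant). `max_p` is always reported alongside; a strict mode
additionally requires `max_p` ≤ threshold. Each set gets its own
threshold because validity varies by set — with breed-specific fixation,
the three-breed set has fewer valid tests than any pair.

A component p of exactly 0 would make Fisher's statistic diverge; the
combined p is returned as 0 with a warning.

## Firth-penalized logistic regression

Risk models are fitted with no intercept on class-variable designs: each
marker contributes indicator columns for its observed non-reference
genotype levels (reference AA), plus an explicit "missing" level when
missing calls are present (keeping n constant across multi-marker
models); cohort and sex enter the generalized models as class indicators.
Constant and duplicate columns are pruned with a log record.

Estimation maximizes the Jeffreys-penalized likelihood
l(β) + ½ ln det I(β). Newton iterations use the modified score
U\*ᵣ = Σᵢ (yᵢ − πᵢ + hᵢ(½ − πᵢ)) xᵢᵣ with hat diagonals
h = diag(W^{1/2}X(XᵀWX)⁻¹XᵀW^{1/2}); step-halving (up to 25 halvings)
enforces a non-decreasing penalized log-likelihood. The penalized
estimate exists and is finite for any design with both classes present,
including separated data where ML diverges.

Numerical choices: tol = 1e-8 on both the max score component and the
step norm, max_iter = 50. On ill-conditioned class designs (e.g. a
genotype level carried by one sample) the achievable gradient floor in
double precision can sit slightly above 1e-8 while the penalized
log-likelihood is already stationary to < 1e-12; three consecutive
stationary iterations with gradient < 1e-5 are therefore accepted as
converged. Wald CIs use the inverse Fisher information at the estimate.

Separation is diagnosed by two linear programs: maximize the worst
margin of z·Xb over ‖b‖∞ ≤ 1 (positive optimum ⇒ complete separation),
then maximize the total margin subject to non-negative margins (positive
optimum ⇒ quasi-separation). Flags attach to the columns supporting the
separating direction; flagged odds-ratio rows keep their finite Firth
point estimate but are marked non-estimable ("suggestive of large
effects") — large ORs under separation are directionally informative but
their magnitudes should not be read literally.

## Model selection

**Stepwise forward** (α_enter = α_remove = 0.05): marker terms enter and
leave as whole blocks of genotype-level columns. The block test is the
penalized likelihood-ratio test with the reduced model *constrained
within the full design*: the block's coefficients are fixed at 0 while
the Jeffreys penalty is still evaluated on the full design's information
matrix. This matters — comparing penalized log-likelihoods of designs
with different column counts carries a dimension bias from the penalty
(½ ln det I grows with every added column), which makes the naive test
anti-conservative enough to select several null markers per run. With the
constrained form, all-null candidate pools yield ~0.5 selected terms out
of 20 on average. After each addition, included blocks whose p rose to
≥ α_remove are removed (largest first); ties break by candidate order;
a state-repeat guard prevents add/remove cycles.

**LASSO/AIC**: the no-intercept L1-penalized logistic path
(−l(β)/n + λ‖β‖₁) over 100 log-spaced λ from λ_max (computed from the
gradient at β = 0, where all π = ½) down to λ_max·10⁻⁴, warm-started
from large to small λ (scikit-learn's saga solver behind the module
surface). Columns are scaled to unit variance before penalization (no
centering — there is no intercept) and coefficients returned on the
original scale. Each indicator column is penalized separately (no group
penalty); a marker is selected if any of its columns is nonzero. The
model is chosen by lowest AIC = 2k − 2l with k the nonzero count and l
the *unpenalized* log-likelihood at the penalized estimate; ties break
toward larger λ. The chosen support is then refitted by plain Firth — no
further selection — to produce the final coefficients and OR table.

## Evaluation and validation

With no intercept, the null model is β = 0 (all π = ½), so
l₀ = n·ln ½. Cox–Snell R² = 1 − exp(−(2/n)(l₁ − l₀)) and max-rescaled
R² divides by its maximum 1 − exp((2/n) l₀); l₁ is the unpenalized
log-likelihood at the Firth estimate (an intercept-containing null would
change the numbers — a documented convention, not an estimate of the
same quantity). AIC = 2k − 2l₁ on the same likelihood scale as the LASSO
path. Hosmer–Lemeshow uses 10 near-equal groups of sorted fitted risk
with ties kept together; degenerate groups (E = 0 or E = n) merge into a
neighbor with the df adjusted; df = groups − 2. Percent correct uses a
fixed 0.5 cutoff with strict ">". Validation is refit-validation: the
fixed selected term set is refitted by Firth on the independent cohort
(no selection, no coefficient transfer) and the same statistics
reported.

## Epistasis scan

For every unordered candidate pair, ordinary ML logistic regression (with
intercept) of case status on the two allele-dosage codes and their
product; the reported p is the Wald test of the product coefficient.
Dosage coding — not class coding — keeps the scan identical to the
standard single-df interaction test; ML rather than Firth because a
diverging (separated) interaction fit is evidence the pair is not
testable, and such pairs are flagged and excluded from the Bonferroni
denominator (α / n_testable). All pairs are fitted simultaneously by a
batched Newton solver (per-pair masks handle pairwise missing-genotype
exclusion); per-pair statsmodels fits reproduce it to ~1e-6 and serve as
the independent check in the tests.

## Breed clustering

UPGMA (arithmetic average linkage) on Euclidean distances between breed
allele-B-frequency vectors at the candidate markers. The metric is a
package choice — average linkage defines the agglomeration, not the
distance. Breeds with fewer than 5 genotyped individuals are excluded;
missing frequencies are imputed by column mean with a logged count. Merge
heights are monotone and the cophenetic matrix ultrametric; the tree is
exported as Newick with leaf depth = merge height / 2.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical design* of a three-breed
case/control array study: fixed cohort sizes (153/114, 28/62, 80/55
cases/controls by default), breed-specific allele frequencies drawn
Beta(2, 2) per breed, optional breed-specific fixation of null markers
(25% in the canonical scenarios — closed breeds are extensively fixed,
and this is what drives the per-set valid-test counts), Hardy–Weinberg
genotypes within breed, a per-genotype-level logistic disease model
(separate het/hom odds ratios, matching the class-variable fitting
convention), case/control quota ascertainment (individuals drawn until
quotas fill; `baseline_log_odds` tunes draw efficiency, not prevalence
realism), 50/50 sex with an optional sex effect, and uniform random
missing calls. Planted loci can pin per-breed risk-allele frequencies;
the power and recovery scenarios pin 0.3, the common-variant frequency
their effect calibrations are computed at — with frequencies drawn from
the prior, a near-0.05 draw makes any fixed OR statistically
undetectable at these cohort sizes, so unpinned frequencies would test
the draw rather than the method.

It does **not** emulate linkage disequilibrium between markers (markers
are independent; the pipeline treats peak SNPs as independent
predictors), within-breed population structure or relatedness (the
mixed-model correction such structure requires belongs to the upstream
GWAS, not to this pipeline), genotyping batch effects, or informative
missingness. Passing tests therefore demonstrate the statistical
machinery is correct under the stated design — not that real-data
results are free of confounding handled upstream.

Determinism: every generator stream derives from the config seed;
identical configs give bit-identical cohorts.

## Canonical scenarios and problem sizes

`breedgwas.scenarios` freezes the study conditions used by the tests and
the acceptance script:

* *null_three_breed* — no effects, 10⁴ markers, 25% per-breed fixation;
  family-wise error measured over 100–200 replicates per breed set.
* *shared_modest_effect* — one locus in all three breeds with allelic
  ORs 1.95 / 3.6 / 2.55 (log-additive per genotype, frequency 0.3),
  calibrated so each breed's expected allelic z ≈ 3.3 (typical
  within-breed p ≈ 10⁻³): detectable by the three-breed Fisher
  combination, far from any single breed's genome-wide threshold. A
  structural note: the joint per-replicate event {Fisher-significant and
  no single breed significant} is capped near 50–60% under any such
  calibration, because all three per-breed z-statistics carry unit
  sampling standard deviation — the Fisher sum needs Σz² large exactly
  when the no-single-hit condition needs every z² small. The package
  reports both the joint rate and the marginal Fisher power.
* *greyhound_strong_locus* — OR_hom = 5 (log-additive) among 19 nulls at
  the Greyhound size, frequency 0.3; stepwise recovery ≥ 95/100.
* *or3_recovery* — OR_hom = 3 at n = 5000/5000; 95% Wald CI coverage of
  ln 3 over 100 replicates.
* *marginal_effects_candidates* — 34 markers with marginal effects only
  (allelic ORs cycling 1.2–1.8 in all breeds), no interactions; the
  epistasis scan over all 561 pairs should pass Bonferroni in no pair in
  ≥ 95% of replicates.

Replicate counts (100–200) and marker counts (10⁴ for genome-scale
scenarios, panel-sized elsewhere) are the package's chosen problem sizes:
large enough for the binomial tolerances quoted above, small enough to
re-run routinely on one CPU.

## Known limitations

* The allelic chi-square is asymptotic; in small cohorts with rare
  alleles its extreme tail is mildly anti-conservative, which can nudge
  measured family-wise error slightly above nominal at genome-wide
  thresholds (exact tests are out of scope, matching the reference
  procedure).
* Indicator (dummy) coding with AA reference is used for class variables;
  software that defaults to effect coding will report different (but
  transformable) coefficients, so numeric OR comparisons across
  implementations require matching the parameterization.
* Wald CIs are reported for all terms; under separation they are flagged
  rather than replaced (profile-penalized CIs are a possible extension).
* The LASSO df used in AIC is the nonzero-coefficient count — the lasso
  degrees-of-freedom convention — applied to indicator columns without a
  group penalty.
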