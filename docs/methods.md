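# Methods

## Labels, bins and strata

Ground truth is the variant's in-vitro activity, expressed as intrinsic
clearance relative to the wild-type allele (dimensionless; values above 1
— gain of function — are allowed). A variant is **deleterious** when its
activity is reduced more than 2-fold, i.e. strictly below 0.5; an
activity of exactly 0.5 is neutral. Graded evaluation uses four activity
bins: loss-of-function `[0, 0.10)`, decreased `[0.10, 0.50)`, moderate
`[0.50, 0.90]`, neutral `(0.90, ∞)`. The boundary conventions follow the
strict readings "< 10%" and "> 90%"; 0.50 falls in *moderate* because
deleterious requires a strictly more-than-2-fold reduction. Minor allele
frequencies are stratified as very rare (< 0.1%), rare (0.1–1%) and
common (≥ 1%); records without a MAF are dropped from the MAF
stratification only. Three-level label overrides are supported through an
optional `label_override` column (used, e.g., to force named common
variants to neutral) rather than hard-coded variant lists.

## Threshold calibration

Each algorithm is calibrated independently on the variants for which it
produced a score (per-algorithm complete case). Calls are strict
inequalities in the algorithm's fixed orientation. The calibrated cutoff
maximizes the Youden index J = sensitivity + specificity − 1, which
weights the two error types equally and is therefore insensitive to the
class imbalance of activity datasets.

Candidate cutoffs come from one of two policies:

- **midpoints** (default): one candidate between every pair of adjacent
  distinct scores, plus one candidate half the smallest gap beyond each
  extreme. This enumerates *every* achievable operating point, so the
  returned optimum is exact, and it makes the strict-versus-non-strict
  inequality choice immaterial.
- **fixed_grid**: an arithmetic grid of a user-chosen step over the
  observed range, for comparability with grid-based protocols. It is
  dominated by midpoints by construction (property-tested).

Tie-breaking when several candidates attain J_max: highest sensitivity
first; remaining ties go to the smallest threshold for
deleterious-if-greater methods and the largest for deleterious-if-less —
either way the wider deleterious-flagged region, the conservative choice
for a screening tool. Degenerate inputs (fewer than two distinct scores,
or a single class) raise typed errors rather than returning a vacuous
optimum, and cross-validation skips such algorithms on the affected fold.

Calibration quality is reported as ΔI (J at the calibrated cutoff minus J
at the conventional literature cutoff, on the same variants; unavailable
for PhyloP/PhastCons, which have no literature cutoff) and as the
absolute coefficient of variation of the fold-optimal thresholds. |CV|
uses the sample (n−1) standard deviation, appropriate for the small
number of folds (default 5).

## Consensus model and combination search

The consensus score of a variant is the arithmetic mean of the available
components' binary calls (deleterious = 1, neutral = 0); components
without a score abstain, and the score is missing only when every
component abstains. The variant is flagged deleterious when the score
reaches the call cutoff (default 0.5); a score of exactly 0.5 is flagged
— again the conservative screening choice.

The component subset is chosen by exhaustive enumeration of all
2^m − 1 non-empty subsets, vectorized over bit-mask blocks (the full
18-method panel, 262,143 subsets, takes on the order of a second). The
default objective is the informedness of the consensus calls. The
sum-of-agreement criterion Σᵢ Σₗ s(l, i) — where s(l, i) = 1 when
component l's call on variant i matches the label — is monotone
non-decreasing in subset size when left unnormalized and would always
select the full panel; it is therefore exposed in its normalized form
(`mean_component_correctness`: mean correctness over available
(component, variant) pairs, which for a singleton reduces to that
algorithm's accuracy on its non-missing calls), alongside
`consensus_accuracy`. Ties between subsets are broken toward the smaller
subset, then lexicographically by algorithm name, with a 1e-12 numeric
tolerance for float comparisons.

## Cross-validation and aggregation

Variants are partitioned into k stratified folds (default k = 5) by a
seeded per-class shuffle followed by round-robin dealing, so per-fold
class counts differ by at most one. Per fold, thresholds are calibrated
and the subset selected on the training split only; the fold model is
then scored on the held-out fold. The aggregated model uses per-algorithm
thresholds averaged (arithmetic mean) across folds and the modal fold
subset (ties toward smaller, then lexicographic). Fold summaries report
mean ± SD of sensitivity, specificity, accuracy and J. All randomness
flows from a single integer seed; repeated runs are bit-reproducible, and
CLI outputs carry no timestamps so identical invocations are
byte-identical.

The fixed published five-component model (LRT < 0.0025,
MutationAssessor > 2.0566, PROVEAN < −3.286, VEST3 > 0.4534,
CADD > 19.19, cutoff 0.5) is available independently of any training run.

## Evaluation surfaces

`evaluate` reports: overall confusion metrics and J; per activity bin the
count, flagged fraction, and mean ± s.e.m. consensus score (s.e.m. with
the n−1 standard deviation); metrics restricted to the activity extremes
(LOF vs neutral); MAF-stratified metrics; per-algorithm and model-level
unpredicted fractions; and an ordinary least-squares regression of the
per-bin mean score on the bin midpoints (0.05, 0.30, 0.70, 0.95) with
slope, intercept, R² and p-value. The four-point regression is an
intentionally coarse summary of how quantitatively the score tracks
activity; it is reported as such, not as a per-variant model. Empty
strata are reported with n = 0 and their undefined metrics as null,
never silently as zero.

## Synthetic data generator

The generator emulates the structure of a pharmacogenetic benchmark
table: 337 variants by default, activity drawn per bin with weights
(0.32, 0.27, 0.20, 0.21) so that roughly a third are complete
loss-of-function and a fifth neutral (the lof and neutral weights match
the 109/337 and 71/337 composition typical of curated ADME activity
sets; the decreased/moderate split of the remainder is a fixed design
choice), uniform activity within each bin (neutral activities extend to
1.2 to include mild gain of function), and MAF log-uniform over
10⁻⁵–10⁻⁰·⁵ so most variants are rare.

Scores follow an equal-variance binormal model on a raw standard-normal
scale: a variant scores N(d·severity, 1) with severity = clip((0.9 −
activity)/0.8, 0, 1) — exactly 1 below 10% activity and exactly 0 above
90% — and d = √2·Φ⁻¹(AUC) per algorithm. On the extreme bins the model
is therefore exactly binormal with separation d, giving closed-form
oracles: optimal raw cutoff d/2, maximal J = 2Φ(d/2) − 1, AUC = Φ(d/√2).
The graded severity in between makes partially functional variants
receive intermediate scores, as real predictors do. A shared standard
normal latent factor with loading √ρ (default ρ = 0.3) models the
correlation real predictors inherit from shared conservation features.
Raw scores are negated for deleterious-if-less algorithms and mapped
affinely onto each algorithm's nominal range (raw support padded by 4
sd); per-algorithm Bernoulli missingness is applied afterwards, keeping
at least one score per record. The default 18-method panel mirrors the
real registry's names, orientations and score ranges, with target AUCs
spanning 0.51–0.81 and 5% missingness for the three methods that
typically fail to score some variants. Each synthetic algorithm also
carries an intentionally off-optimum "conventional" cutoff (the mapped
neutral-class mean) so that ΔI reporting is exercised.

What the generator does **not** emulate: sequence context, gene
identity, substrate-specific activity, real allele-frequency spectra,
heavy-tailed or multimodal score distributions, and
algorithm-specific error structure beyond a single shared latent factor.
Passing tests on synthetic data therefore demonstrate the correctness of
the calibration/selection/evaluation machinery under a known model, not
the field performance of any particular predictor panel.

## Problem sizes and tolerances

Oracle-equivalence checks run on ≥ 100 random instances of n ≤ 50
(thresholds and AUC) and 20 instances with up to 6 algorithms
(combination search), where exact agreement (1e-12) with brute-force
enumeration is required. Parameter-recovery checks use 2,000 variants
per class for the d = 2 binormal cutoff (tolerances 0.15 on the cutoff,
0.04 on J) and 10,000 variants for per-algorithm AUC calibration
(tolerance 0.02). Cross-validation behavior is exercised on 250–400
variant panels over 10 seeded replicates. The acceptance script uses the
same sizes and a 337-variant benchmark run.

## Known limitations

- Threshold averaging across folds assumes fold optima estimate a common
  operating point; for unstable algorithms (large |CV|) the averaged
  threshold can sit far from any fold's optimum. The |CV| table makes
  this visible rather than correcting it.
- The consensus treats components as exchangeable votes: no weighting,
  no correlation adjustment, no abstention penalty.
- The exhaustive search optimizes in-sample training informedness per
  fold; with many near-equivalent subsets the modal-subset aggregation
  can be sensitive to fold composition.
- No confidence intervals on AUC or J are provided.
- Genomic coordinates are carried as metadata only; no liftover or VCF
  handling.
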