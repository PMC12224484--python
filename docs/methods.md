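# Methods

This note documents the generative model behind the synthetic cohorts, the
statistical procedures of the analysis pipeline, the defaults and why they
were chosen, and the limits of what the synthetic evaluation can show.

## The synthetic cohort generator

The generator (`connclass.cohort`) is first-class, tested code, not a test
fixture: it defines the conditions under which the pipeline's statistical
contracts (chance level, effect recovery, calibration) are evaluated.

### Covariates, trauma score, liability

Per subject: age ~ Uniform(45, 80) years; sex Bernoulli(1/2); intracranial
volume normal per sex (female 1.34×10⁶ ± 1.1×10⁵ mm³, male 1.50×10⁶ ±
1.2×10⁵ mm³, typical adult magnitudes); a comorbid-disorder exclusion flag
with probability 0.02.

The abbreviated CTQ score is the mean of five item scores in [0, 1]. A
latent severity m is drawn from a zero-inflated Beta — P(m = 0) = 0.27,
otherwise Beta(0.43, 1.57) — and the five items are i.i.d.
Beta(κm, κ(1−m)) with concentration κ = 25, so the items scatter tightly
around m and their mean inherits its distribution. The zero inflation
reproduces the large no-reported-trauma group seen in community samples;
the sub-unit Beta shape parameter gives the long right tail that makes the
conventional 0.2/0.4/0.6 thresholds meaningful.

All six phenotype definitions are driven by one latent liability

    L = 0.28·(±1 for female/male) + 1.5·(CTQ − mean CTQ) + 0.9·ε,  ε ~ N(0,1),

which is approximately standard normal marginally. The three coefficients
were calibrated jointly (once, by Monte-Carlo at n = 4×10⁵) so that at the
default thresholds:

* the broad "ever" definition has ~23% prevalence with a ~2:1
  female-to-male case ratio;
* among "ever" cases the CTQ thresholds 0.2/0.4/0.6 fall near the
  50th/70th/80th percentile of the case CTQ distribution (so a 0.2
  threshold keeps about half the cases, 0.4 about 30%, 0.6 about 20%).

### Phenotype definitions

With t₁ = 0.74 and t₂ = 1.70:

| flag | rule |
|---|---|
| ever | L > t₁ |
| current | L > t₂ and current symptoms present (P = 0.274) |
| ever_severe | L > t₂ and current symptoms absent |
| recurrent | ever and ≥ 2 lifetime episodes (1 + Poisson(0.868) among ever) |
| drug | Bernoulli(expit(−3.895 + 1.5·L)) |
| mdd_narrow | Bernoulli(expit(−3.579 + 1.5·L)) |

This yields the expected nesting (current ⊆ ever, recurrent ⊆ ever via
t₂ > t₁) and nontrivial pairwise overlap among all definitions — with one
deliberate exception: `ever_severe` and `current` are **disjoint**, because
the severe definition requires current symptoms to be absent. The
generator follows that textual definition; the overlap convention for the
two flags is the one genuinely open modelling choice here, and the
disjoint reading was chosen because it is the only one the definitions
themselves support. Excluded subjects carry no flags. Severe prevalence
(L > t₂) is ~4.7%, of which ~27% are "current", so a default-sized cohort
needs roughly 100× more subjects than the desired number of current cases.

### Functional connectomes

Each subject has a population correlation matrix over the 55 nodes built on
the Fisher-z scale: within-subnetwork z = atanh(0.30), between-subnetwork
z = atanh(0.05), plus a subject-level random intercept per unordered
subnetwork-block pair, N(0, 0.15²) on the z scale. The block random effect
is what keeps between-subject variance realistic: without it, edge values
would differ only by time-series sampling noise (SD ≈ 1/√(T−3) ≈ 0.07) and
even small planted effects would be trivially separable. For case subjects
(under the configured effect phenotype) the target blocks shift by
delta·(1 + ctq_slope·CTQ) on the z scale; defaults delta = 0.5,
ctq_slope = 0.5, target block = within-VN, effect phenotype = "current".
The trauma amplification makes CTQ-thresholded case groups carry larger
effects, mirroring the hypothesis the CTQ analyses probe. The matrix is
mapped back through tanh, repaired to the nearest correlation matrix by
eigenvalue clipping at 10⁻⁶ (the repair is a no-op for default parameters),
and T = 200 multivariate-normal samples are drawn.

The observed **full** matrix is the Fisher-z of the sample correlation; the
**partial** matrix is the Fisher-z of partial correlations from the
Tikhonov-regularised inverse (R + ρI)⁻¹ with ρ = 0.5, the standard netmats
ridge default. Both are exactly symmetric with zero diagonal.

Connectome simulation is seeded per subject from (cohort seed, stream,
subject index), so simulating any subset of subjects — e.g. only the
matched sample — reproduces bit-identical matrices.

### Structural connectomes

A shared base topology (Erdős–Rényi, edge probability 0.6 over the 85
nodes) is drawn once per cohort; each subject retains each base edge with
reliability 0.9, and absent edges are exact zeros — this is what makes
group proportional thresholding meaningful. Edge weights are log-normal:
log w = (per-edge factor shared across channels, SD 0.4) + (channel noise,
SD 0.4), giving six positively correlated weighting channels. Case
subjects get a log-weight shift delta_s·(1 + ctq_slope·CTQ) (default
delta_s = 0.3) on edges among the first 10 nodes. The channels are
abstract correlated weightings, not biophysical models of FA/MD/NODDI
parameters; the classifier only consumes edge weights.

### What the generator does not emulate

Site/scanner effects, age- or sex-dependent connectivity gradients,
heavy-tailed motion artefacts, non-Gaussian BOLD dynamics, and any
quantitative match to real-world effect sizes (real MDD effects are far
smaller than the default planted delta). Passing tests therefore
demonstrate the *procedural* correctness and calibration of the pipeline —
leak-free cross-validation at chance under the null, recovery and FDR
control for block-concentrated effects — not expected accuracy on real
cohorts.

## Matching

Cases are processed in ascending id order; each takes the unused same-sex
control minimising |Δage|/σ_age + |ΔICV|/σ_ICV (σ over the full control
pool; ties to the smallest control id). The combination rule — a sum of
pool-standardised absolute differences with sex as a hard constraint — was
an open design point; it was chosen because it is scale-free and treats
the two continuous covariates symmetrically. Greedy matching without
replacement guarantees a 1:1 sample procedurally. The control pool is
restricted to subjects with no case flag under *any* definition.

## Nested cross-validation

The objective is stated as a **mean** log-loss plus λ‖β‖² with an
unpenalised intercept, so λ is comparable across sample sizes. Fitting is
delegated to scikit-learn's lbfgs logistic solver through the exact mapping
C = 1/(2nλ), with a first-order optimality check (gradient ∞-norm < 10⁻³
on the mean scale) after every fit; the λ grid (13 half-decade points over
[10⁻³, 10³]) is fitted warm-start along the ascending path.

The plan assigns matched *pairs* (never individuals) to 6 outer folds and,
within each outer-training set, to 5 inner folds, sizes differing by at
most one pair, so every split stays exactly balanced. Per inner fold, λ
maximising inner-validation accuracy is chosen, ties resolved toward the
stronger penalty (parsimony). Each of the 30 inner-optimal models is
evaluated on its outer test fold **as trained on its inner-training set**
(no refit on the full outer-training set): the procedure counts 30
evaluations, and this is the reading consistent with that count.
Z-normalisation is refitted on every inner-training set — the strictest
placement — and its statistics are reused unchanged for the validation and
outer-test transforms, so outer-test subjects never influence
normalisation or model selection. Zero-variance training columns
transform to exactly zero, so dead features get exactly zero coefficients.

## Important features, Jaccard, block aggregation

"Top 50%" is operationalised as rank ≤ floor(p/2) under descending |β|
with ties broken toward the smaller feature index — deterministic for odd
p and exact ties. Sign consistency requires an identical nonzero sign in
all 30 models. Under independent coefficients a feature survives with
probability ≈ 2·(1/2)³⁰, which is the basis of the selection-null test.

The Jaccard index treats two empty sets as identical (J = 1). Printed
values use half-up decimal rounding (0.15625 → 0.1563 at 4 decimals), the
convention the reference worked values follow.

The per-block aggregate β_norm is the sum of mean coefficients of the
important edges in the block divided by the total absolute mean-coefficient
mass of **all** edges. This formulation is a reconstruction — the
originating supplement is not available — chosen to reproduce the reported
behaviour (the sign gives the block's predictive direction; magnitudes are
small fractions). Users comparing β_norm magnitudes against externally
reported values should treat the formula as package-defined.

## Hypergeometric block tests

The branch rule is exact integer arithmetic (O·Ne ≤ K·S selects the lower
tail, including the boundary), and tails are evaluated through
`scipy.stats.hypergeom` log-CDF/log-SF before exponentiation; the test
suite verifies agreement with exact binomial-coefficient enumeration to
10⁻¹⁰ over every feasible configuration with Ne ≤ 21. Blocks with zero
capacity (diagonal of a singleton subnetwork) are excluded. The BH family
is the 21 block tests of one model — the per-model correction matching how
enrichment matrices are annotated; correcting across phenotypes or
modalities jointly is a stricter alternative the package does not impose.
The directional discrete test is conservative: under uniform random
selection the fraction of blocks with p < α stays at or below α.

## Problem sizes in the shipped tests

The end-to-end suites run at deliberately modest scales chosen as the
smallest sizes at which each contract is statistically meaningful: the
chance-level contract at 200 pairs (binomial SE on the 30-fold mean ≈ 1
point, against a ±3-point band); planted-effect recovery at 300 pairs × 5
replicates; the delta-monotonicity ladder at 100 pairs × 5 seeds, where the
default block random effect keeps accuracy off the ceiling so the ladder
(≈0.48, ≈0.70, ≈0.92, ≈0.97) is strictly informative; generator
calibration checks at n = 10⁴ subjects. The unit suites additionally use a
20-node, six-subnetwork configuration for anything that does not need the
full 55-node space.

## Known limitations

* The synthetic effect model is block-homogeneous; edge-heterogeneous
  effects within a block would spread coefficient mass differently.
* Greedy nearest-neighbour matching is order-dependent by construction
  (ascending case id); it is deterministic and audit-friendly, but not
  globally optimal in total distance.
* β_norm is a package-defined reconstruction (see above).
* Accuracy-vs-sample-size correlations across grid cells are descriptive;
  cells share the underlying cohort, so they are not independent samples.
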