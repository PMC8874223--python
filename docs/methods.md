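# Methods

## Model and variational family

The model treats a locus as an N×G genotype matrix X and T traits. Each of K
latent components represents one causal variant, selected by a categorical
one-hot vector φ_k shared across traits; a per-trait Bernoulli switch s_tk
(prior p0k) gates whether the component has any effect in trait t; the active
effect w_tk is Gaussian with its own Gamma-distributed precision α_tk, so
effect magnitudes are unconstrained across traits and variants; residual
precision τ_t is Gamma-distributed per trait.

Inference is coordinate-ascent variational inference (CAVI) on the
structured mean-field family

    q = Π_{t,k} q(w_tk | φ_k, s_tk) q(s_tk) q(α_tk) · Π_k q(φ_k) · Π_t q(τ_t)

where the effect prior is treated in its spike-and-slab form
(1−p0)δ₀ + p0·N(0, α⁻¹): the spike branch is a point mass at zero against
the prior's own atom, so it contributes neither second moments nor entropy.
Consequences used throughout:

* slab update — q(w_tk | φ_k=g, s_tk=1) is Gaussian with precision
  E[τ_t]·x_g'x_g + E[α_tk] and mean E[τ_t]·x_g'r / precision, where r is the
  expected residual of trait t excluding component k;
* evidence score — A_tkg = μ²/(2σ²) + ½(log σ² + E[log α_tk]) is the
  expected slab-vs-spike log evidence of variant g, combining the data gain
  with the KL cost of the slab factor;
* activity update — logit q(s_tk=1) = logit p0k + Σ_g q(φ_k=g)·A_tkg;
* causal-variant update — log q(φ_k=g) = log π0g + Σ_t q(s_tk=1)·A_tkg + c,
  the cross-trait evidence pooling that gives joint fine-mapping its power;
* precision updates — q(α_tk) = Gamma(a0 + γ/2, b0 + γ·E[w²]/2) with
  γ = q(s_tk=1) (the spike contributes zero); q(τ_t) = Gamma(c0 + N/2,
  d0 + E‖y_t − Xb_t‖²/2).

Every step maximizes the ELBO in its coordinate, so the ELBO is
non-decreasing across sweeps; the fitting loop raises an error if it ever
drops by more than 1e-4 (tested at 1e-6), which is the package's primary
guard against derivation or implementation errors.

All updates are written in the sufficient statistics X'X, X'y, y'y and N.
Summary-statistic mode replaces them with their RSS-likelihood counterparts
S⁻¹RS⁻¹ and S⁻²β̂ (S the diagonal of per-variant scales
s_i = sqrt(β̂_i²/N + σ̂_i²), R the LD matrix) and fixes the residual
precision at 1, since the scale matrix already absorbs the per-variant noise
level. The two modes therefore share one code path, which is why their
posteriors agree to high precision when the LD matrix is in-sample.

## Sweep order and initialization

Within a sweep, components are processed in order; for each component the
slab moments of all traits are updated first, then the shared φ_k, then the
activity probabilities, each against the current state of everything else.
Updating φ before s matters: at the null initialization φ is uniform, and an
activity update against a diffuse φ averages the evidence over all variants,
which is negative for any realistic locus — components would switch off
before ever localizing. With φ updated first, the concentrated
causal-variant posterior feeds the activity decision.

Initialization is null for the effects: all posterior effect means are 0,
τ_t⁻¹ starts at the sample variance of trait t (1 for standardized traits),
and the prior effect-size variance starts at α⁻¹ = 0.1 — a sensible scale
for standardized genotypes and traits, where single-variant effects rarely
explain more than ~10% of variance. Activity probabilities start at 1: every
component is provisionally active so that early sweeps can assign components
to signals (the Bernoulli update re-applies the sparse p0 prior every sweep
and switches unsupported components off within a few sweeps). Starting
activity at p0 instead starves φ of evidence and collapses the model on
signal and null data alike — the same pathology as the sweep order above,
and the reason both are fixed design decisions here.

Unused components end with diffuse φ (≈ π0) and activity ≈ 0, so K is an
upper bound, not a tuning parameter; K=20 is the default and K=10 is used in
the test grids (true causal counts ≤ 6).

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| K | 20 | upper bound on causal variants at the locus |
| p0k | 0.1 | prior activity probability per component and trait |
| π0 | 1/G | prior causal-variant probabilities |
| a0, b0, c0, d0 | 1e-6 | vague Gamma priors on α, τ |
| α⁻¹ init | 0.1 | initial prior effect-size variance |
| elbo_tol | 1e-6 | convergence tolerance on the ELBO |
| max_sweeps | 1000 | sweep cap |
| ridge | 1e-6 / 0.01 | LD regularization (in-sample / reference panel) |

Restarts (off by default, n_restarts=1) redraw each φ_k from a flat
Dirichlet with per-restart seeds and keep the maximum-ELBO fit; the
component-to-signal assignment is the only label-switching degree of freedom
worth exploring. Monte-Carlo estimation of the q(φ) expectations (stochastic
inference for very large variant sets) activates automatically in summary
mode above G=5000, with 100 samples per component per sweep and a fixed
seed; exact expectations are the default everywhere else. No damping is
applied to any update.

## Reported quantities

* 95% credible set per component: the smallest variant set whose φ mass
  reaches 0.95 (ties broken by variant order).
* PIP per trait: 1 − Π_k (1 − s_tk·φ_kg), the standard inclusion–exclusion
  over single-effect components.
* Colocalization per trait pair: per component, the mean-field product
  s_{t1k}·s_{t2k} (a min-rule alternative is available by flag);
  "any-component" colocalization calls a pair when some component's joint
  probability passes 0.5, "top-component" when the two traits agree on the
  component holding their strongest credible-set variant by
  |p_active × effect/sd|, ties to the lower component index.
* An optional credible-set purity filter (min pairwise |r| ≥ 0.5) exists but
  is off by default.

## Synthetic data

Genotypes are diploid dosages from 2N haplotypes simulated as binary Markov
chains: within an LD block (block lengths geometric, mean 50 variants)
adjacent alleles correlate at the block's strength, drawn between 0.7 and
1.0 of the `ld_decay` parameter (default 0.9); chains restart at block
boundaries. Allele frequencies are uniform on (0.05, 0.5). This reproduces
the high- and low-LD regimes relevant to fine-mapping — including pairs of
distinct variants at controlled r² for the LD-confusion design — but not
real-genome features such as recombination hotspot structure, allele
frequency spectra, or population stratification; passing tests demonstrate
statistical correctness of the method under the stated generative model,
not performance on any particular cohort.

Trait designs:

* two-group — traits are shuffled and split between two groups with disjoint
  causal sets (q variants each, all pairwise r² ≤ rmax², default 0.8);
  each trait draws its own effects, frequency-scaled N(0, 1/(p(1−p)));
  the residual variance solves ρ = Var(Xb)/(τ⁻¹ + Var(Xb)) exactly from the
  realized genetic variance, so the variance-explained identity holds on
  every dataset, not just in expectation;
* random-sharing — q=10 causal variants each assigned to each of T=10 traits
  independently with probability 1/5 (two causal variants per trait and two
  traits per variant on average);
* LD-confusion — two one-causal groups whose causal variants sit at a
  controlled pairwise r² band, measuring false-positive colocalization as a
  function of LD between truly distinct causal variants;
* expression model — Y = Σ b_i x_i + ε on standardized genotypes with
  b_i ~ N(0, 0.1/n) and ε ~ N(0, 0.9): 10% total heritability split over n
  causal variants;
* alternative effect models — normal-mixture (variance drawn from
  {0.01, 0.05, 0.1, 0.5} per causal variant, residual variance fixed at 1,
  standardized genotypes) and point-mass effects at ±sqrt(2α⁻¹/π), the mean
  absolute value of the corresponding normal, with random sign.

Marginal summary statistics are per-variant simple linear regressions with
intercept (slope, SE via residual variance on N−2 degrees of freedom).

## Evaluation conventions

FDP = FP/(FP+TP), defined as 0 when nothing is called positive; power =
TP/(TP+FN). Credible-set coverage counts a set as covered when it contains
at least one truly causal variant; only sets of active components (max
p_active ≥ 0.5) are scored. Colocalization truth for a trait pair is a
non-empty intersection of their causal sets.

## Problem sizes in the test suite

The recovery grid runs T=4, q ∈ {1,2,3}, ρ ∈ {0.05, 0.1, 0.2} at N=500,
G=1000 with 20 seeds per cell and K=10; mode concordance uses N=500, G=200,
T=3, q=2, ρ=0.1 over 20 seeds; LD-confusion 50 seeds per band at G=300;
null calibration 50 seeds at N=300, G=100; the enumeration oracle 20
instances at N=100, G=4, T=2. The calibration script pools 2,000 expression
replicates (t1, t2) and 1,000 random-sharing replicates (t3).

## Numerical choices and degenerate inputs

Slab variances are floored at 1e-12; activity logits are clipped at ±700
before the sigmoid; φ updates use log-sum-exp. p0k ∈ {0, 1} short-circuits
the activity update exactly. Constant genotype columns are dropped (with a
warning) at standardization; exact duplicate columns are retained and
legitimately split φ mass. Reference-panel LD is ridge-regularized,
(1−λ)R + λI with the diagonal renormalized to 1 (eigenvalue clipping
available); the RSS covariance is Cholesky-factorized once per fit.
Expected heritability estimates pool variance components across replicates
(the per-replicate ratio is downward-biased by Jensen's inequality because
realized effect sizes are heavily skewed).

## Known limitations

* Mean-field underestimates the coupling between φ and s on
  likelihood-flat, near-null instances (exact-posterior agreement is
  validated on identifiable instances; on ambiguous draws the activity
  probability can deviate by ~0.1 from the exact value). This is a property
  of the variational family, not of the updates.
* A single component can absorb two distinct causal variants in very high
  LD (r² > 0.7), producing false-positive colocalization — measured and
  reproduced by the LD-confusion design.
* One LD matrix serves all studies in summary mode; multi-population LD is
  out of scope, as are missing summary statistics (variants are intersected
  across studies) and missing genotypes (impute upstream).
* Traits are assumed pre-residualized; there is no covariate model.
* Components claimed greedily in early sweeps are not revisited; borderline
  secondary signals at low ρ can be missed (power at ρ=0.05 with q ≥ 2 is
  materially below the ρ ≥ 0.1 regime).
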