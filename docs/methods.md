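# Methods

This note records the statistical machinery implemented in `linkscore`, the
derivations behind its closed forms, the defaults of the synthetic-data
generators, and the numerical choices and known limitations.

## 1. Links, case-control transform, and stratum weights

A population risk model is a binomial GLM `g(π) = η` with link `g`.  Under
case-control sampling with ratio `K` of case to non-case sampling
fractions, Bayes' theorem shifts every subject's odds by `K`, whatever the
link:

    logit(π) = logit(μ) − log K,

where `μ` is the probability of being a case in the study sample.  The
efficient score of the induced study-sample GLM weights each observation by
`w(μ) = 1/(g_CC′(μ) μ(1−μ))`; substituting the odds-shift identity shows
this equals

    W(π) = 1 / (g′(π) π (1 − π))

at the back-transformed population risk — a single formula that generates
every built-in weight (logit → 1, log → 1/(1−π), probit → φ(Φ⁻¹(π))/(π(1−π)),
identity → 1/(π(1−π)), independence → 1/π, power-odds λ → odds(π)^−λ).
Weights are reported unnormalized; every statistic built on them is
invariant to a global rescaling (asserted by property tests).  For the
power-odds family the weight is a pure power of the stratum case:control
odds, so relative weights require no estimate of `K`.

A small utility computes the power-odds exponent whose predictor is most
nearly an affine function of a target link over a risk grid (least squares
on π ∈ [0.001, 0.5]); for the probit target it returns λ ≈ 0.125.

## 2. Weighted score tests and their permutation variances

With strata `z`, weights `w_z`, genotype dose `x` and 0/1 phenotype `y`:

* stratified:  `U = Σ_z w_z Σ_{i∈z} (x_i − x̄_z)(y_i − ȳ_z)`, with the
  exact within-stratum permutation variance
  `V = Σ_z w_z² n_z²/(n_z−1) S²(x_z) S²(y_z)` (`S²` the divide-by-n
  variance).  This is Mantel's conditional variance; it is verified against
  exhaustive enumeration of all within-stratum orderings on small strata.
* marginal (valid when genotype ⊥ stratum in the population):  replace the
  case indicator by `0/w_z` and run the pooled trend test;
  `V = N²/(N−1) S²(x) S²(w_z y)` is the whole-sample permutation variance.
  With unit weights this is exactly the Cochran-Armitage test ignoring
  strata.

The 2-df variant applies the same construction to two genotype indicator
columns, with the permutation covariance matrix and a generalized-inverse
quadratic form (df = rank).  Monte-Carlo permutation p-values use the
matching permutation scheme and the add-one estimator
`(1 + #{|U*| ≥ |U|})/(1 + B)`.

Degenerate strata (single subject, constant genotype or phenotype)
contribute zero to both `U` and `V` and are counted in the result's
warnings.

## 3. Power-odds GLM fitting and the λ profile

The power-odds link is non-canonical, so IRLS uses step-halving: a Newton
step is halved until the Bernoulli log-likelihood does not decrease and all
fitted values stay inside (ε, 1−ε), ε = 1e-10; convergence at relative
log-likelihood change < 1e-10 or 100 iterations.  The Box-Cox transform is
evaluated with `expm1`/`log1p` so the family is numerically exact through
λ → 0 (a naive `(odds^λ − 1)/λ` loses all precision below λ ≈ 1e-8, which
matters because floating-point grids place "0" at ~1e-17).

`profile_lambda` fits the model at each grid λ (default −0.3 … 0.5 by
0.05), warm-starting from the previous solution, refines the argmax by a
quadratic through the bracketing triple (refinements that land more than 1
nat above the evaluated profile are rejected as ill-conditioned), and
reports the likelihood-ratio confidence set `{λ : 2(ℓ_max − ℓ(λ)) ≤
χ²₁(0.95)}`.  No sampling-ratio correction is needed: the family maps onto
itself under case-control sampling, rescaling coefficients only.  Coverage
of the 95% set at a true logistic model is ~95% in the suite's simulation
(200 replicates, n = 5000, two strong loci).

## 4. Non-centrality and efficiency under link misspecification

Strata are summarized by population fractions `f_z` and risks `π_z`.  Under
case:control ratio r (`q = r/(1+r)` cases), the study composition is

    a_z ∝ q·f_zπ_z/Σfπ + (1−q)·f_z(1−π_z)/Σf(1−π),   μ_z = q f_zπ_z/(Σfπ · a_z).

For a small effect β per genotype dose on the true-link scale (HWE dose,
`Var(x) = 2·maf·(1−maf)`), within stratum z the case indicator's
within-stratum covariance with the dose is `β Var(x) μ_z(1−μ_z) w*_z` with
`w*_z = W_true(π_z)` — but case-control sampling also *induces* a
between-stratum genotype-stratum association: the stratum genotype mean
shifts by `β Var(x) w*_z (μ_z − π_z)`.  Both terms enter the mean of the
marginal statistic, and the whole-sample permutation variance of `w_z y`
retains its between-stratum component, giving

    NCP = N β² Var(x) · m(w)² / v(w),
    m(w) = Σ a_z w_z w*_z μ_z(1−π_z) − (Σ a_z w*_z(μ_z−π_z))(Σ a_z w_z μ_z),
    v(w) = Σ a_z w_z² μ_z − (Σ a_z w_z μ_z)².

Efficiency of an analysis weighting is `NCP(w)/NCP(w*)`; it is free of β,
N and maf.  The purely within-stratum (stratified-test) analogue
`(Σ a I w w*)²/(Σ a I w² Σ a I w*²)`, `I = μ(1−μ)`, is also provided; it is
Cauchy-Schwarz-bounded by 1 with equality iff `w ∝ w*`.

Two bundled scenarios ship as JSON fixtures: a steep stratification (seven
equal strata, risks 0.1, 0.05, 0.02, 0.01, 0.005, 0.002, 0.001; 100-fold
range) and a moderate one (five equal strata, risks 0.05, 0.02, 0.01,
0.005, 0.002; 25-fold range).  Under 1:1 sampling and maf 0.5 the headline
efficiencies are 0.9486/0.9690 (unit weights, probit truth) and
0.9830/0.9837 (probit weights, logistic truth).  The analytic local limit
was validated two independent ways: an exact finite-β computation from the
joint (stratum, genotype, status) table, and direct simulation of the test
statistics (mean excess χ² ratio); all three agree.

Two structural findings are worth recording.  First, the reference
weighting `w*` is the efficient choice only up to the between-stratum
information: maximizing `m(w)²/v(w)` numerically beats `w*` by ~0.2% in the
steep scenario, so the efficiency measure can nominally exceed 1 by < 0.3%
in a narrow window of near-correct supra-multiplicative misspecification.
Second, with this (validated) non-centrality the unit-weight test loses
*more* under sub-multiplicative truth (λ > 0) than under the mirrored
supra-multiplicative truth on the display range — e.g. 0.76 at λ = +0.3 vs
0.93 at λ = −0.3 in the steep scenario — and the two scenarios' curves
cross by ≤ 0.006 near λ ≈ −0.2.  Both facts are asserted as such in the
tests rather than idealized away.

## 5. Prediction models

All four models are parameterized either natively or by the observable pair
(P, λ_S), solving internally for the native parameters so cross-model
comparisons are matched.

* **Multiplicative (log link).**  Score x ~ N(0,1), risk `exp(c0 + αx)`,
  `c0 = log P − α²/2`.  Sibling scores are bivariate normal with
  correlation 1/2, and `E[e^{α(x₁+x₂)}] = e^{α²(1+ρ)}` gives
  `λ_S = exp(α²/2)`.  Cases' scores are N(α, 1) by exponential tilting; the
  non-case density `(1−π(x))φ(x)/(1−P)` is integrated on a grid.  Nominal
  risks can exceed 1; the affected population fraction
  `Φ(−(log(1/P) + α²/2)/α)` is reported, and the simulator caps risks at 1
  (at λ_S = 3, P = 0.005 the capped fraction is ~1e-5, so analytic and
  simulated curves agree to < 0.005 in AUC).
* **Independent sufficient causes.**  Variant count x ~ Poisson(μ),
  per-variant penetrance p, sporadic risk b:
  `risk = 1 − (1−b)(1−p)^x`, `P = 1 − (1−b)e^{−μp}` (Poisson pgf).
  Sibling counts share a Poisson(μ/2) component (`x_i = s + u_i`), and
  `E[(1−p)^{2s+u₁+u₂}] = e^{−2μp + μp²/2}` gives
  `λ_S = (1 − 2(1−b)e^{−μp} + (1−b)²e^{−2μp+μp²/2})/P²`; in the rare fully
  penetrant limit λ_S → 1/(2P).  The ROC uses integer thresholds with
  linear interpolation.  Matching (P, λ_S) fixes `μp` from P and solves p
  by bracketed root-finding (λ_S increases with p at fixed μp).
* **Quadratic-log.**  `log risk = c0 + c1x + c2x²` (the small-exponent
  expansion of a power transform of risk); integrable iff c2 < 1/2.  The
  normalizer `E[e^{c1x+c2x²}] = (1−2c2)^{−1/2} e^{c1²/(2(1−2c2))}` fixes c0;
  λ_S comes from the exact 2-d Gaussian integral
  `|I − 2ΣA|^{−1/2} exp(½ b'(I−2ΣA)⁻¹Σb)` with Σ the sibling correlation
  matrix, and is independent of c0 and P.  Cases' scores are
  N(c1/(1−2c2), 1/(1−2c2)); ROC thresholds the score x itself (risk is
  monotone in x over the relevant range for the small |c2| used).
  c2 = 0 reduces exactly to the multiplicative model.
* **Probit (liability threshold).**  Liability L ~ N(0,1), threshold
  `T = Φ⁻¹(1−P)`, sibling liability correlation H/2:
  `λ_S = Φ₂(L₁>T, L₂>T; H/2)/P²`, inverted for H by bracketed
  root-finding on [0, 1].  The genotype score correlates √H with liability,
  so `TPR(t) = Φ₂(g>t, L>T; √H)/P` and
  `FPR(t) = (Φ(−t) − Φ₂(g>t, L>T; √H))/(1−P)`, swept over a threshold grid
  with extra far-tail points so curves at P = 1e-4 resolve.

Bivariate normal orthant probabilities are computed as
`∫_h^∞ φ(x) Φ((ρx−k)/√(1−ρ²)) dx` by adaptive quadrature (absolute
tolerance well below 1e-7, checked against `scipy.stats.multivariate_normal`).
FPR is computed against non-cases exactly, not against the whole
population; at small P the distinction is negligible but fixed for
determinism.

Every closed form above is guarded by a seeded Monte-Carlo sibling-pair
oracle (up to 1e6 pairs in the acceptance checks; 3 delta-method standard
errors for λ_S, 0.005 for AUC).  The oracle, not the formula, is treated as
ground truth.

## 6. Synthetic-data generators

`simulate_cc_study` computes the exact joint (stratum, genotype)
probabilities among cases and among controls — HWE genotype independent of
stratum in the population, stratum intercepts solved so the risk at the
mean dose equals the nominal stratum risk, effect constant across strata on
the chosen link scale — and multinomial-samples the design's case and
control counts.  This makes many-replicate power studies cheap and the
generative model identical to the asymptotic theory's.  Defaults mirror the
study conditions used throughout: maf 0.5, 1:1 design, the two bundled
scenarios.  Out-of-range risks at any attainable genotype raise an error
(detected by a round-trip check that defeats the links' numerical
clipping).

The sib-pair generators draw the latent structure of each prediction model
directly (bivariate normal scores/liabilities, shared/unshared Poisson
counts) and return per-subject records plus empirical P, λ_S (delta-method
SE on the log scale) and AUC.

What these generators deliberately do not emulate: linkage disequilibrium,
multi-locus genotypes in the association simulator, genotyping error,
population-stratification confounding (genotype is independent of stratum
by construction), ascertainment beyond simple case-control sampling, and
non-sibling relatives.  Passing tests therefore demonstrate correctness of
the mathematics under the stated models, not robustness to those real-data
complications.

## 7. Numerical choices

* Risks are clipped to [1e-12, 1−1e-12] before link evaluation; IRLS clips
  fitted values at 1e-10.
* Box-Cox odds transform via `expm1`/`log1p` (exact through λ → 0).
* Permutation p-values use the add-one estimator; two-sided via |U|.
* 2-df statistics use `pinv` with rank-based df; ties in ROC operating
  points are handled by trapezoidal AUC on monotone-rectified curves.
* Profile-λ quadratic refinement is rejected when the fitted vertex exceeds
  the evaluated profile by > 1 nat.
* Simulation sizes in the test suite (400–1000 replicates for calibration,
  100–200 for recovery, 1e6 sibling pairs for prediction oracles) were
  chosen so that three Monte-Carlo standard errors resolve the effects
  being checked.

## 8. Known limitations

* The marginal-test efficiency measure is defined relative to the
  true-link weighting, which is only near-optimal at finite sampling ratio
  (see §4); values up to ~1.003 can occur for adversarial weightings.
* The continuous-covariate regression generalization is exposed only as a
  hook (weights from fitted values); the discrete-stratum pathway is the
  implemented, tested contract.
* The log-link model's nominal risks are uncapped in its analytic ROC; use
  the reported above-one fraction to judge applicability.
* Genome-scale input formats (VCF/PLINK) are out of scope; the testing
  surface is single-variant tabular data.
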