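# Methods

## The growth model and AR definition

Age at adiposity rebound (AR) is the age of the last BMI minimum (nadir)
before the sustained mid-childhood rise. We model log BMI as a cubic in age
(days), fitted separately by sex with child-level random effects on all
four polynomial terms and an unstructured 4×4 random-effects covariance G:

log(BMI)ᵢⱼ = (β₀+μ₀ᵢ) + (β₁+μ₁ᵢ)aᵢⱼ + (β₂+μ₂ᵢ)aᵢⱼ² + (β₃+μ₃ᵢ)aᵢⱼ³ + εᵢⱼ.

The log transform stabilises the multiplicative error of BMI and is a fixed
contract of the fitting routine, not an option. Each child's individual
curve is cₖ = βₖ + μ̂ₖ with μ̂ the predicted (BLUP) random effects; AR is the
last root of the curve's first derivative inside the analysis window with
positive second derivative. For a cubic there is at most one minimum, but
the "last minimum" rule is written generally so other curve families can
reuse it.

Children contribute if they have at least three BMI measurements between
18 months (548 days) and 13 years (4748 days), both bounds inclusive; a
365.25-day year is used throughout. The AR search window equals the
eligibility window — the handful of curves whose minimum falls on or outside
a window edge are classified `no_rebound` rather than assigned an edge age
(boundary tolerance 1e-6 days).

### Estimation details

- Age is centred and scaled (days/1000) internally; coefficients are
  back-transformed to the day scale by polynomial composition before
  export.
- REML via statsmodels MixedLM. The **Powell optimizer is primary**: near
  the boundary of the G parameter space (higher-order random-effect
  variances close to zero, common in practice) the gradient-based
  optimizer's convergence flag is unstable even when its parameters are
  correct, whereas Powell converges reproducibly. Fallback chain, each step
  logged in the fit's warning list: REML/L-BFGS, ML/Powell, then dropping
  the cubic random effect (REML, then ML). Exhausting all fallbacks raises;
  there are no silent coefficients.
- Dense noise-free data drive the profiled residual variance to zero, where
  the mixed-model likelihood degenerates. In that limit the BLUP curve
  equals the per-child least-squares cubic, so when the pooled per-child
  residual variance falls below 1e-12 the fit returns those exact per-child
  solutions directly, flagged `zero_residual_limit`.

## Risk-allele score

Additive (co-dominant) coding only: the unweighted score is the sum over 27
loci of the BMI-increasing allele count (0–54); the weighted score
multiplies each count by the per-allele GWAS effect on adult BMI. A child's
score is **missing if any locus is missing** — proration would change the
score's scale — and missing child scores are recovered downstream by
imputation with parental scores among the predictors. QC: per-SNP call rate
> 0.95 (computed among assayed children; children never genotyped are not
in the batch) and HWE χ² p > 0.01. The shipped 27-SNP panel uses real rsIDs
from the adult-BMI GWAS literature but **illustrative, non-canonical
weights and frequencies**; analyses of real data should supply their own
panel CSV.

## Customized birth-weight standard

Expected birth weight is a linear predictor in fetal sex, parity and
maternal weight/height, scaled by a quadratic gestational-age proportion
equal to 1 at 40 weeks, with SD proportional to the expected weight
(constant CV, default 0.11). z = (observed − E)/(CV·E); SGA/LGA cut the
normal CDF of z at the 10th/90th centiles (SGA uses ≤, so the 10th centile
itself is SGA). The default coefficient set is illustrative — it produces
plausible term weights (~3.3 kg) and, under the simulator's z distribution
(mean −0.05, SD 1.1), ~13 % SGA as observed in comparable cohorts — and
deliberately does not reproduce any published proprietary table. An
ethnic-origin term is omitted (no such data in the intended setting).
Gestational-age support is 28–43 weeks; records outside raise.

## Multiple imputation

Fully conditional specification with stochastic draws: continuous variables
use a Bayesian linear-regression draw (σ² from the scaled inverse-χ²
posterior, β from its normal posterior, then a noise draw); binary
variables use a logistic fit with a normal coefficient draw and Bernoulli
outcomes; predictive mean matching (5 donors) is the universal fallback,
logged per variable. Defaults: M = 40 datasets, 10 burn-in cycles, visit
order by increasing missingness, per-dataset RNG streams derived from the
master seed. The analysis outcome (AR age) and auxiliaries (parental
scores) are in the conditioning set by default; the squared birth-weight-z
term is recomputed passively from the imputed z, never imputed directly.
Pooling uses Rubin's rules with Barnard–Rubin degrees of freedom
(complete-data df from the analysis model).

## Hierarchical association models

Four strictly nested regressions ordered distal → proximal:

| Model | adds |
|---|---|
| A | centre, maternal age, maternal + paternal education |
| B | risk-allele score, maternal + paternal BMI |
| C | gestational weight gain, smoking in pregnancy |
| D | preterm, birth-weight z, z², sex |

A variable's headline coefficient comes from the model where it first
enters, so proximal intermediates cannot absorb distal effects. Outcomes:
AR age in days (linear) and early AR (logistic), early AR being a rebound
strictly before the in-sample 20th percentile of AR age
(linear-interpolation/type-7 quantile; with ties at the threshold nobody is
early). Per-SNP scans regress AR on each dosage separately on complete
cases, with no multiplicity adjustment by default (a deliberate match to
nominal-significance reporting practice; monomorphic SNPs are flagged
not-testable). Adjusted means by SGA/AGA/LGA evaluate model D at the
analysis-sample covariate means, with the class-linked terms (z, z²) at
their within-class means; SEs use the delta method and everything is pooled
over imputations. In the preterm-exclusion sensitivity run the preterm term
is dropped (it is constant in that subset).

## The simulator

The generator is the package's study-conditions definition, not a tuning
knob. Per child:

- **True AR** = sex-specific base (5.5 y boys / 5.4 y girls) + mean-centred
  covariate effects + score effect + quadratic birth-weight-z effect +
  N(0, 1.26 y). Default effects (days per unit): education +15.7/+14.4,
  maternal/paternal BMI −15.9/−15.6, gestational weight gain −7.5, smoking
  −72.1, preterm +39.4, score −9.2/allele, z terms +24.1 and −14.4.
  Centring makes the base the population mean; the residual SD is chosen so
  the **total** SD of AR is ≈ 1.3 y. An `sga_deficit_days` option rescales
  the two z terms so the implied SGA−AGA contrast (truncated-normal
  moments of the generating z) equals a requested value exactly.
- **Curve**: derivative 3c₃(a − peak)(a − AR) with the infancy BMI peak at
  ~270 ± 40 days and c₃ ≈ 2.0e-11/day³ (log-normal 12 % spread). This
  parametrization guarantees the nadir sits exactly at the latent AR for
  every child and gives full-rank random effects. c₃ is chosen for
  curvature realism — it reproduces the observed ~0.04 log-BMI rise 900
  days after the nadir — and is capped per child so the cubic's projected
  BMI at 13 y stays below 50 (cubics extrapolate steeply for the earliest
  rebounds; the cap binds for ~1 % of children). Nadir BMI ≈ 15.5 kg/m².
- **Measurements**: per-child counts from a negative binomial (mean 10,
  dispersion 4, clipped to [1, 25]); ages mix four jittered clinic visits
  (birth, 1, 3, 5 y) with draws from a routine-record age pool — the real
  visit process is unknown, so this schedule is a documented stand-in.
  Observed log BMI adds N(0, 0.04) measurement noise; weight and height are
  decomposed from BMI via a crude stature curve (only their ratio matters).
- **Genotypes**: parents Binomial(2, p) per SNP, children inherit one
  allele from each; ~30 % of children have genotypes withheld with parental
  scores retained, mirroring realistic score availability.
- **Missingness**: MAR via a logistic model in recruitment centre and
  maternal education with the intercept solved (Brent) to hit each
  column's marginal rate exactly in expectation.

What the simulator does **not** emulate: the infancy BMI surge from a much
lower birth BMI (a single cubic cannot produce it), longitudinal covariates,
family structure beyond parental scores, MNAR missingness, genotyping
error, and curve-family misspecification (children really are cubic here).
Passing tests therefore certify the estimation machinery, not robustness to
model misspecification on real data.

## Validation conditions and measured behaviour

Problem sizes for the validation battery were chosen as the smallest that
make each check informative: grid-oracle equivalence on 10,000 random
curves at 1-day resolution; noiseless daily-sampled recovery on 40
children; default-noise recovery at n = 500; effect recovery at n = 5000
(true-AR outcome, isolating the association machinery); 400–1000 null
replicates at n = 250 for type-I error; a full pipeline run at n = 1400
with M = 40. Under the default conditions the median |AR error| measured
≈ 94 days across pilot seeds with bias compatible with zero; the frozen
regression bound is 120 days (`rebound.DEFAULT_RECOVERY_BOUND_DAYS`),
declared from that pilot with headroom. With roughly ten noisy measurements
per child a ~3-month individual error is expected; cohort-level effect
estimates remain unbiased, with mild attenuation from BLUP shrinkage when
the estimated (rather than true) AR is the outcome.

## Known limitations

- A single cubic compromises between the infancy peak and the rebound; AR
  estimates inherit that compromise exactly as in the classic cohort
  analyses this package mirrors.
- Translation covariance of AR estimates (shift all ages by Δ → AR shifts
  by Δ) holds exactly in exact arithmetic but is limited in practice by the
  REML optimizer's stopping tolerance (observed well under one day).
- The logistic early-AR models use large-sample normal pooling reference
  (no complete-data df); ORs at small n carry the usual small-sample bias.
- The default panel weights and centile coefficients are placeholders for
  structure, clearly labelled; scientific use requires the real tables.
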