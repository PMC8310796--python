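# adrebound

Tools for studying the **adiposity rebound (AR)** — the second rise of the
childhood BMI curve — and its perinatal and genetic determinants, in the
style of a birth-cohort analysis: repeated weight/height measurements per
child, a polygenic obesity risk-allele score, perinatal covariates, multiple
imputation, and hierarchical regression.

After an infancy peak, a child's BMI declines to a nadir around ages 4–7 and
then rises again. An early rebound predicts later obesity, which makes *age
at AR* an outcome worth modelling in its own right. This package implements
the full estimation chain for epidemiologists working with longitudinal
anthropometry:

1. **Growth model** (`growthmodel`) — sex-stratified mixed-effects cubic
   model on log BMI with age in days,

   log(BMI) = (β₀+μ₀) + (β₁+μ₁)·Age + (β₂+μ₂)·Age² + (β₃+μ₃)·Age³ + ε,

   with an unstructured 4×4 random-effects covariance (REML via statsmodels
   MixedLM). Children need ≥ 3 BMI measurements between 18 months and
   13 years to enter the model.
2. **AR estimation** (`rebound`) — each child's curve cₖ = βₖ + μₖ is
   differentiated analytically; the age at AR is the *last* root of
   c₁ + 2c₂a + 3c₃a² = 0 inside the window with positive second derivative
   (the last BMI minimum before the sustained rise). Because log is
   monotone, the answer is identical on the BMI and log-BMI scales.
3. **Risk-allele score** (`genetics`) — QC (call rate > 95 %, HWE p > 0.01)
   and the 27-SNP obesity score: the sum of BMI-increasing alleles
   (0/1/2 per locus, range 0–54), plus a GWAS-weighted variant.
4. **Perinatal covariates** (`perinatal`) — customized birth-weight
   z-scores, z = (observed − E)/(CV·E), with E adjusted for fetal sex,
   gestational age and maternal weight/height/parity; SGA/AGA/LGA classes
   at the 10th/90th customized centiles; parental BMI; preterm flag.
5. **Multiple imputation** (`mimpute`) — chained equations (FCS, 40
   datasets by default, parental scores as auxiliaries for missing child
   scores) and Rubin pooling with Barnard–Rubin degrees of freedom.
6. **Hierarchical models** (`hierassoc`) — four nested regressions, distal
   to proximal (socio-demographics → parental BMI + genetic score →
   pregnancy exposures → newborn characteristics, with birth-weight z and
   z²); each variable is reported from the model where it first enters.
   Linear models on AR age in days, logistic models on "early AR" (rebound
   before the in-sample first quintile), per-SNP co-dominant scans, and
   model-D adjusted mean AR by SGA/AGA/LGA class.
7. **Simulator** (`simcohort`) — synthetic mother–child cohorts with known
   true AR per child, so every stage above is testable without any
   real data; the pipeline module (`pipeline`) runs the whole chain and
   writes a manifest with flow counts.

## Worked example

```python
from adrebound import simcohort, growthmodel, rebound
import pandas as pd

cfg = simcohort.SimConfig(n_children=500, seed=1)
anthro, covariates, genotypes, truth = simcohort.generate_cohort(cfg)

eligible, excluded = growthmodel.eligibility_filter(anthro)
records = anthro[anthro.child_id.isin(eligible)]
curves = pd.concat(
    [growthmodel.predict_curves(growthmodel.fit_cubic_mixed(records, sex=s))
     for s in ("male", "female")], ignore_index=True)
ar, counts = rebound.ar_for_cohort(curves, excluded)
print(counts)
est = ar[ar.status == "estimated"].merge(truth, on="child_id")
err = est.ar_age_days - est.true_ar_days
print(f"median |error| {err.abs().median():.1f} d, "
      f"mean AR {est.ar_age_years.mean():.2f} y")
```

Output (seed 1):

```
{'estimated': 402, 'insufficient_data': 97, 'no_rebound': 1}
median |error| 93.9 d, mean AR 5.42 y
```

Of 500 simulated children, 97 lack three in-window measurements and one
fitted curve shows no in-window minimum; the 402 estimated rebound ages
centre on ~5.4 years, and the per-child estimation error (median ≈ 3
months) reflects roughly ten noisy measurements per child.

The same chain runs from the shell:

```bash
adrebound simulate --out cohort/ --seed 1 --n 500
adrebound fit-growth --anthro cohort/anthropometry.csv --out fits/
adrebound estimate-ar --curves fits/curves.csv --out ar.csv
```

or end-to-end with `adrebound run --config run.yaml`, which writes every
intermediate table (curves, AR ages, QC report, imputed datasets, pooled
model coefficients, adjusted means by birth-weight class) plus a
`manifest.json` recording seeds and flow counts.

## Layout

```
src/adrebound/     simcohort, growthmodel, rebound, genetics, perinatal,
                   mimpute, hierassoc, pipeline, cli
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    modelling assumptions, defaults and limitations
```
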