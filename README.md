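# scljoint

Joint modeling of a longitudinal serum drug level and survival after lung
transplantation.

After lung transplantation (LTx), recipients are maintained on cyclosporine
and the serum cyclosporine level (SCL) is monitored at every clinic visit.
Because death truncates the measurement series — and the risk of death may
depend on the same latent trajectory that generates the measurements —
analyzing the biomarker and survival separately (or feeding the biomarker
into a time-dependent Cox model) can be biased. `scljoint` implements the
shared-random-effects joint model for this setting, for biostatisticians
working with therapeutic-drug-monitoring cohorts: a longitudinal submodel
and a Weibull hazard submodel tied together by a per-subject latent
intercept and fitted as one marginal likelihood.

## The model

Longitudinal submodel (time `t` in months since transplant, knot `k = 10`):

    Y_ij = β₀ + β₁ t I(0<t≤k) + β₂ t² I(0<t≤k) + β₃ t I(t>k) + u_i + ε_ij,
    ε_ij ~ N(0, σ²),   u_i ~ N(0, σ_u²)

a quadratic early phase and a linear late phase, plus a shared random
intercept `u_i`.  Survival submodel (Weibull proportional hazards):

    h_i(t) = p · exp(γ₀ + Σ_k γ_k x_ik + α u_i) · t^(p−1)

The association parameter `α` links the two: `α < 0` means recipients with
higher-than-expected drug levels die at a lower rate.  Hazard ratios are
`e^γ`; for users holding accelerated-failure-time coefficients the identity
`γ = −β_AFT · p` is exposed as `hr_from_aft`.

Fitting maximizes the marginal likelihood, integrating `u_i` out per subject
with Gauss–Hermite quadrature.  Since the longitudinal factor is exactly
Gaussian in `u`, the package collapses it analytically and places the nodes
adaptively on each subject's conditional posterior, so a 15-node rule is
accurate even with dozens of measurements per subject.  Inference is Wald
(two-tailed), with log-scale intervals for `σ`, `σ_u` and `p`.  The package
also provides one-at-a-time covariate screening and a boundary
likelihood-ratio test for between-subject heterogeneity (`σ_u = 0`).

Because no registry data ship with the package, a first-class synthetic
cohort generator reproduces the cohort structure this design targets:
published baseline covariate margins, the clinical visit schedule (weekly to
month 3, monthly to month 12, irregular after), the trajectory and event
processes above, and administrative censoring.

## Worked example

```sh
scljoint simulate --n 50 --seed 101 --out-dir sim/
scljoint fit --longitudinal sim/longitudinal.csv --subjects sim/subjects.csv \
             --out-dir fit/ --covariates ar
```

prints (abridged):

```
subjects: 50  measurements: 1832  log-likelihood: 1740.0864  converged: True

Survival component of the model (Weibull, log-hazard scale)
     term    coef     se     hr  hr_lo  hr_hi  p_value
intercept -5.8946 0.9467 0.0028 0.0004 0.0176   0.0000
       ar  0.1184 0.3877 1.1257 0.5265 2.4069   0.7601

Serum drug level (longitudinal component)
 term  estimate     se   ci_lo   ci_hi  p_value
beta0    0.3641 0.0183  0.3281  0.4000   0.0000
beta1    0.1286 0.0030  0.1228  0.1344   0.0000
beta2   -0.0197 0.0003 -0.0204 -0.0191   0.0000
beta3   -0.0200 0.0001 -0.0202 -0.0197   0.0000
sigma    0.0809 0.0014  0.0783  0.0836      NaN

Association parameter and random effect
           term  estimate     se   ci_lo   ci_hi  p_value
          alpha   -3.1891 1.4854 -6.1004 -0.2778   0.0318
        sigma_u    0.1260 0.0127  0.1033  0.1536      NaN
```

Reading it: the biomarker (model scale = raw ng/mL ÷ 1000) starts near 0.36
µg/mL, rises and bends over during the first 10 months (β₁ > 0, β₂ < 0) and
declines about 2% of the model scale per month afterwards (β₃ ≈ −0.020); the
acute-rejection hazard ratio in this small simulated cohort is 1.13 with a
wide interval; the negative α says higher-than-expected drug levels go with
lower mortality.  At n=50 the association is noisily estimated — its
interval is wide — which is why the recovery experiments below average over
replicates at n=300.

The same steps are available in Python:

```python
from scljoint import CohortSpec, JointModel, generate_dataset, reference_truth_params

dataset, latent = generate_dataset(CohortSpec(50, reference_truth_params(), seed=101))
model = JointModel(covariates=("ar",)).fit(dataset)
print(model.hr_table_)          # hazard ratios with Wald CIs
print(model.params_.assoc.alpha)
```

`JointModel` follows the scikit-learn estimator conventions
(`get_params`/`set_params`, fitted attributes with trailing underscores), so
it composes with sklearn tooling; `fit_joint`, `univariate_screen` and
`heterogeneity_test` are functional wrappers.

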