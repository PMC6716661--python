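# ggfit

Small-sample estimation for the three-parameter **Generalized Gamma (GG)
distribution**, with a penalized maximum-likelihood estimator as the
recommended default, a simulated-annealing optimizer that removes
initial-value sensitivity, bootstrap confidence intervals, competitor
lifetime models with AIC/AICc/KS model selection, mean-residual-lifetime
prediction, and a Monte Carlo harness for bias/MSE/failure-rate studies.

## Who this is for

Analysts modelling small samples of positive durations — hospital lengths
of stay, times on mechanical ventilation, component lifetimes — where a
flexible parametric family is wanted but the classical fitting machinery
breaks down: maximum likelihood for the GG family is notoriously unstable
below a few hundred observations, and simpler methods (moments, least
squares on the cdf) fail to converge outright for most samples.

## The model

The GG density with shape parameters `phi, alpha > 0` and rate-type scale
`mu > 0` (units 1/time) is

    f(t | phi, mu, alpha) = alpha * mu^(alpha*phi) * t^(alpha*phi - 1)
                            * exp(-(mu*t)^alpha) / Gamma(phi),   t > 0.

It nests the Weibull (`phi = 1`), Gamma (`alpha = 1`), exponential,
half-normal, Rayleigh and — as a limit — lognormal distributions, and its
hazard can be constant, increasing, decreasing, bathtub or unimodal.

Eight estimators are provided: method of moments (MM), ordinary and
weighted least squares on the cdf (OLS/WLS), maximum likelihood (ML),
**penalized maximum likelihood (PML)**, maximum product of spacings (MPS),
and the Anderson–Darling and right-tail Anderson–Darling minimum-distance
estimators (AD/RAD).  The PML criterion multiplies the likelihood by a
Jeffreys-type penalty

    pi(phi, mu, alpha) ∝ sqrt(phi^2 psi'(phi)^2 - psi'(phi) - 1) / (mu * alpha),

whose radicand is exactly `mu^2` times the determinant of the
per-observation Fisher information.  The penalty removes most of the
small-sample bias of the MLE and — crucially — makes the fit succeed
essentially always, which is what makes bootstrap intervals feasible at
n ≈ 20.  Global optimization uses simulated annealing in log-parameter
space followed by a gradient polish and a stationarity check; every fit
reports whether its estimating equations are actually solved.

## Worked example

Generate a synthetic 19-stay hospital sample (whole days, ceil-rounded,
drawn at the published point estimates for total length of stay after
traumatic brain injury), fit the GG by PML, and ask the practical
question: *a patient has been in hospital ten days — how much longer?*

```sh
$ ggfit fixture --preset D1-like --seed 3 d1.csv
wrote d1.csv (19 rows)

$ ggfit fit d1.csv --method pml --seed 1 --sann-max-iter 3000
{
  "failed": false,
  "loglik": -72.99,
  "method": "PML",
  "params": {"alpha": 6.131, "mu": 0.0235, "phi": 0.1756},
  "score_norm": 1.27e-14,
  ...
}

$ ggfit mrl --params 0.410,0.025,3.040 --t-grid 10
t,mrl
10,17.2772
```

The fit returns the parameter triple (here `phi ≈ 0.18`, `mu ≈ 0.023`/day,
`alpha ≈ 6.1` — small-sample scatter around the generating values is
expected at n = 19) together with the log-likelihood and the residual norm
of the estimating equations (`score_norm`; a fit is only reported as
successful when this is below 1e-5).  The `mrl` call evaluates the mean
residual lifetime at the published total-stay estimates: after ten days in
hospital the model expects about **17 more days** before discharge
(`r(0)` would give the unconditional mean stay, ≈ 23 days).

Model comparison against four rival three-parameter lifetime families
(generalized, exponentiated, Marshall–Olkin and extended Poisson–Weibull):

```sh
$ ggfit compare d1.csv --seed 2
family,loglik,c,AIC,AICc,KS_D,KS_p,KS_reject_5pct,delta_w,support
EW,-72.82,3,151.63,153.23,0.099,0.992,False,0.0,plausible
GG,-72.99,3,151.99,153.59,0.125,0.926,False,0.355,plausible
...
```

`delta_w` is each model's AIC distance from the best; models within 2 are
all plausible.  The simulation harness behind Tables of failure
proportions is exposed as `ggfit simulate`.

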