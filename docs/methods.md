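# Methods

This note records the statistical model, the algorithmic choices, and the
limits of what the package's synthetic studies demonstrate.

## Model

`T ~ GG(phi, mu, alpha)` with density

    f(t) = alpha * mu^(alpha*phi) * t^(alpha*phi-1) * exp(-(mu*t)^alpha) / Gamma(phi)

on `t > 0`; `phi` and `alpha` are dimensionless shapes, `mu` a rate (1/time).
Distribution function `P(phi, (mu*t)^alpha)` and survival
`Q(phi, (mu*t)^alpha)` are the regularized incomplete gamma functions; the
r-th raw moment is `Gamma(phi + r/alpha) / (mu^r Gamma(phi))`; the mean
residual lifetime is

    r(t) = Gamma(phi + 1/alpha, x) / (mu * Gamma(phi, x)) - t,   x = (mu*t)^alpha,

with unregularized upper incomplete gammas, computed through log-gamma
differences so large `phi` cannot overflow.  All likelihood work is done in
log space: the raw likelihood of even fifty observations overflows for
moderately large shapes.  Sampling uses the exact Gamma-power transform
`T = W^(1/alpha) / mu`, `W ~ Gamma(phi, 1)`.

Uncensored data only: the estimators target complete samples of observed
durations, as in the hospital-stay application the package is built around.

## The penalty

The PML criterion adds to the log-likelihood

    0.5 * log(phi^2 psi'(phi)^2 - psi'(phi) - 1) - log(mu) - log(alpha).

The radicand is identically `mu^2 * det(I_1)`, the determinant of the
per-observation Fisher information — i.e. the first term is the Jeffreys
prior — and is therefore strictly positive for every `phi` the information
is defined at (we verified positivity numerically across `phi` from 1e-3
to 1e3; beyond ~1e7 double-precision cancellation ends the usable range
and a domain error is raised).  The additional `1/alpha` factor mirrors
the Weibull Jeffreys prior and trims the small-sample bias of `alpha`.
The penalty is O(1) while the log-likelihood grows like n, so PML and ML
estimates coincide asymptotically; the package's large-sample agreement
test exercises exactly that.

The per-observation Fisher matrix is derived from `-E[Hessian]` using
`E[x log x] = phi*psi(phi) + 1` for `x ~ Gamma(phi, 1)`:

    [  psi'(phi)         -alpha/mu            -psi(phi)/alpha   ]
    [ -alpha/mu           phi*alpha^2/mu^2    (1+phi*psi)/mu    ]
    [ -psi(phi)/alpha     (1+phi*psi)/mu      (1+2psi+phi*psi'+phi*psi^2)/alpha^2 ]

(checked entrywise against a 40 000-draw Monte-Carlo numeric Hessian).
The penalized information adds the deterministic negative Hessian of the
log penalty: `(J'^2 - J''J)/(2J^2)` on the (phi,phi) entry and `-1/mu^2`,
`-1/alpha^2` on the scale entries, verified against the numeric Hessian of
the penalized log-likelihood.  Note the penalized matrix is an O(1)
correction of an O(n) matrix and can be indefinite for adversarial
`(theta, n)` combinations at very small n; at the study conditions it is
positive definite.

## Optimization

Simulated annealing with Metropolis acceptance `exp(-dg/k)`, per-coordinate
uniform proposals `x + r*V`, Corana-style step adaptation toward 50%
acceptance every `s = 20` iterations, geometric cooling `k <- 0.95 k` every
`m = 100` iterations, stopping on small `k`, a long no-acceptance streak,
or the iteration cap (library default 20 000; the replicated-fit harness
uses 2 000 — the polish below, not annealing length, decides success).
Initial temperature defaults to `max(1, log g(x0))`, guarded to stay
positive where the bare logarithm would not be.  All estimators anneal in
log-parameter space, which removes the positivity constraints and makes
the uniform proposal scale-appropriate.

Annealing is followed by a three-stage polish: Nelder–Mead, then BFGS with
the analytic criterion gradient, then — because the BFGS line search
stalls once objective *differences* fall below the floating resolution of
an objective that scales with n, while the gradient is still resolvable —
a root-find (Powell hybrid) on the stationarity equations themselves.
A fit is reported failed iff the solver returns a non-finite point, an
estimate escapes [1e-6, 1e6], the estimating-equation residual exceeds
1e-5, or the criterion is non-finite at the returned point.  This
stationarity-verified notion of "success" is deliberately stricter than
an optimizer's own convergence report (see "Failure semantics" below).

Profile structures reduce the dimension wherever one exists:

* **ML** profiles to one dimension: for trial `alpha`,
  `phi(alpha) = n*A / (n*B - A*C)` with `A = sum t^a`, `B = sum t^a log t^a`,
  `C = sum log t^a` (denominator positive by the Chebyshev sum inequality),
  `mu(alpha) = (n*phi/A)^(1/a)`; the remaining score is
  `h(alpha) = n log(n*phi) - n log A + alpha*sum log t - n psi(phi)`,
  derived symbolically from the score equations and verified against
  finite differences.  Interior roots of `h` are bracketed on a log grid
  over [1e-3, 1e3] and solved by Brent.
* **PML** eliminates `phi = (alpha*S + 1)/(n*alpha)`, `S = sum (mu t)^alpha`
  — the stationarity identity of its own mu-score — leaving a smooth 2-D
  problem whose stationary points satisfy all three equations.
* **MPS/AD/RAD** optimize all three log-parameters; their gradients use
  the closed-form cdf derivatives in `mu` and `alpha` and fourth-order
  central differences for the `phi` derivative of the incomplete gamma.

MM deliberately gets no annealing rescue: the two moment equations (with
`phi` substituted by its moment identity) are solved by a plain undamped
Newton iteration with forward-difference Jacobian from the random start,
NaN-terminating outside the domain — the textbook procedure whose
fragility the failure study documents.  OLS/WLS likewise run a standard
BFGS from the raw random start (with a stationarity sharpening applied
only when BFGS has found a genuine optimum).

## Failure semantics and the degenerate corner

For small samples the GG likelihood's supremum frequently sits on the
boundary `alpha -> inf, phi -> 0` (with `alpha*phi` bounded), where no
estimate exists; the same corner attracts the spacings and
Anderson–Darling criteria.  We verified on individual n = 20 replicates
that every interior start converges to the same extreme point pressed
against the double-precision underflow cliff — the criterion's infimum is
at the corner and no interior stationary point exists.  Under the
package's taxonomy such replicates are *failures*; an optimizer that
merely reports "converged" after a fixed iteration budget would call them
successes.  Consequently the ML/MPS/AD/RAD failure proportions reported by
the harness at n = 20 (roughly 0.2 for ML, 0.1–0.2 for the distance
estimators at the first study truth) are estimates of the probability that
no interior optimum exists, not counts of numerical accidents, and they
shrink quickly with n.  The penalized criterion has no such corner — the
penalty's `-log(mu*alpha)` and the bounded radicand tame both ends — which
is precisely why its failure proportion is 0.000 in every cell.

The EW and GW competitors have analogous degeneracies (EW's
`theta -> 0, alpha -> inf` ridge; GW's support-endpoint singularity when
`1/lambda - 1 < 0`).  Their ML fits polish both the annealed point and a
neutral moment-flavoured start and return the best point that actually
solves the score equations; on small tied samples an interior EW/GW
optimum often does not exist, and those rows then drop from comparison
tables as failed fits rather than being reported at arbitrary values.

## Monte Carlo protocol

The harness draws one sample per replicate and hands the same sample to
every requested method (paired design; an unpaired mode exists), each
method receiving an independent U(0, 4)^3 random starting draw — the
study's stance that good initial values are unavailable in practice.
Per-replicate generators derive from `SeedSequence((master_seed, n, k))`,
so any single cell of a failure table is reproducible in isolation.  Bias
`mean(theta_hat - theta)` and MSE `mean((theta_hat - theta)^2)` are
computed over successful replicates (failed replicates yield no estimate;
both counts are reported).  Desk-scale sizes used throughout the tests and
the acceptance script: N = 2000 replicates for failure proportions
(n = 20–100), N = 250 for the bias/MSE trend over n in {20, 60, 150, 300},
500 replicates for Wald-coverage checks, single fits at n = 10^4 for the
asymptotic-agreement checks.

## Intervals

Wald intervals use the inverse information at the estimates; they are
flagged with a warning below n = 400, where approximate normality for
`phi` is known to be unattainable.  The bootstrap resamples the data with
replacement, refits per replicate (failures dropped and counted; more than
50% failures aborts — a fragile estimator cannot support a bootstrap,
which is the practical argument for PML), and builds BCa intervals with an
automatic fall-back to plain percentile when the jackknife acceleration is
degenerate; percentile endpoints are order statistics of the replicate
estimates.  B defaults to 1000.

## Model selection

KS distance `D_n = max_i max(i/n - F(t_(i)), F(t_(i)) - (i-1)/n)` with the
asymptotic Kolmogorov p-value.  With estimated parameters this p-value is
conservative; a parametric-bootstrap p-value is available behind a flag.
AIC `= -2 loglik + 2c` and AICc `= AIC + 2c(c+1)/(n-c-1)`; for the GG the
*unpenalized* log-likelihood at the PML estimates enters the criteria so
that families with and without a penalty remain comparable.  Support
bands follow the usual rule of thumb (Δ < 2 plausible, 4–7 considerably
less, > 10 essentially none).

A practical limit worth stating: the four competitor families approximate
a GG(0.5, 0.5, 3) density to within Kullback–Leibler distances that
samples of a few hundred cannot resolve, so the minimum-AIC *winner* on
GG-generated data is decided by noise among near-equivalent models.  The
reliable statement — and the one the tests assert — is that the true
family stays inside the Δ < 2 plausibility band in the vast majority of
replicates.  Five-way AIC selection at n ≈ 200 should be read as a
plausibility screen, not an oracle.

## Synthetic fixtures

The application stand-ins draw from the GG at the published point
estimates for the three hospital-stay samples (total stay n = 19;
neurology department n = 19; mechanical ventilation n = 16) and round
*up* to whole days, matching strictly positive integer day counts and
reproducing the tie structure that exercises the spacings tie-branch.
They emulate sample size, scale and discreteness of the real admissions
data; they do not carry its dependence on clinical covariates, and tests
passing on them validate the workflow's contracts, not the published
point estimates, which would require the original patient records.

## Numerical edges

* Hazard at points where the survival underflows returns +inf with a
  warning rather than NaN.
* Mean residual life raises a domain error once both incomplete-gamma
  tails underflow (t far beyond the support's numeric resolution).
* Spacings with tied order statistics substitute the density for the
  collapsed interval, in both the objective and its gradient.
* Quantiles use bracket-and-Brent on the cdf to 1e-10 — needed only for
  plotting-style use, never by the estimators.
* Proposals beyond e^15 in any log-parameter are rejected outright: they
  are past the boundary-escape box and only stall the incomplete-gamma
  routines.
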