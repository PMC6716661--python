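"""Fisher information, Wald intervals, and bootstrap intervals.

The per-observation Fisher matrix of the Generalized Gamma (parameter
order phi, mu, alpha) is

    [ psi'(phi)            -alpha/mu             -psi(phi)/alpha             ]
    [ -alpha/mu            phi alpha^2/mu^2      (1 + phi psi(phi))/mu       ]
    [ -psi(phi)/alpha      (1+phi psi(phi))/mu   (1 + 2 psi + phi psi' +
                                                   phi psi^2)/alpha^2        ]

(derived from -E[Hessian]; its determinant times mu^2 is the Jeffreys
radicand phi^2 psi'(phi)^2 - psi'(phi) - 1 of the penalty).

The penalized variant adds the (deterministic) negative Hessian of the log
penalty: a polygamma correction on the (phi, phi) entry that vanishes at
rate 1/n relative to the likelihood part, and -1/mu^2, -1/alpha^2 on the
scale entries from the -log mu - log alpha factors.

Wald intervals from this matrix are known to be optimistic for phi at the
sample sizes this package targets (normality can fail even at n of several
hundred), so the bootstrap interval is the recommended one below n ~ 400;
`asymptotic_ci` emits a warning in that regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special, stats

from .model import GGParams, LifetimeSample
from . import estimators as est

__all__ = ["FisherMatrix", "IntervalSet", "fisher_info", "asymptotic_ci", "bootstrap_ci"]

_PARAM_NAMES = ("phi", "mu", "alpha")


@dataclass(frozen=True)
class FisherMatrix:
    """3x3 information matrix for n observations, order (phi, mu, alpha)."""

    matrix: np.ndarray
    penalized: bool
    n: int

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass(frozen=True)
class IntervalSet:
    """Per-parameter confidence intervals.

    ``intervals`` maps parameter name -> (lower, upper); ``method`` is one
    of {"asymptotic", "bootstrap-percentile", "bootstrap-bca"}.
    """

    intervals: dict
    method: str
    level: float
    B: int = 0
    seed: Optional[int] = None
    n_failed: int = 0

    def __getitem__(self, name: str):
        return self.intervals[name]


def _unit_fisher(params: GGParams) -> np.ndarray:
    # signs from -E[Hessian] directly (E[x log x] = phi psi(phi) + 1 etc.
    # for x ~ Gamma(phi, 1)); note I12 = -alpha/mu and I23 = +(1+phi psi)/mu
    phi, mu, alpha = params.phi, params.mu, params.alpha
    p0 = special.digamma(phi)
    p1 = special.polygamma(1, phi)
    return np.array(
        [
            [p1, -alpha / mu, -p0 / alpha],
            [-alpha / mu, phi * alpha**2 / mu**2, (1.0 + phi * p0) / mu],
            [
                -p0 / alpha,
                (1.0 + phi * p0) / mu,
                (1.0 + 2.0 * p0 + phi * p1 + phi * p0**2) / alpha**2,
            ],
        ]
    )


def _penalty_phi_info(phi: float) -> float:
    """-d^2/dphi^2 of (1/2) log J(phi) = (J'^2 - J'' J) / (2 J^2)."""
    j = est._jeffreys_radicand(phi)
    j1 = est._jeffreys_radicand_d1(phi)
    j2 = est._jeffreys_radicand_d2(phi)
    return (j1 * j1 - j2 * j) / (2.0 * j * j)


def fisher_info(params: GGParams, n: int, penalized: bool = False) -> FisherMatrix:
    """Expected information of n observations at ``params``.

    With ``penalized=True`` the matrix is the expected negative Hessian of
    the penalized log-likelihood; the corrections are O(1) while the
    likelihood part grows like n, so the two matrices agree asymptotically.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    m = n * _unit_fisher(params)
    if penalized:
        m = m + np.diag(
            [
                _penalty_phi_info(params.phi),
                -1.0 / params.mu**2,
                -1.0 / params.alpha**2,
            ]
        )
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite information matrix entries")
    return FisherMatrix(matrix=m, penalized=penalized, n=int(n))


#: sample size below which Wald normality for phi is not trustworthy
SMALL_SAMPLE_N = 400


def asymptotic_ci(fit: est.FitResult, level: float = 0.95) -> IntervalSet:
    """Wald intervals  theta_j +/- z * sqrt([I^-1]_jj)  at the estimates."""
    if fit.failed or fit.params is None:
        raise ValueError("cannot build intervals from a failed fit")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if fit.n < SMALL_SAMPLE_N:
        warnings.warn(
            f"n={fit.n} < {SMALL_SAMPLE_N}: Wald normality for phi is unreliable "
            "at this size; prefer bootstrap_ci",
            UserWarning,
        )
    info = fisher_info(fit.params, fit.n, penalized=False)
    try:
        cov = info.inverse()
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular information matrix") from exc
    se = np.sqrt(np.diag(cov))
    if np.any(~np.isfinite(se)):
        raise ValueError("negative variance from the information matrix")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    theta = fit.params.as_array()
    ivs = {
        name: (float(theta[i] - z * se[i]), float(theta[i] + z * se[i]))
        for i, name in enumerate(_PARAM_NAMES)
    }
    return IntervalSet(intervals=ivs, method="asymptotic", level=level)


def _percentile_pair(sorted_vals: np.ndarray, lo_q: float, hi_q: float):
    """Interval endpoints as order statistics of the replicate estimates."""
    b = sorted_vals.size
    ilo = min(max(int(np.floor(lo_q * b)), 0), b - 1)
    ihi = min(max(int(np.ceil(hi_q * b)) - 1, 0), b - 1)
    if ihi < ilo:
        ilo, ihi = ihi, ilo
    return float(sorted_vals[ilo]), float(sorted_vals[ihi])


def bootstrap_ci(
    sample: LifetimeSample,
    method: str = "PML",
    level: float = 0.95,
    B: int = 1000,
    seed: Optional[int] = None,
    bca: bool = True,
    **fit_kwargs,
) -> IntervalSet:
    """Nonparametric bootstrap intervals for (phi, mu, alpha).

    The sample is resampled with replacement B times and refitted per
    replicate with the requested estimator; replicates whose refit fails
    are dropped and counted (more than 50% failures is an error — a
    fragile estimator cannot support a bootstrap, which is precisely why
    the penalized fit is the default here).  Intervals are BCa with an
    automatic fall-back to plain percentile when the jackknife acceleration
    is degenerate.
    """
    if B < 200:
        raise ValueError("B must be >= 200 for quantile resolution")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    point = est.fit(sample, method=method, rng=rng, **fit_kwargs)
    if point.failed:
        raise ValueError(f"{method} fit failed on the full sample: {point.failure_reason}")
    theta_hat = point.params.as_array()

    reps = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, sample.n, size=sample.n)
        try:
            res = est.fit(LifetimeSample(sample.values[idx]), method=method,
                          rng=rng, **fit_kwargs)
        except Exception:
            res = None
        if res is None or res.failed:
            n_failed += 1
            continue
        reps.append(res.params.as_array())
    if n_failed > B // 2:
        raise RuntimeError(
            f"{method}: {n_failed}/{B} bootstrap refits failed; interval not reliable"
        )
    reps = np.asarray(reps)

    alpha_lo = 0.5 * (1.0 - level)
    alpha_hi = 1.0 - alpha_lo
    used_bca = False
    accel = np.zeros(3)
    z0 = np.zeros(3)
    if bca:
        # jackknife acceleration
        jack = []
        for i in range(sample.n):
            try:
                res = est.fit(
                    LifetimeSample(np.delete(sample.values, i)),
                    method=method, rng=rng, **fit_kwargs,
                )
            except Exception:
                res = None
            if res is not None and not res.failed:
                jack.append(res.params.as_array())
        jack = np.asarray(jack)
        if jack.shape[0] >= 3 and np.any(jack.std(axis=0) > 0):
            jm = jack.mean(axis=0)
            num = ((jm - jack) ** 3).sum(axis=0)
            den = 6.0 * (((jm - jack) ** 2).sum(axis=0)) ** 1.5
            with np.errstate(divide="ignore", invalid="ignore"):
                accel = np.where(den > 0, num / den, 0.0)
            frac = (reps < theta_hat).mean(axis=0)
            frac = np.clip(frac, 1.0 / (reps.shape[0] + 1), 1.0 - 1.0 / (reps.shape[0] + 1))
            z0 = stats.norm.ppf(frac)
            used_bca = True

    ivs = {}
    z_lo, z_hi = stats.norm.ppf(alpha_lo), stats.norm.ppf(alpha_hi)
    for j, name in enumerate(_PARAM_NAMES):
        vals = np.sort(reps[:, j])
        if used_bca:
            def adj(z):
                return stats.norm.cdf(z0[j] + (z0[j] + z) / (1.0 - accel[j] * (z0[j] + z)))
            lo_q, hi_q = adj(z_lo), adj(z_hi)
        else:
            lo_q, hi_q = alpha_lo, alpha_hi
        ivs[name] = _percentile_pair(vals, lo_q, hi_q)
    return IntervalSet(
        intervals=ivs,
        method="bootstrap-bca" if used_bca else "bootstrap-percentile",
        level=level,
        B=B,
        seed=seed,
        n_failed=n_failed,
    )
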