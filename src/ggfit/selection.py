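"""Goodness of fit and model discrimination for fitted lifetime models.

KS statistic, asymptotic Kolmogorov p-value, AIC / AICc, and the usual
AIC-difference rule of thumb: models within 2 of the best are all
plausible, a gap of 4-7 means considerably less support, beyond 10
essentially none.

Two caveats are deliberate and documented rather than hidden:

* The KS p-value uses the asymptotic Kolmogorov distribution with the
  *fitted* cdf plugged in.  With estimated parameters this test is
  conservative (p-values biased upward); a parametric-bootstrap p-value is
  available behind ``bootstrap_p=True`` for users who need a calibrated
  test.
* The AIC of the GG model is computed from the UNPENALIZED log-likelihood
  evaluated at the (penalized) estimates, so criteria remain comparable
  across families for which no penalty exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import GGParams, LifetimeSample, gg_cdf
from .estimators import FitResult, fit as fit_gg
from .model_zoo import COMPETITOR_FAMILIES, competitor_cdf, fit_competitor_ml

__all__ = ["ModelComparison", "ks_test", "aic_aicc", "rank_models", "compare_models"]


def ks_test(
    sample: LifetimeSample,
    cdf: Callable[[np.ndarray], np.ndarray],
    bootstrap_p: bool = False,
    rvs: Optional[Callable] = None,
    n_boot: int = 500,
    seed=None,
):
    """Kolmogorov-Smirnov distance of the sample from a fitted cdf.

    D_n = max_i max(i/n - F(t_(i)), F(t_(i)) - (i-1)/n); the p-value comes
    from the asymptotic Kolmogorov distribution.  With ``bootstrap_p=True``
    (requires ``rvs``, a sampler ``rvs(n, rng) -> array``), the p-value is
    instead the parametric-bootstrap tail frequency of D_n, which stays
    calibrated when the cdf's parameters were estimated from this sample.

    Returns ``(D_n, p)``.
    """
    n = sample.n
    f = np.asarray(cdf(sample.sorted), dtype=float)
    if np.any(f < -1e-12) or np.any(f > 1.0 + 1e-12):
        raise ValueError("cdf values outside [0, 1]")
    i = np.arange(1, n + 1)
    d = float(np.max(np.maximum(i / n - f, f - (i - 1) / n)))
    d = min(max(d, 0.0), 1.0)
    if not bootstrap_p:
        p = float(stats.kstwobign.sf(np.sqrt(n) * d))
        return d, min(max(p, np.finfo(float).tiny), 1.0)
    if rvs is None:
        raise ValueError("bootstrap_p=True requires an rvs sampler")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        x = np.sort(np.asarray(rvs(n, rng), dtype=float))
        fb = np.asarray(cdf(x), dtype=float)
        db = np.max(np.maximum(i / n - fb, fb - (i - 1) / n))
        count += db >= d
    return d, (count + 1) / (n_boot + 1)


def aic_aicc(loglik: float, c: int, n: int):
    """AIC = -2 loglik + 2c and its small-sample correction
    AICc = AIC + 2c(c+1)/(n-c-1)."""
    aic = -2.0 * loglik + 2.0 * c
    if n <= c + 1:
        raise ValueError(f"AICc undefined for n={n} <= c+1={c + 1}")
    return aic, aic + 2.0 * c * (c + 1.0) / (n - c - 1.0)


def _support_band(delta: float) -> str:
    if delta < 2.0:
        return "plausible"
    if 4.0 < delta < 7.0:
        return "considerably less support"
    if delta > 10.0:
        return "essentially no support"
    return "intermediate support"


@dataclass
class ModelComparison:
    """Ranked comparison table for one sample.

    ``table`` rows are indexed by family and carry loglik, c, AIC, AICc,
    KS_D, KS_p, delta_w and the support band; ``best`` names the minimum-AIC
    family.
    """

    table: pd.DataFrame
    best: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="family")

    def to_json(self) -> str:
        payload = self.table.reset_index(names="family").to_dict(orient="records")
        import json

        return json.dumps({"best": self.best, "models": payload}, indent=2)


def _cdf_for(fit: FitResult) -> Callable:
    if fit.family == "GG":
        return lambda t, p=fit.params: gg_cdf(t, p)
    return lambda t, p=fit.params: competitor_cdf(t, p)


def rank_models(fits, sample: LifetimeSample) -> ModelComparison:
    """Assemble the comparison table from ``(family, FitResult)`` pairs.

    Failed fits are dropped with their reason recorded; at least two live
    fits are required for a ranking to mean anything.
    """
    rows = {}
    for family, fr in fits:
        if fr.failed or fr.params is None:
            continue
        cdf = _cdf_for(fr)
        d, p = ks_test(sample, cdf)
        aic, aicc = aic_aicc(fr.loglik, 3, sample.n)
        rows[family] = {
            "loglik": fr.loglik,
            "c": 3,
            "AIC": aic,
            "AICc": aicc,
            "KS_D": d,
            "KS_p": p,
            "KS_reject_5pct": p < 0.05,
        }
    if len(rows) < 2:
        raise ValueError("need at least two successful fits to rank models")
    table = pd.DataFrame.from_dict(rows, orient="index")
    amin = table["AIC"].min()
    table["delta_w"] = table["AIC"] - amin
    table["support"] = table["delta_w"].map(_support_band)
    table = table.sort_values("AIC")
    return ModelComparison(table=table, best=table.index[0])


def compare_models(
    sample: LifetimeSample,
    families=("GG",) + COMPETITOR_FAMILIES,
    seed=None,
    gg_method: str = "PML",
    **fit_kwargs,
) -> ModelComparison:
    """Fit the requested families and rank them on one sample.

    GG is fitted by the penalized default (its AIC still uses the plain
    log-likelihood at those estimates); competitors are fitted by ML.
    """
    rng = np.random.default_rng(seed)
    fits = []
    for family in families:
        fam = family.upper()
        if fam == "GG":
            fits.append((fam, fit_gg(sample, method=gg_method, rng=rng, **fit_kwargs)))
        else:
            fits.append((fam, fit_competitor_ml(sample, fam, rng=rng, **fit_kwargs)))
    return rank_models(fits, sample)
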