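"""Simulated annealing (SANN) minimizer with step-size adaptation.

The schedule is the classic Metropolis-style one: from the current point x,
propose x' = x + r*V with r ~ U(-1, 1) per coordinate; accept downhill moves
always and uphill moves with probability exp(-dg/k); every ``s`` iterations
rescale the step vector V so the recent acceptance fraction approaches 50%;
every ``m`` iterations cool k <- rk * k.  The run stops when k falls below
``k_min``, when no new solution has been accepted for ``stop_repeat``
consecutive proposals, or at ``max_iter``.  The best point ever visited is
returned, not the last one.

Estimators in this package hand over *log*-parameters, so the positivity
constraints of the lifetime models vanish and the uniform box proposal is
scale-appropriate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["SANNConfig", "SANNResult", "sann_minimize"]


@dataclass
class SANNConfig:
    """Control parameters of the annealing schedule.

    Parameters
    ----------
    k0 : float or None
        Initial control parameter (temperature).  ``None`` uses
        ``max(1, log g(x0))``, guarded so it stays positive when the
        objective at the start is at most one.
    rk : float
        Cooling rate in [0, 1]; k is multiplied by ``rk`` every ``m``
        iterations.  0.95 is the customary choice.
    m, s : int
        Iterations per cooling stage and per step-vector adaptation.
    step : sequence of float, optional
        Initial per-coordinate step sizes V (default: all ones).
    max_iter, stop_repeat : int
        Hard iteration cap and the no-acceptance streak that stops the run.
    k_min : float
        "Sufficiently small" temperature at which the run stops; the
        threshold is deliberately exposed rather than hard-coded.
    seed : int, optional
        Seed for the proposal stream when no generator is passed in.
    """

    k0: Optional[float] = None
    rk: float = 0.95
    m: int = 100
    s: int = 20
    step: Optional[Sequence[float]] = None
    max_iter: int = 20000
    stop_repeat: int = 500
    k_min: float = 1e-8
    seed: Optional[int] = None
    keep_trace: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.rk <= 1.0):
            raise ValueError("rk must lie in [0, 1]")
        for name in ("m", "s", "max_iter", "stop_repeat"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.step is not None and np.any(np.asarray(self.step, float) <= 0):
            raise ValueError("step sizes must be positive")


@dataclass
class SANNResult:
    x_opt: np.ndarray
    f_opt: float
    n_iter: int
    accepted_frac: float
    trace: list = field(default_factory=list)


def sann_minimize(
    objective: Callable[[np.ndarray], float],
    x0,
    config: SANNConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SANNResult:
    """Minimize ``objective`` from ``x0`` by simulated annealing.

    Non-finite proposals are treated as infinitely uphill (always rejected);
    a non-finite objective at ``x0`` itself is an error.
    """
    cfg = config or SANNConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    f = float(objective(x))
    if not np.isfinite(f):
        raise ValueError("objective must be finite at the initial point")

    v = np.ones(d) if cfg.step is None else np.asarray(cfg.step, dtype=float).copy()
    if cfg.k0 is not None:
        k = float(cfg.k0)
    else:
        k = max(1.0, np.log(f)) if f > 1.0 else 1.0

    x_best, f_best = x.copy(), f
    trace = []
    n_accept_total = 0
    n_accept_window = 0
    since_accept = 0
    i = 0
    while i < cfg.max_iter:
        i += 1
        r = rng.uniform(-1.0, 1.0, size=d)
        x_new = x + r * v
        with np.errstate(all="ignore"):
            f_new = float(objective(x_new))
        if np.isfinite(f_new):
            dg = f_new - f
            if dg <= 0.0:
                accept = True
            else:
                p = np.exp(-dg / k) if k > 0.0 else 0.0
                accept = rng.uniform() < p
        else:
            accept = False
        if accept:
            x, f = x_new, f_new
            n_accept_total += 1
            n_accept_window += 1
            since_accept = 0
            if f < f_best:
                f_best, x_best = f, x.copy()
                if cfg.keep_trace:
                    trace.append((i, f_best))
        else:
            since_accept += 1

        if i % cfg.s == 0:
            # Corana-style adaptation toward 50% acceptance
            frac = n_accept_window / cfg.s
            if frac > 0.6:
                v *= 1.0 + 2.0 * (frac - 0.6) / 0.4
            elif frac < 0.4:
                v /= 1.0 + 2.0 * (0.4 - frac) / 0.4
            n_accept_window = 0
        if i % cfg.m == 0:
            k *= cfg.rk
        if k < cfg.k_min or since_accept >= cfg.stop_repeat:
            break

    return SANNResult(
        x_opt=x_best,
        f_opt=f_best,
        n_iter=i,
        accepted_frac=n_accept_total / max(i, 1),
        trace=trace,
    )
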