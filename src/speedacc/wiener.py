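"""Two-boundary Wiener diffusion: single-trial simulation and closed-form oracles.

A decision process accumulates evidence ``X(t) = start + v*t + sigma*W(t)``
between an upper boundary at ``a`` (correct response) and a lower boundary at
``0`` (error).  The first-passage time is the decision time; a constant
non-decision time ``t_er`` is added to yield the response time (RT).

Simulation uses an Euler-Maruyama discretization with step ``dt`` (default
1 ms, i.e. millisecond RT resolution):

    X <- X + v*dt + sigma*sqrt(dt)*N(0, 1)

absorbed at ``X >= a`` (correct) or ``X <= 0`` (error).  The scheme carries a
positive O(sqrt(dt)) first-passage bias (the discrete path can overshoot a
boundary between steps), so simulated mean decision times slightly exceed the
closed forms at dt = 1 ms; the bias shrinks as dt is reduced, which the test
suite verifies against the analytic oracles below.

Time is in milliseconds throughout.  Evidence units are arbitrary: only the
ratios ``v*a/sigma^2`` and ``a^2/sigma^2`` matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from numba import njit

__all__ = [
    "DiffusionParams",
    "TrialResult",
    "simulate_trial",
    "simulate_trials",
    "analytic_accuracy",
    "analytic_mean_dt",
    "InvalidParameterError",
    "MaxDurationError",
    "DEFAULT_DT",
    "DEFAULT_MAX_STEPS",
    "DEFAULT_SIGMA",
]

#: Default Euler step (ms); matches the millisecond resolution of empirical RTs.
DEFAULT_DT = 1.0
#: Default cap on the number of Euler steps per trial.
DEFAULT_MAX_STEPS = 20_000
#: Default diffusion noise scale (evidence units per sqrt(ms)).
DEFAULT_SIGMA = 4.0


class InvalidParameterError(ValueError):
    """A diffusion parameter is non-finite or violates its domain."""


class MaxDurationError(RuntimeError):
    """A trial failed to reach either boundary within ``max_steps`` steps."""


@dataclass(frozen=True)
class DiffusionParams:
    """One trial-generating parameter set.

    Parameters
    ----------
    v : float
        Drift rate (evidence units per ms).  Positive drift favours the
        correct (upper) boundary.
    a : float
        Threshold separation (evidence units); must be positive.
    start : float, optional
        Starting activation.  Defaults to the unbiased midpoint ``0.5 * a``.
    sigma : float
        Diffusion noise scale (evidence units per sqrt(ms)).
    t_er : float
        Non-decision time in ms, added to the decision time.
    """

    v: float
    a: float
    start: float | None = None
    sigma: float = DEFAULT_SIGMA
    t_er: float = 0.0

    def __post_init__(self) -> None:
        if self.start is None:
            object.__setattr__(self, "start", 0.5 * self.a)
        vals = (self.v, self.a, self.start, self.sigma, self.t_er)
        if not all(math.isfinite(x) for x in vals):
            raise InvalidParameterError(f"non-finite diffusion parameter in {vals}")
        if self.a <= 0:
            raise InvalidParameterError(f"threshold separation a must be > 0, got {self.a}")
        if not (0 < self.start < self.a):
            raise InvalidParameterError(
                f"start must lie strictly between the boundaries (0, {self.a}), got {self.start}"
            )
        if self.sigma <= 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.t_er < 0:
            raise InvalidParameterError(f"t_er must be >= 0, got {self.t_er}")


@dataclass(frozen=True)
class TrialResult:
    """First-passage outcome of a single trial: RT in ms and correctness."""

    rt: float
    correct: bool


@njit(cache=True)
def _first_passage_batch(v, a, start, sigma, t_er, dt, max_steps, n, rng):  # pragma: no cover
    """Sequentially simulate n first-passage trials from one random stream.

    Trials are generated one after the other, each drawing standard normals
    from ``rng`` step by step, so a batch of n trials consumes the stream
    exactly as n consecutive single-trial calls would.  Trials that exceed
    max_steps get rt = NaN.
    """
    rts = np.empty(n, dtype=np.float64)
    correct = np.empty(n, dtype=np.bool_)
    drift = v * dt
    noise = sigma * math.sqrt(dt)
    for i in range(n):
        x = start
        step = 0
        absorbed = False
        while step < max_steps:
            step += 1
            x += drift + noise * rng.standard_normal()
            if x >= a:
                rts[i] = step * dt + t_er
                correct[i] = True
                absorbed = True
                break
            if x <= 0.0:
                rts[i] = step * dt + t_er
                correct[i] = False
                absorbed = True
                break
        if not absorbed:
            rts[i] = np.nan
            correct[i] = False
    return rts, correct


def simulate_trials(
    params: DiffusionParams,
    n: int,
    rng: np.random.Generator,
    *,
    dt: float = DEFAULT_DT,
    max_steps: int = DEFAULT_MAX_STEPS,
    on_max: str = "raise",
) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` independent trials; returns ``(rts, correct)`` arrays.

    The batch consumes the random stream exactly as ``n`` consecutive
    :func:`simulate_trial` calls sharing ``rng`` would, so the two entry
    points are observationally equivalent.

    ``on_max`` controls trials that exhaust ``max_steps``: ``"raise"``
    (library default) raises :class:`MaxDurationError`; ``"drop"`` removes
    them from the returned arrays (study mode; callers can log the shortfall
    as ``n - len(rts)``).
    """
    if not isinstance(params, DiffusionParams):
        params = DiffusionParams(*params)
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if dt <= 0 or not math.isfinite(dt):
        raise InvalidParameterError(f"dt must be a positive finite step, got {dt}")
    if on_max not in ("raise", "drop"):
        raise ValueError(f"on_max must be 'raise' or 'drop', got {on_max!r}")
    rts, correct = _first_passage_batch(
        params.v, params.a, params.start, params.sigma, params.t_er,
        dt, max_steps, n, rng,
    )
    overflow = np.isnan(rts)
    if overflow.any():
        if on_max == "raise":
            raise MaxDurationError(
                f"{int(overflow.sum())} of {n} trials exceeded max_steps={max_steps} "
                f"(dt={dt}, params={params})"
            )
        keep = ~overflow
        rts, correct = rts[keep], correct[keep]
    return rts, correct


def simulate_trial(
    params: DiffusionParams,
    rng: np.random.Generator,
    *,
    dt: float = DEFAULT_DT,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> TrialResult:
    """Simulate a single first-passage trial.

    Raises :class:`MaxDurationError` if neither boundary is reached within
    ``max_steps`` Euler steps.
    """
    rts, correct = simulate_trials(params, 1, rng, dt=dt, max_steps=max_steps, on_max="raise")
    return TrialResult(rt=float(rts[0]), correct=bool(correct[0]))


def analytic_accuracy(params: DiffusionParams) -> float:
    """Exact probability of absorption at the upper (correct) boundary.

    For the continuous process, with ``theta = 2*v/sigma^2``:

        P(correct) = (1 - exp(-theta*start)) / (1 - exp(-theta*a))

    continuous at ``v = 0`` where the limit is ``start / a``.  For the
    unbiased start ``start = a/2`` this reduces to the logistic
    ``1 / (1 + exp(-v*a/sigma^2))``.
    """
    if not isinstance(params, DiffusionParams):
        params = DiffusionParams(*params)
    theta = 2.0 * params.v / params.sigma**2
    # The formula is 0/0 at v = 0; switch to the limit when theta*a is tiny.
    if abs(theta * params.a) < 1e-12:
        return params.start / params.a
    return float(np.expm1(-theta * params.start) / np.expm1(-theta * params.a))


def analytic_mean_dt(params: DiffusionParams) -> float:
    """Exact mean decision time (ms, excluding ``t_er``) for an unbiased start.

    For ``start = a/2``:

        E[DT] = (a / (2v)) * tanh(v*a / (2*sigma^2))    for v != 0
        E[DT] = a^2 / (4*sigma^2)                        for v = 0

    The value is even in ``v`` (tanh is odd, the prefactor is odd).  Only the
    unbiased start is supported; other starting points raise
    ``NotImplementedError``.
    """
    if not isinstance(params, DiffusionParams):
        params = DiffusionParams(*params)
    if not math.isclose(params.start, 0.5 * params.a, rel_tol=1e-12, abs_tol=0.0):
        raise NotImplementedError(
            f"analytic_mean_dt requires start = a/2, got start={params.start}, a={params.a}"
        )
    arg = params.v * params.a / (2.0 * params.sigma**2)
    if abs(arg) < 1e-12:
        return params.a**2 / (4.0 * params.sigma**2)
    return float((params.a / (2.0 * params.v)) * math.tanh(arg))
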