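"""Immigration-death ("box") process: exact simulation and analytic oracles.

The box model describes a region (a shop, a street, a city) that people
enter at a constant rate ``alpha`` and leave independently at a per-capita
rate ``beta``.  The count ``x(t)`` of people inside is a continuous-time
Markov birth-death chain whose stationary distribution is Poisson with mean
``gamma = alpha / beta``.

The module provides

* an exact event-driven (Gillespie) sampler, both for single trajectories
  and vectorised over an ensemble of independent realisations;
* the closed-form mean ``u(t) = gamma + (u0 - gamma) e^{-beta t}`` and
  variance
  ``v(t) = gamma + (u0 - gamma) e^{-beta t}
          + [v0 - gamma - (u0 - gamma)] e^{-2 beta t}``;
* a truncated master-equation integrator for the full count distribution
  ``p_n(t)``, with explicit tracking of probability mass leaked past the
  truncation bound;
* a pooled empirical autocorrelation estimator for stationary ensembles.

The closed forms and the integrator serve as independent oracles for each
other and for the stochastic sampler, which is what makes this model a good
test bed for ensemble filtering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import expm_multiply

__all__ = [
    "BoxParams",
    "BoxTrajectory",
    "MomentState",
    "CountDistribution",
    "AutocorrelationEstimate",
    "simulate_box",
    "simulate_box_ensemble",
    "mean_solution",
    "variance_solution",
    "moments_at",
    "integrate_master_equation",
    "empirical_autocorrelation",
]


@dataclass(frozen=True)
class BoxParams:
    """Rates of the immigration-death process.

    Parameters
    ----------
    alpha
        Arrival rate, events per unit time.  Must be non-negative.
    beta
        Per-capita departure rate, per unit time.  Must be positive.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")

    @property
    def gamma(self) -> float:
        """Stationary mean ``alpha / beta`` (recomputed on access)."""
        return self.alpha / self.beta


@dataclass(frozen=True)
class BoxTrajectory:
    """A realisation of the box process sampled on a time grid.

    Between recorded times the underlying path is piecewise constant; the
    value recorded at each output time is the state immediately at (or
    carried forward to) that time.
    """

    times: np.ndarray
    counts: np.ndarray
    seed: object = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts)
        if times.shape != counts.shape:
            raise ValueError("times and counts must have equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class MomentState:
    """Mean and variance of the count at elapsed time ``t``."""

    u0: float
    v0: float
    t: float
    u: float
    v: float


@dataclass(frozen=True)
class AutocorrelationEstimate:
    """Estimated stationary autocorrelation ``a_h`` per lag ``h``."""

    lags: np.ndarray
    values: np.ndarray
    n_realizations: int


@dataclass
class CountDistribution:
    """A (possibly truncated) distribution over counts ``0..n_max``.

    ``leak`` is the probability mass unaccounted for beyond ``n_max``;
    ``sum(probs) + leak == 1`` within floating tolerance.
    """

    n_max: int
    probs: np.ndarray
    leak: float = 0.0
    leak_warning: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (self.n_max + 1,):
            raise ValueError("probs must have length n_max + 1")
        if np.any(probs < -1e-12):
            raise ValueError("probs must be non-negative")
        total = probs.sum() + self.leak
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probs + leak must sum to 1, got {total}")
        self.probs = probs

    @classmethod
    def poisson(cls, mean: float, n_max: int) -> "CountDistribution":
        from scipy.stats import poisson as _pois

        n = np.arange(n_max + 1)
        probs = _pois.pmf(n, mean)
        return cls(n_max=n_max, probs=probs, leak=float(1.0 - probs.sum()))

    @classmethod
    def delta(cls, n: int, n_max: int) -> "CountDistribution":
        probs = np.zeros(n_max + 1)
        probs[n] = 1.0
        return cls(n_max=n_max, probs=probs)

    def mean(self) -> float:
        n = np.arange(self.n_max + 1)
        return float(n @ self.probs)

    def variance(self) -> float:
        n = np.arange(self.n_max + 1)
        m = self.mean()
        return float(((n - m) ** 2) @ self.probs)

    def total_variation(self, other: "CountDistribution") -> float:
        n = min(self.n_max, other.n_max)
        a, b = self.probs[: n + 1], other.probs[: n + 1]
        tail = self.probs[n + 1 :].sum() + other.probs[n + 1 :].sum()
        return float(0.5 * (np.abs(a - b).sum() + tail + self.leak + other.leak))


# ---------------------------------------------------------------------------
# Exact stochastic simulation
# ---------------------------------------------------------------------------


def advance_counts(
    alpha,
    beta,
    counts: np.ndarray,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance an array of independent box realisations by ``dt``.

    Vectorised Gillespie stepper: all realisations are advanced in lock-step
    by drawing exponential waiting times from each realisation's current
    total event rate ``alpha + beta * x``.  A realisation whose next event
    would fall beyond ``dt`` keeps its state (carry-forward), which is the
    exact distribution of the state at ``dt``.

    ``alpha`` and ``beta`` may be scalars or arrays of the same length as
    ``counts`` (per-realisation rates, used for parameter-augmented
    ensembles).
    """
    x = np.asarray(counts).astype(np.int64).copy()
    n = x.shape[0]
    alpha_v = np.broadcast_to(np.asarray(alpha, dtype=float), (n,))
    beta_v = np.broadcast_to(np.asarray(beta, dtype=float), (n,))
    if np.any(x < 0):
        raise ValueError("counts must be non-negative integers")
    t = np.zeros(n)
    active = np.ones(n, dtype=bool)
    while True:
        rates = alpha_v + beta_v * x
        active &= rates > 0.0
        if not active.any():
            break
        tau = rng.exponential(size=n) / np.where(rates > 0.0, rates, 1.0)
        t = np.where(active, t + tau, t)
        active &= t <= dt
        if not active.any():
            break
        u = rng.random(n)
        arrival = u * rates < alpha_v
        step = np.where(arrival, 1, -1)
        x = np.where(active, x + step, x)
    return x


def simulate_box(
    params: BoxParams,
    x0: int,
    output_times,
    rng: np.random.Generator | int,
) -> BoxTrajectory:
    """Sample one exact box-model trajectory on the given time grid.

    The process starts from integer count ``x0`` at time 0 and is recorded
    at each of the strictly increasing ``output_times`` by carry-forward of
    the state at that time.
    """
    if isinstance(rng, (int, np.integer)):
        seed, rng = rng, np.random.default_rng(rng)
    else:
        seed = None
    x0 = _check_integer_count(x0)
    times = np.asarray(output_times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("output_times must be a non-empty 1-D grid")
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("output_times must be non-negative and increasing")
    counts = simulate_box_ensemble(params, np.array([x0]), times, rng)[:, 0]
    return BoxTrajectory(times=times, counts=counts, seed=seed)


def simulate_box_ensemble(
    params: BoxParams,
    x0s: np.ndarray,
    output_times,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample many independent box trajectories on a common grid.

    Returns an array of shape ``(len(output_times), len(x0s))``.  All
    realisations consume the shared generator in lock-step, so results are
    reproducible for a fixed seed and ensemble size.
    """
    times = np.asarray(output_times, dtype=float)
    x = np.asarray(x0s).astype(np.int64)
    if np.any(x < 0):
        raise ValueError("initial counts must be non-negative")
    out = np.empty((times.size, x.size), dtype=np.int64)
    prev = 0.0
    for j, t in enumerate(times):
        dt = t - prev
        if dt > 0:
            x = advance_counts(params.alpha, params.beta, x, dt, rng)
        out[j] = x
        prev = t
    return out


def _check_integer_count(x0) -> int:
    if isinstance(x0, (bool, np.bool_)):
        raise ValueError("x0 must be an integer count")
    xf = float(x0)
    if not xf.is_integer():
        raise ValueError(f"x0 must be an integer count, got {x0}")
    if xf < 0:
        raise ValueError(f"x0 must be non-negative, got {x0}")
    return int(xf)


# ---------------------------------------------------------------------------
# Closed-form moments
# ---------------------------------------------------------------------------


def mean_solution(params: BoxParams, u0: float, t) -> float | np.ndarray:
    """Mean count ``u(t) = gamma + (u0 - gamma) e^{-beta t}``.

    Monotone in ``t`` towards the stationary mean ``gamma``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    g = params.gamma
    out = g + (u0 - g) * np.exp(-params.beta * t)
    return float(out) if out.ndim == 0 else out


def variance_solution(params: BoxParams, u0: float, v0: float, t) -> float | np.ndarray:
    """Variance of the count,

    ``v(t) = gamma + (u0 - gamma) e^{-beta t}
            + [v0 - gamma - (u0 - gamma)] e^{-2 beta t}``.

    For a Poisson initial condition (``v0 == u0``) the bracketed term
    vanishes and ``v(t) == u(t)`` for all ``t`` — the process preserves
    Poisson marginals.
    """
    if v0 < 0:
        raise ValueError("v0 must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    g = params.gamma
    e1 = np.exp(-params.beta * t)
    e2 = np.exp(-2.0 * params.beta * t)
    out = g + (u0 - g) * e1 + (v0 - g - (u0 - g)) * e2
    return float(out) if out.ndim == 0 else out


def moments_at(params: BoxParams, u0: float, v0: float, t: float) -> MomentState:
    """Closed-form mean and variance bundled with their initial condition."""
    return MomentState(
        u0=u0,
        v0=v0,
        t=t,
        u=mean_solution(params, u0, t),
        v=variance_solution(params, u0, v0, t),
    )


# ---------------------------------------------------------------------------
# Master equation
# ---------------------------------------------------------------------------


def default_truncation(params: BoxParams) -> int:
    """Default truncation bound ``gamma + 10 sqrt(gamma)`` (at least 50)."""
    g = params.gamma
    return int(max(50, math.ceil(g + 10.0 * math.sqrt(max(g, 1.0)))))


def integrate_master_equation(
    params: BoxParams,
    p0: CountDistribution,
    t: float,
    n_max: int | None = None,
    leak_tol: float = 1e-8,
) -> CountDistribution:
    """Integrate the truncated master equation

    ``dp_n/dt = alpha p_{n-1} + beta (n+1) p_{n+1} - (alpha + beta n) p_n``

    forward to time ``t``.  The generator is truncated at ``n_max``
    (default ``gamma + 10 sqrt(gamma)``); probability flowing past the
    bound is lost from the system and reported as ``leak``.  A leak above
    ``leak_tol`` is surfaced as a warning on the result, never silently.

    The truncated system is linear, so the solution is the exact matrix
    exponential applied to ``p0`` (computed by Krylov-free scaling of the
    sparse tridiagonal generator).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if n_max is None:
        n_max = max(default_truncation(params), p0.n_max)
    p = np.zeros(n_max + 1)
    p[: p0.n_max + 1] = p0.probs
    if t == 0:
        return CountDistribution(n_max=n_max, probs=p, leak=p0.leak)

    n = np.arange(n_max + 1, dtype=float)
    diag = -(params.alpha + params.beta * n)
    lower = np.full(n_max, params.alpha)          # from n-1 via arrival
    upper = params.beta * (n[1:])                 # from n+1 via departure
    gen = sparse.diags([lower, diag, upper], offsets=[-1, 0, 1], format="csc")
    probs = expm_multiply(gen * t, p)
    probs = np.clip(probs, 0.0, None)
    leak = float(max(0.0, 1.0 - p0.leak - probs.sum()) + p0.leak)
    # renormalise away the tiny negative clipping residue only
    result = CountDistribution(n_max=n_max, probs=probs, leak=leak)
    if leak > leak_tol:
        msg = (
            f"master-equation truncation at n_max={n_max} leaked {leak:.3e} "
            f"probability mass (tolerance {leak_tol:.1e}); increase n_max"
        )
        result.leak_warning = msg
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return result


# ---------------------------------------------------------------------------
# Autocorrelation
# ---------------------------------------------------------------------------


def empirical_autocorrelation(
    trajectories,
    lags,
    params: BoxParams | None = None,
    burn_in: float | None = None,
) -> AutocorrelationEstimate:
    """Pooled stationary autocorrelation of an ensemble of trajectories.

    ``trajectories`` is either a list of :class:`BoxTrajectory` sharing one
    uniform grid, or a pair ``(times, counts)`` with ``counts`` of shape
    ``(n_times, n_realizations)``.  Samples before the burn-in time
    (default ``5 / beta`` when ``params`` is given, else 0) are discarded;
    the autocorrelation at each requested lag is estimated from all
    realisations pooled, with the grand mean and pooled variance.
    """
    if isinstance(trajectories, tuple):
        times, counts = trajectories
        times = np.asarray(times, dtype=float)
        counts = np.asarray(counts, dtype=float)
    else:
        trajectories = list(trajectories)
        times = np.asarray(trajectories[0].times, dtype=float)
        for tr in trajectories:
            if not np.allclose(tr.times, times):
                raise ValueError("trajectories must share a common grid")
        counts = np.column_stack([tr.counts for tr in trajectories]).astype(float)

    steps = np.diff(times)
    if times.size < 2 or not np.allclose(steps, steps[0]):
        raise ValueError("trajectories must be sampled on a uniform grid")
    dt = float(steps[0])

    if burn_in is None:
        burn_in = 5.0 / params.beta if params is not None else 0.0
    keep = times >= burn_in
    x = counts[keep]
    n_t, n_r = x.shape

    lags = np.asarray(lags, dtype=float)
    if np.any(lags < 0):
        raise ValueError("lags must be non-negative")
    lag_steps = np.rint(lags / dt).astype(int)
    if np.any(np.abs(lag_steps * dt - lags) > 1e-9 + 1e-6 * dt):
        raise ValueError("lags must be multiples of the sampling interval")

    mu = x.mean()
    var = ((x - mu) ** 2).mean()
    if var == 0.0:
        raise ValueError("constant series has undefined autocorrelation")
    values = np.empty(lag_steps.size)
    for j, h in enumerate(lag_steps):
        if n_t - h < 2 or n_r * (n_t - h) < 2:
            raise ValueError(f"fewer than 2 usable samples at lag {lags[j]}")
        a = x[: n_t - h] - mu
        b = x[h:] - mu
        values[j] = (a * b).mean() / var
    return AutocorrelationEstimate(lags=lags, values=values, n_realizations=n_r)
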