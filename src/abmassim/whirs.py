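"""WHIRS shopper/worker compartment model of hourly street footfall.

A fixed pool of ``N`` agents splits into shoppers (``N - N_w``) and workers
(``N_w``).  Shoppers cycle susceptible -> in town -> returned; workers
cycle home <-> work.  A virtual camera counter ``C`` accumulates every
agent movement and is read and reset on the hour, emulating hourly footfall
counts.

Event rates (per hour, time-of-day gated, half-open windows):

* shopper arrival  S -> I at ``epsilon + alpha * S * (I + W) / N`` while
  ``S > 0`` and 09:00 <= h < 18:00 — the ``alpha`` term is a
  rich-get-richer amplification: a busy town attracts more shoppers;
* shopper departure I -> R at ``beta * I`` (any time of day);
* worker to work   H -> W at ``gamma_minus + delta_minus * W`` while
  ``H > 0`` and 06:00 <= h < 10:00 (morning rush);
* worker to home   W -> H at ``gamma_plus + delta_plus * W`` while
  ``W > 0`` and 14:00 <= h < 23:00 (evening rush).

Shopper events move a whole batch of agents whose size is a rounded
lognormal (log-mean ``mu``, log-s.d. ``sigma``), capped at the agents
available; worker events move one agent.  Both arrivals and departures
increment the camera (cameras are direction-blind).  At midnight all
returned shoppers become susceptible again, giving daily periodicity.

The clock is weekday-continuous: hour 23 of one simulated day is followed
directly by hour 0 of the next, with no weekend gap.

Simulation is exact (Gillespie) with piecewise-constant rates: a candidate
waiting time that would cross the next scheduled boundary (hour mark or
rate-window edge) is discarded, the clock jumps to the boundary, scheduled
actions fire, and the draw is taken afresh — valid by memorylessness of
the exponential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WhirsParams",
    "WhirsState",
    "HourlyCounts",
    "WhirsResult",
    "initial_state",
    "shopper_arrival_rate",
    "worker_rates",
    "draw_batch_size",
    "simulate_whirs",
    "WhirsEvolutionModel",
    "whirs_packing_names",
    "pack_whirs",
    "unpack_whirs",
]


@dataclass(frozen=True)
class WhirsParams:
    """All rates, windows and batch parameters of the WHIRS model.

    Rates are events per hour; windows are ``(start_hour, end_hour)``
    half-open intervals in local clock hours.
    """

    n_total: int = 20000
    n_workers: int = 1000
    epsilon: float = 60.0
    alpha: float = 0.15
    beta: float = 0.35
    gamma_minus: float = 60.0
    delta_minus: float = 0.5
    gamma_plus: float = 40.0
    delta_plus: float = 0.25
    mu: float = 1.0
    sigma: float = 0.5
    shopper_window: tuple = (9.0, 18.0)
    worker_arrival_window: tuple = (6.0, 10.0)
    worker_departure_window: tuple = (14.0, 23.0)

    def __post_init__(self) -> None:
        if not 0 <= self.n_workers <= self.n_total:
            raise ValueError("need 0 <= n_workers <= n_total")
        for name in ("epsilon", "alpha", "beta", "gamma_minus", "delta_minus",
                     "gamma_plus", "delta_plus", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class WhirsState:
    """Compartment occupancies, camera counter and model clock (hours)."""

    S: int
    I: int
    R: int
    H: int
    W: int
    C: int = 0
    t: float = 0.0

    def validate(self, params: WhirsParams) -> None:
        vals = (self.S, self.I, self.R, self.H, self.W, self.C)
        if any(v < 0 for v in vals):
            raise ValueError(f"negative compartment in {self}")
        if self.S + self.I + self.R != params.n_total - params.n_workers:
            raise ValueError("shopper conservation violated")
        if self.H + self.W != params.n_workers:
            raise ValueError("worker conservation violated")


@dataclass(frozen=True)
class HourlyCounts:
    """Camera count per simulated hour, labelled by hour start."""

    hour_starts: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        hs = np.asarray(self.hour_starts, dtype=float)
        c = np.asarray(self.counts, dtype=np.int64)
        if hs.shape != c.shape:
            raise ValueError("one count per hour is required")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "hour_starts", hs)
        object.__setattr__(self, "counts", c)


@dataclass
class WhirsResult:
    final_state: WhirsState
    hourly: HourlyCounts
    n_events: int
    states: list = field(default_factory=list)
    audit: np.ndarray | None = None
    clamp_events: int = 0


def initial_state(params: WhirsParams, t: float = 0.0) -> WhirsState:
    """Midnight-style start: everyone home, nobody in town."""
    return WhirsState(
        S=params.n_total - params.n_workers, I=0, R=0,
        H=params.n_workers, W=0, C=0, t=t,
    )


def _in_window(hour_of_day: float, window: tuple) -> bool:
    return window[0] <= hour_of_day < window[1]


def shopper_arrival_rate(state: WhirsState, params: WhirsParams) -> float:
    """Rate of S -> I batch arrivals; zero outside 09:00-18:00 or if S=0."""
    if state.S <= 0 or not _in_window(state.t % 24.0, params.shopper_window):
        return 0.0
    return params.epsilon + params.alpha * state.S * (state.I + state.W) / params.n_total


def worker_rates(state: WhirsState, params: WhirsParams) -> tuple:
    """(to-work, to-home) rates, gated by the rush-hour windows."""
    h = state.t % 24.0
    to_work = 0.0
    if state.H > 0 and _in_window(h, params.worker_arrival_window):
        to_work = params.gamma_minus + params.delta_minus * state.W
    to_home = 0.0
    if state.W > 0 and _in_window(h, params.worker_departure_window):
        to_home = params.gamma_plus + params.delta_plus * state.W
    return to_work, to_home


def draw_batch_size(mu: float, sigma: float, cap: int, rng: np.random.Generator) -> int:
    """Rounded-lognormal batch size, clamped to [1, cap]."""
    if cap < 1:
        raise ValueError("cannot draw a batch when no agents are available")
    draw = math.exp(rng.normal(mu, sigma))
    size = int(math.floor(draw + 0.5))
    return max(1, min(size, cap))


def simulate_whirs(
    params: WhirsParams,
    init: WhirsState,
    t_end: float,
    rng: np.random.Generator,
    max_events: int | None = None,
    record_states: bool = False,
    audit: bool = False,
    check_invariants: bool = False,
) -> WhirsResult:
    """Exact event-driven simulation from ``init.t`` to ``t_end``.

    Hourly camera counts are recorded (and the counter reset) at every
    integer hour boundary reached after the start; the midnight reset
    R -> S fires at hour boundaries divisible by 24.  With ``audit=True``
    an independent per-hour tally of event increments is kept so the
    recorded counts can be cross-checked exactly.  ``max_events`` stops the
    run early after that many individual Gillespie events.
    """
    init.validate(params)
    if t_end <= init.t:
        raise ValueError("t_end must exceed the initial time")
    s = replace(init)
    eps = 1e-9
    # boundaries: integer hours plus any fractional window edges
    edges = sorted({
        params.shopper_window[0] % 24, params.shopper_window[1] % 24,
        params.worker_arrival_window[0] % 24, params.worker_arrival_window[1] % 24,
        params.worker_departure_window[0] % 24, params.worker_departure_window[1] % 24,
    })
    frac_edges = [e for e in edges if abs(e - round(e)) > eps]

    def next_boundary(t: float) -> float:
        nb = math.floor(t + eps) + 1.0
        day0 = math.floor(t / 24.0) * 24.0
        for e in frac_edges:
            for base in (day0, day0 + 24.0):
                cand = base + e
                if t + eps < cand < nb:
                    nb = cand
        return nb

    hour_starts: list = []
    hourly: list = []
    audit_tally: list = []
    states: list = []
    pending_audit = 0
    n_events = 0
    stopped = False

    while s.t < t_end - eps and not stopped:
        rate_arr = shopper_arrival_rate(s, params)
        rate_dep = params.beta * s.I
        rate_tw, rate_th = worker_rates(s, params)
        total = rate_arr + rate_dep + rate_tw + rate_th
        nb = min(next_boundary(s.t), t_end)

        if total > 0.0:
            tau = rng.exponential() / total
        else:
            tau = math.inf

        if s.t + tau >= nb - eps:
            # advance to the boundary; scheduled actions fire there
            s.t = nb
            if abs(nb - round(nb)) < eps and nb <= t_end + eps:
                hour = round(nb)
                hour_starts.append(hour - 1.0)
                hourly.append(s.C)
                audit_tally.append(pending_audit)
                pending_audit = 0
                s.C = 0
                if hour % 24 == 0:
                    s.S += s.R
                    s.R = 0
                if record_states:
                    states.append(replace(s))
            continue

        # an event fires strictly inside the current window
        s.t += tau
        u = rng.random() * total
        if u < rate_arr:
            batch = draw_batch_size(params.mu, params.sigma, s.S, rng)
            s.S -= batch
            s.I += batch
            s.C += batch
            pending_audit += batch
        elif u < rate_arr + rate_dep:
            batch = draw_batch_size(params.mu, params.sigma, s.I, rng)
            s.I -= batch
            s.R += batch
            s.C += batch
            pending_audit += batch
        elif u < rate_arr + rate_dep + rate_tw:
            s.H -= 1
            s.W += 1
            s.C += 1
            pending_audit += 1
        else:
            s.W -= 1
            s.H += 1
            s.C += 1
            pending_audit += 1
        n_events += 1
        if s.S < 0 or s.I < 0 or s.H < 0 or s.W < 0:
            raise AssertionError(f"compartment went negative at t={s.t}: {s}")
        if check_invariants:
            s.validate(params)
        if max_events is not None and n_events >= max_events:
            stopped = True

    return WhirsResult(
        final_state=s,
        hourly=HourlyCounts(np.array(hour_starts), np.array(hourly)),
        n_events=n_events,
        states=states,
        audit=np.array(audit_tally) if audit else None,
    )


def rounded_lognormal_mean(mu: float, sigma: float, k_max: int = 100000) -> float:
    """Mean of the rounded lognormal batch-size law floored at 1.

    Computed by direct mass summation over the integers (the independent
    oracle for the sampler): P(1) collects all mass below 1.5, and
    P(k) = F(k + 1/2) - F(k - 1/2) for k >= 2.
    """
    if sigma == 0:
        return max(1.0, float(np.floor(np.exp(mu) + 0.5)))
    from scipy.stats import lognorm

    k = np.arange(1, k_max + 1)
    upper = lognorm.cdf(k + 0.5, s=sigma, scale=np.exp(mu))
    lower = lognorm.cdf(k - 0.5, s=sigma, scale=np.exp(mu))
    pmf = upper - lower
    pmf[0] = upper[0]                    # everything below 1.5 rounds/clamps to 1
    tail = 1.0 - upper[-1]
    return float((k * pmf).sum() + tail * (k_max + 1)) / float(pmf.sum() + tail)


def mean_field_hourly_counts(
    template: WhirsParams,
    alphas,
    betas,
    dt: float = 0.02,
) -> np.ndarray:
    """Deterministic mean-field hourly camera counts for rate pairs.

    Integrates the rate equations of the model (expected compartment flows,
    with the time-of-day gating but no stochasticity) over one day from the
    standard midnight start, vectorised over ``(alpha, beta)`` pairs that
    share all other parameters with ``template``.  Batch events contribute
    their expected rounded-lognormal size.  Returns an ``(n_pairs, 24)``
    array of expected counts per hour.

    This is the identifiability yardstick for the planted-truth experiment:
    two rate pairs whose mean profiles are closer than the observation
    error cannot be told apart by any weighting of one day's data.
    """
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    n = alphas.size
    p = template
    # expected batch size of the rounded, floored lognormal
    b_mean = rounded_lognormal_mean(p.mu, p.sigma)
    S = np.full(n, float(p.n_total - p.n_workers))
    I = np.zeros(n)
    H = np.full(n, float(p.n_workers))
    W = np.zeros(n)
    counts = np.zeros((n, 24))
    t = 0.0
    while t < 24.0 - 1e-9:
        h = t % 24.0
        hour = int(h)
        shop_open = p.shopper_window[0] <= h < p.shopper_window[1]
        arr = np.where(
            shop_open & (S > 0), p.epsilon + alphas * S * (I + W) / p.n_total, 0.0
        )
        dep = betas * I
        tw = (p.gamma_minus + p.delta_minus * W) if _in_window(h, p.worker_arrival_window) else 0.0
        tw = np.where(H > 0, tw, 0.0)
        th = (p.gamma_plus + p.delta_plus * W) if _in_window(h, p.worker_departure_window) else 0.0
        th = np.where(W > 0, th, 0.0)
        move_in = np.minimum(arr * b_mean * dt, S)
        move_out = np.minimum(dep * b_mean * dt, I)
        w_in = np.minimum(tw * dt, H)
        w_out = np.minimum(th * dt, W)
        S -= move_in
        I += move_in - move_out
        H += w_out - w_in
        W += w_in - w_out
        counts[:, hour] += move_in + move_out + w_in + w_out
        t += dt
    return counts


# ---------------------------------------------------------------------------
# EnKF packing and evolution adapter
# ---------------------------------------------------------------------------

_PARAM_NAMES_TIED = ("N", "Nw", "alpha", "beta", "epsilon", "gamma",
                     "delta_plus", "delta_minus", "sigma", "mu")
_PARAM_NAMES_SPLIT = ("N", "Nw", "alpha", "beta", "epsilon", "gamma_minus",
                      "gamma_plus", "delta_plus", "delta_minus", "sigma", "mu")


def whirs_packing_names(tie_gamma: bool = False) -> tuple:
    """State-vector component order used by the filter.

    Model components first — ``(S, I, H, C)`` — then the parameters.  With
    ``tie_gamma=True`` a single ``gamma`` drives both worker windows and
    the layout is the 14-component one; the default keeps ``gamma_minus``
    and ``gamma_plus`` separate (15 components).  ``mu`` is always last
    because it is the one component that may be negative and is therefore
    left out of the log transform.
    """
    params = _PARAM_NAMES_TIED if tie_gamma else _PARAM_NAMES_SPLIT
    return ("S", "I", "H", "C") + params


def whirs_log_mask(tie_gamma: bool = False) -> np.ndarray:
    names = whirs_packing_names(tie_gamma)
    return np.array([n != "mu" for n in names])


def pack_whirs(state: WhirsState, params: WhirsParams, tie_gamma: bool = False) -> np.ndarray:
    if tie_gamma:
        tail = [params.gamma_minus, params.delta_plus, params.delta_minus,
                params.sigma, params.mu]
    else:
        tail = [params.gamma_minus, params.gamma_plus, params.delta_plus,
                params.delta_minus, params.sigma, params.mu]
    return np.array(
        [state.S, state.I, state.H, state.C,
         params.n_total, params.n_workers,
         params.alpha, params.beta, params.epsilon] + tail, dtype=float
    )


def unpack_whirs(
    values: np.ndarray,
    template: WhirsParams,
    tie_gamma: bool = False,
    t: float = 0.0,
):
    """Rebuild (state, params) from a packed vector.

    Counts are rounded half-away and clamped at 0; ``R`` and ``W`` are
    reconstructed from the conservation identities
    ``R = (N - Nw) - S - I`` and ``W = Nw - H``.  If a reconstructed
    compartment would be negative it is clamped to 0 and the paired
    compartment adjusted to restore conservation; the number of such clamp
    events is returned.
    """
    v = np.asarray(values, dtype=float)
    names = whirs_packing_names(tie_gamma)
    if v.shape != (len(names),):
        raise ValueError(f"expected {len(names)} components, got {v.shape}")
    d = dict(zip(names, v))

    def rnd(x):
        return max(int(math.floor(abs(x) + 0.5)), 0)

    clamps = 0
    n_total = max(rnd(d["N"]), 2)
    n_workers = min(max(rnd(d["Nw"]), 0), n_total)
    S, I, H, C = rnd(d["S"]), rnd(d["I"]), rnd(d["H"]), rnd(d["C"])
    n_shoppers = n_total - n_workers
    if S + I > n_shoppers:
        over = S + I - n_shoppers
        take = min(S, over)
        S -= take
        I -= over - take
        clamps += 1
    R = n_shoppers - S - I
    if H > n_workers:
        H = n_workers
        clamps += 1
    W = n_workers - H

    gm = d["gamma"] if tie_gamma else d["gamma_minus"]
    gp = d["gamma"] if tie_gamma else d["gamma_plus"]
    params = replace(
        template,
        n_total=n_total, n_workers=n_workers,
        alpha=max(d["alpha"], 0.0), beta=max(d["beta"], 0.0),
        epsilon=max(d["epsilon"], 0.0),
        gamma_minus=max(gm, 0.0), gamma_plus=max(gp, 0.0),
        delta_plus=max(d["delta_plus"], 0.0),
        delta_minus=max(d["delta_minus"], 0.0),
        sigma=max(d["sigma"], 0.0), mu=d["mu"],
    )
    state = WhirsState(S=S, I=I, R=R, H=H, W=W, C=C, t=t)
    return state, params, clamps


from .enkf import EvolutionModel  # noqa: E402  (adapter lives with the model)


class WhirsEvolutionModel(EvolutionModel):
    """EnKF adapter: packed vector in, one simulated interval, vector out.

    The repacked ``C`` is the camera count accumulated over ``(t0, t1]``,
    i.e. the hourly count when the interval is one hour.  Clamp events from
    conservation repair are accumulated on ``clamp_events``.
    """

    def __init__(self, template: WhirsParams | None = None, tie_gamma: bool = False):
        self.template = template if template is not None else WhirsParams()
        self.tie_gamma = tie_gamma
        self.names = whirs_packing_names(tie_gamma)
        self.log_mask = whirs_log_mask(tie_gamma)
        self.clamp_events = 0

    def evolve(self, values, t0, t1, rng):
        state, params, clamps = unpack_whirs(values, self.template, self.tie_gamma, t=t0)
        self.clamp_events += clamps
        state.C = 0
        res = simulate_whirs(params, state, t1, rng)
        final = res.final_state
        c_window = int(res.hourly.counts.sum()) + final.C
        final = replace(final, C=c_window)
        return pack_whirs(final, params, self.tie_gamma)
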