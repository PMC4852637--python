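"""Perturbed-observation ensemble Kalman filter over stochastic simulators.

The filter alternates two steps over a sequence of observation times:

* *forecast*: every ensemble member is evolved independently by the model,
  each with its own randomness substream;
* *analysis*: per-member "virtual observations" are drawn around the real
  observation from N(0, R) and each member is shifted by the Kalman gain
  times its innovation,

  ``x_hat(i) = x_f(i) + K [z(i) - H x_f(i)]``,
  ``K = P_f H' (H P_f H' + R)^{-1}``.

Ensemble mean and covariance (1/(N-1) normalisation) summarise the forecast
and analysis at every step.  Unknown parameters are estimated sequentially
by appending them to the state vector: they persist through the forecast
and are updated only through their ensemble covariance with the observed
components.  Components spanning orders of magnitude can be filtered in
natural-log space via a per-component mask; values at or below a positivity
floor are clamped before logging and the clamp events counted.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StateVector",
    "Ensemble",
    "EvolutionModel",
    "FunctionModel",
    "ObservationModel",
    "FilterStepResult",
    "FilterRun",
    "StatePacking",
    "ensemble_moments",
    "kalman_gain",
    "forecast_ensemble",
    "assimilate",
    "log_transform",
    "inverse_log_transform",
    "run_filter",
    "BoxEvolutionModel",
    "BoxAugmentedModel",
]


@dataclass(frozen=True)
class StateVector:
    """An ordered, named numeric state with an optional log-space mask."""

    names: tuple
    values: np.ndarray
    log_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        names = tuple(self.names)
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        if values.shape != (len(names),):
            raise ValueError("values must match names in length")
        mask = self.log_mask
        mask = np.zeros(len(names), bool) if mask is None else np.asarray(mask, bool)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "log_mask", mask)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


@dataclass(frozen=True)
class Ensemble:
    """N state vectors sharing names/log-mask, stored as an (N, n) array."""

    names: tuple
    values: np.ndarray
    time: float = 0.0
    log_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        names = tuple(self.names)
        if values.shape[1] != len(names):
            raise ValueError("member dimension must match names")
        if values.shape[0] < 2:
            raise ValueError("an ensemble needs N >= 2 members")
        mask = self.log_mask
        mask = np.zeros(len(names), bool) if mask is None else np.asarray(mask, bool)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "log_mask", mask)

    @property
    def n_members(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def members(self):
        return [
            StateVector(self.names, v, self.log_mask.copy()) for v in self.values
        ]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


class EvolutionModel(ABC):
    """A stochastic simulator as a deterministic map of supplied randomness.

    Given identical input state, interval and generator state, the output is
    identical: all stochasticity comes from the generator.  ``q`` records
    the (informational) dimension of randomness consumed per step.
    """

    names: tuple = ()
    q: int | None = None

    @abstractmethod
    def evolve(
        self, values: np.ndarray, t0: float, t1: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Advance one raw-space state vector from t0 to t1."""

    def evolve_batch(
        self, values: np.ndarray, t0: float, t1: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Advance (N, n) member states; default loops with spawned streams."""
        streams = rng.spawn(values.shape[0])
        return np.stack(
            [self.evolve(v, t0, t1, s) for v, s in zip(values, streams)]
        )


class FunctionModel(EvolutionModel):
    """Wrap a plain callable ``f(values, t0, t1, rng) -> values``."""

    def __init__(self, fn, names=(), q=None, batch_fn=None):
        self.fn = fn
        self.names = tuple(names)
        self.q = q
        self.batch_fn = batch_fn

    def evolve(self, values, t0, t1, rng):
        return np.asarray(self.fn(values, t0, t1, rng), dtype=float)

    def evolve_batch(self, values, t0, t1, rng):
        if self.batch_fn is not None:
            return np.asarray(self.batch_fn(values, t0, t1, rng), dtype=float)
        return super().evolve_batch(values, t0, t1, rng)


@dataclass(frozen=True)
class ObservationModel:
    """Linear observation ``z = H x + nu`` with ``nu ~ N(0, R)``."""

    H: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        H = np.atleast_2d(np.asarray(self.H, dtype=float))
        R = np.atleast_2d(np.asarray(self.R, dtype=float))
        if R.shape[0] != R.shape[1] or R.shape[0] != H.shape[0]:
            raise ValueError("R must be m x m with m = rows of H")
        if not np.allclose(R, R.T):
            raise ValueError("R must be symmetric")
        if np.any(np.linalg.eigvalsh(R) < -1e-10):
            raise ValueError("R must be positive semi-definite")
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "R", R)

    @property
    def m(self) -> int:
        return self.H.shape[0]


@dataclass
class FilterStepResult:
    """All intermediate quantities of one forecast/analysis cycle."""

    time: float
    forecast_members: np.ndarray
    forecast_mean: np.ndarray
    forecast_cov: np.ndarray
    gain: np.ndarray
    virtual_obs: np.ndarray
    analysis_members: np.ndarray
    analysis_mean: np.ndarray
    analysis_cov: np.ndarray
    forecast_errors: np.ndarray
    analysis_errors: np.ndarray


@dataclass
class FilterRun:
    """Per-step results of a full filtering pass."""

    steps: list
    times: np.ndarray
    names: tuple
    config: dict = field(default_factory=dict)

    def forecast_means(self) -> np.ndarray:
        return np.stack([s.forecast_mean for s in self.steps])

    def analysis_means(self) -> np.ndarray:
        return np.stack([s.analysis_mean for s in self.steps])

    def forecast_variances(self) -> np.ndarray:
        return np.stack([np.diag(s.forecast_cov) for s in self.steps])

    def analysis_variances(self) -> np.ndarray:
        return np.stack([np.diag(s.analysis_cov) for s in self.steps])


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def ensemble_moments(ensemble: Ensemble | np.ndarray):
    """Arithmetic mean vector and 1/(N-1) sample covariance of the members."""
    values = ensemble.values if isinstance(ensemble, Ensemble) else np.atleast_2d(ensemble)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 members for a covariance")
    mean = values.mean(axis=0)
    dev = values - mean
    cov = dev.T @ dev / (n - 1)
    return mean, cov


def kalman_gain(P_f: np.ndarray, obs: ObservationModel) -> np.ndarray:
    """Gain ``K`` solving ``K (H P_f H' + R) = P_f H'`` by a linear solve."""
    P_f = np.atleast_2d(np.asarray(P_f, dtype=float))
    H, R = obs.H, obs.R
    PHt = P_f @ H.T
    S = H @ PHt + R
    try:
        return np.linalg.solve(S.T, PHt.T).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "innovation covariance H P H' + R is singular; "
            "regularise R with a small positive variance"
        ) from exc


def _sqrt_psd(R: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(R)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def forecast_ensemble(
    ensemble: Ensemble,
    model: EvolutionModel,
    t_next: float,
    rng: np.random.Generator,
) -> Ensemble:
    """Evolve every member independently to ``t_next``.

    Log-masked components are exponentiated before evolution and re-logged
    after, so the model always sees raw-space states.
    """
    if t_next <= ensemble.time:
        raise ValueError("t_next must exceed the ensemble time")
    raw = ensemble.values.copy()
    mask = ensemble.log_mask
    raw[:, mask] = np.exp(raw[:, mask])
    evolved = model.evolve_batch(raw, ensemble.time, t_next, rng)
    evolved = np.asarray(evolved, dtype=float)
    bad = ~np.isfinite(evolved).all(axis=1)
    if bad.any():
        raise FloatingPointError(
            f"model returned non-finite state for member(s) {np.flatnonzero(bad)}"
        )
    out = evolved.copy()
    if mask.any():
        out[:, mask], _ = log_transform(evolved[:, mask])
    return replace(ensemble, values=out, time=float(t_next))


def assimilate(
    forecast: Ensemble,
    z,
    obs: ObservationModel,
    rng: np.random.Generator,
    virtual_noise: bool = True,
) -> FilterStepResult:
    """One perturbed-observation analysis step.

    Draws one virtual observation per member, ``z(i) = z + nu(i)`` with
    ``nu(i) ~ N(0, R)``, and applies the Kalman-gain update.  Setting
    ``virtual_noise=False`` suppresses the perturbations (useful for exact
    limit checks; the posterior spread is then underestimated).
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if z.shape != (obs.m,):
        raise ValueError(f"observation has dimension {z.shape}, expected ({obs.m},)")
    Xf = forecast.values
    N = Xf.shape[0]
    f_mean, P_f = ensemble_moments(Xf)
    K = kalman_gain(P_f, obs)
    if virtual_noise:
        noise = rng.standard_normal((N, obs.m)) @ _sqrt_psd(obs.R).T
    else:
        noise = np.zeros((N, obs.m))
    virtual = z[None, :] + noise
    innovations = virtual - Xf @ obs.H.T
    Xa = Xf + innovations @ K.T
    a_mean, P_a = ensemble_moments(Xa)
    return FilterStepResult(
        time=forecast.time,
        forecast_members=Xf,
        forecast_mean=f_mean,
        forecast_cov=P_f,
        gain=K,
        virtual_obs=virtual,
        analysis_members=Xa,
        analysis_mean=a_mean,
        analysis_cov=P_a,
        forecast_errors=Xf - f_mean,
        analysis_errors=Xa - a_mean,
    )


# ---------------------------------------------------------------------------
# Log-space transform and parameter packing
# ---------------------------------------------------------------------------


def log_transform(values: np.ndarray, floor: float = 1.0):
    """Natural log with a positivity floor.

    Values at or below ``floor`` are clamped to ``floor`` before logging;
    the number of clamp events is returned alongside the result.
    """
    values = np.asarray(values, dtype=float)
    clamped = int(np.count_nonzero(values < floor))
    return np.log(np.maximum(values, floor)), clamped


def inverse_log_transform(values: np.ndarray) -> np.ndarray:
    return np.exp(np.asarray(values, dtype=float))


def transform_state(state: StateVector, floor: float = 1.0):
    """Log-transform the masked components of a raw-space state vector."""
    out = state.values.copy()
    logged, clamped = log_transform(out[state.log_mask], floor)
    out[state.log_mask] = logged
    return replace(state, values=out), clamped


def untransform_state(state: StateVector) -> StateVector:
    out = state.values.copy()
    out[state.log_mask] = np.exp(out[state.log_mask])
    return replace(state, values=out)


@dataclass(frozen=True)
class StatePacking:
    """Fixed packing order of model components followed by parameters."""

    model_names: tuple
    param_names: tuple

    @property
    def names(self) -> tuple:
        return tuple(self.model_names) + tuple(self.param_names)

    def augment(self, model_values, param_values) -> np.ndarray:
        model_values = np.atleast_1d(np.asarray(model_values, dtype=float))
        param_values = np.atleast_1d(np.asarray(param_values, dtype=float))
        if model_values.shape[-1] != len(self.model_names):
            raise ValueError("model values do not match packing order")
        if param_values.shape[-1] != len(self.param_names):
            raise ValueError("parameter values do not match packing order")
        return np.concatenate([model_values, param_values], axis=-1)

    def project_back(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        k = len(self.model_names)
        return values[..., :k], values[..., k:]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown component {name!r}") from None


# ---------------------------------------------------------------------------
# Full filtering pass
# ---------------------------------------------------------------------------


def run_filter(
    model: EvolutionModel,
    times,
    observations,
    obs_model: ObservationModel,
    init: Ensemble,
    rng: np.random.Generator,
    integer_names: tuple = (),
    floors: dict | None = None,
    virtual_noise: bool = True,
    horizon: float | None = None,
) -> FilterRun:
    """Alternate forecast and analysis over all observation times.

    ``integer_names`` lists components the model requires to be integer
    counts; after each analysis they are rounded half-away-from-zero and
    clamped at 0 (in raw space) before the next stochastic forecast.
    ``floors`` maps component names to lower bounds applied after analysis
    (a guard against the linear update driving rates negative).

    With an empty observation list the ensemble is forecast to ``horizon``
    with no analysis steps.
    """
    times = np.asarray(times, dtype=float)
    observations = np.asarray(observations, dtype=float)
    if times.size == 0:
        if horizon is None:
            raise ValueError("need a horizon when there are no observations")
        ens = forecast_ensemble(init, model, horizon, rng)
        mean, cov = ensemble_moments(ens)
        step = FilterStepResult(
            time=horizon,
            forecast_members=ens.values,
            forecast_mean=mean,
            forecast_cov=cov,
            gain=np.zeros((ens.dim, obs_model.m)),
            virtual_obs=np.zeros((ens.n_members, obs_model.m)),
            analysis_members=ens.values,
            analysis_mean=mean,
            analysis_cov=cov,
            forecast_errors=ens.values - mean,
            analysis_errors=ens.values - mean,
        )
        return FilterRun(steps=[step], times=np.array([horizon]), names=init.names)
    if observations.ndim == 1:
        observations = observations[:, None]
    if observations.shape[0] != times.size:
        raise ValueError("one observation per time is required")
    if np.any(np.diff(times) <= 0) or times[0] <= init.time:
        raise ValueError("observation times must be increasing and after init.time")

    int_idx = [init.names.index(n) for n in integer_names]
    floor_items = [(init.names.index(n), v) for n, v in (floors or {}).items()]
    mask = init.log_mask

    ens = init
    steps = []
    for k, (t_k, z_k) in enumerate(zip(times, observations)):
        try:
            ens = forecast_ensemble(ens, model, t_k, rng)
            step = assimilate(ens, z_k, obs_model, rng, virtual_noise=virtual_noise)
        except Exception as exc:
            raise RuntimeError(f"filter step {k} (t={t_k}) failed: {exc}") from exc
        values = step.analysis_members.copy()
        raw = values.copy()
        raw[:, mask] = np.exp(raw[:, mask])
        for i in int_idx:
            raw[:, i] = np.maximum(np.copysign(np.floor(np.abs(raw[:, i]) + 0.5), raw[:, i]), 0.0)
        for i, floor in floor_items:
            raw[:, i] = np.maximum(raw[:, i], floor)
        values = raw
        if mask.any():
            values = raw.copy()
            values[:, mask], _ = log_transform(raw[:, mask])
        ens = replace(ens, values=values, time=float(t_k))
        steps.append(step)
    return FilterRun(steps=steps, times=times, names=init.names)


# ---------------------------------------------------------------------------
# Box-model adapters
# ---------------------------------------------------------------------------


class BoxEvolutionModel(EvolutionModel):
    """Box model with known rates as a one-component evolution model."""

    names = ("x",)
    q = None

    def __init__(self, params):
        self.params = params

    def evolve(self, values, t0, t1, rng):
        return self.evolve_batch(values[None, :], t0, t1, rng)[0]

    def evolve_batch(self, values, t0, t1, rng):
        from .box import advance_counts

        x = _round_counts(values[:, 0])
        x = advance_counts(self.params.alpha, self.params.beta, x, t1 - t0, rng)
        return x[:, None].astype(float)


class BoxAugmentedModel(EvolutionModel):
    """Box model with unknown rates appended to the state.

    Packing order is ``(x, alpha, beta)``; the count evolves by the exact
    simulator under each member's own rates while the rate components
    persist unchanged (their coupling to the data arises only through the
    ensemble covariance with ``x``).
    """

    packing = StatePacking(model_names=("x",), param_names=("alpha", "beta"))
    names = packing.names
    q = None

    def __init__(self, rate_floor: float = 1e-6):
        self.rate_floor = rate_floor

    def evolve(self, values, t0, t1, rng):
        return self.evolve_batch(values[None, :], t0, t1, rng)[0]

    def evolve_batch(self, values, t0, t1, rng):
        from .box import advance_counts

        x = _round_counts(values[:, 0])
        alpha = np.maximum(values[:, 1], 0.0)
        beta = np.maximum(values[:, 2], self.rate_floor)
        x = advance_counts(alpha, beta, x, t1 - t0, rng)
        out = values.copy()
        out[:, 0] = x
        return out


def _round_counts(x: np.ndarray) -> np.ndarray:
    """Round half away from zero and clamp at zero (counts are people)."""
    return np.maximum(np.copysign(np.floor(np.abs(x) + 0.5), x), 0.0).astype(np.int64)
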