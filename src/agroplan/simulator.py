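"""Synthetic farm environment with known ground truth.

The environment models a set of ``m`` fields over a season of ``T`` discrete
steps.  Each field carries a state ``S = {d, e, r, h}``:

* ``d`` — crop vector (growth stage, health, phenotype score), all in [0, 1];
* ``e`` — environment vector (temperature degC, humidity fraction,
  precipitation mm/step);
* ``r`` — cumulative resource use (water L/ha, fertilizer kg/ha, pesticide
  units);
* ``h`` — history lags (last-step yield accrual, last-step water dose,
  last-step fertilizer dose);

plus a latent soil-moisture fraction that drives crop health.  The transition
``S' = Phi(S, u) + eps`` is a documented closed form: soil moisture follows
exponential decay plus irrigation inflow and rainfall, crop health relaxes
toward a moisture-optimum target, growth advances logistically with health,
weather follows AR(1) dynamics around seasonal means, and ``eps`` is
zero-mean Gaussian noise (clipped afterwards to preserve physical bounds).

Outcomes per (field, step) are yield accrual ``Y`` (saturating concave in the
dose, scaled by health), linear resource cost ``C``, and a convex
environmental penalty ``E`` on doses above the saturation point.  The
season objective is ``J = sum_i sum_t [a1*Y - a2*C - a3*E]``, the per-step
reward being the same expression for a single (i, t).

All randomness flows through an explicit :class:`numpy.random.Generator`;
with ``noise_scale = 0`` every map in this module is deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "EnvironmentParams",
    "FieldState",
    "Outcome",
    "ObjectiveWeights",
    "ControlPlan",
    "ObservationBundle",
    "ConstraintReport",
    "make_environment",
    "toy_environment",
    "baseline_state",
    "initial_states",
    "step",
    "outcome",
    "reward",
    "objective",
    "check_constraints",
    "render_observations",
    "rollout",
    "Trajectory",
    "state_features",
]

# index aliases for the crop vector d
GROWTH, HEALTH, PHENOTYPE = 0, 1, 2
# index aliases for the environment vector e
TEMP, HUMIDITY, PRECIP = 0, 1, 2
# resource kinds in the action vector u
WATER, FERT = 0, 1


class ConfigurationError(ValueError):
    """Raised when an environment configuration violates its invariants."""


@dataclass(frozen=True)
class EnvironmentParams:
    """Immutable environment configuration (the transition map's coefficients)."""

    # geometry / horizon
    n_fields: int = 2
    horizon: int = 12
    grid_h: int = 8
    grid_w: int = 8
    n_channels: int = 5
    n_actions: int = 2

    # soil moisture dynamics (fractions per step)
    moisture_decay: float = 0.3          # fraction of moisture lost per step, in (0,1)
    irrigation_efficiency: float = 5e-4  # moisture fraction per (L/ha)
    rain_efficiency: float = 0.01        # moisture fraction per mm
    moisture_optimum: float = 0.55
    moisture_width: float = 0.30

    # crop dynamics
    health_rate: float = 0.5
    growth_rate: float = 0.15

    # weather AR(1)
    temp_mean: float = 22.0
    temp_autocorr: float = 0.7
    humidity_mean: float = 0.6
    humidity_autocorr: float = 0.6
    precip_mean: float = 8.0             # mm per step, seasonal sinusoid around this

    # yield response (per-step accrual)
    baseline_yield: float = 330.0        # kg/ha at zero dose and health 1
    yield_gain: tuple[float, float] = (0.40, 0.25)      # water, fertilizer
    saturation_dose: tuple[float, float] = (400.0, 15.0)  # L/ha, kg/ha per step
    response_exponent: float = 2.0       # diminishing-returns exponent, >= 1

    # cost and environmental penalty
    unit_price: tuple[float, float] = (0.02, 0.5)        # $/L, $/kg
    env_penalty: tuple[float, float] = (1e-5, 5e-3)      # per squared over-dose unit

    # stochasticity: per-component std, all multiplied by noise_scale
    noise_scale: float = 1.0
    moisture_noise: float = 0.02
    health_noise: float = 0.01
    temp_noise: float = 1.5
    humidity_noise: float = 0.03
    precip_noise: float = 2.0
    obs_noise: float = 0.02              # grid observation noise
    sensor_noise: float = 0.02
    forecast_noise: tuple[float, float, float] = (1.0, 0.05, 2.0)
    spatial_amplitude: float = 0.15      # grid heterogeneity, scaled by noise_scale

    # default constraint set
    budget: float = 7000.0
    env_cap: float = 5.0
    dose_lower: tuple[float, float] = (0.0, 0.0)
    dose_upper: tuple[float, float] = (600.0, 25.0)

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_fields", "horizon", "grid_h", "grid_w", "n_channels"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 < self.moisture_decay < 1.0:
            raise ConfigurationError(
                f"moisture_decay must lie in (0, 1), got {self.moisture_decay}")
        if self.noise_scale < 0:
            raise ConfigurationError(f"noise_scale must be >= 0, got {self.noise_scale}")
        if self.response_exponent < 1:
            raise ConfigurationError(
                f"response_exponent must be >= 1, got {self.response_exponent}")
        if self.budget < 0 or self.env_cap < 0:
            raise ConfigurationError("budget and env_cap must be >= 0")
        if any(lo > hi for lo, hi in zip(self.dose_lower, self.dose_upper)):
            raise ConfigurationError("dose_lower must not exceed dose_upper")


def make_environment(config: Mapping | None = None, seed: int = 0) -> EnvironmentParams:
    """Validate a configuration mapping into an immutable parameter record.

    The seed is stored on the record but only affects trajectories drawn from
    it, never the parameters themselves.
    """
    cfg = dict(config or {})
    cfg["seed"] = int(seed)
    valid = {f.name for f in dataclasses.fields(EnvironmentParams)}
    unknown = set(cfg) - valid
    if unknown:
        raise ConfigurationError(f"unknown environment parameter(s): {sorted(unknown)}")
    return EnvironmentParams(**cfg)


def toy_environment(seed: int = 0) -> EnvironmentParams:
    """The shipped 1-field, short-horizon, noiseless toy environment.

    Small enough for grid-search oracles and minute-scale policy training,
    while keeping the full transition/outcome structure of the default
    environment.
    """
    return make_environment(
        {"n_fields": 1, "horizon": 8, "noise_scale": 0.0, "budget": 4000.0},
        seed=seed)


@dataclass
class FieldState:
    """State of one field at one time step."""

    field_id: int
    time: int
    crop: np.ndarray          # d, length 3, each in [0,1]
    environment: np.ndarray   # e = (temp degC, humidity, precip mm)
    resources: np.ndarray     # r, cumulative (water L/ha, fert kg/ha, pesticide)
    history: np.ndarray       # h = (last yield accrual, last water, last fert)
    soil_moisture: float      # latent driver in [0,1]

    def copy(self) -> "FieldState":
        return FieldState(self.field_id, self.time, self.crop.copy(),
                          self.environment.copy(), self.resources.copy(),
                          self.history.copy(), float(self.soil_moisture))


@dataclass(frozen=True)
class Outcome:
    """Realized or predicted (yield accrual, cost, environmental impact)."""

    yield_: float   # kg/ha
    cost: float     # currency/ha
    env_impact: float  # dimensionless >= 0

    def as_array(self) -> np.ndarray:
        return np.array([self.yield_, self.cost, self.env_impact])


@dataclass(frozen=True)
class ObjectiveWeights:
    """Weights (a1, a2, a3) trading off yield, cost and environmental impact."""

    alpha1: float = 1.0
    alpha2: float = 1.0
    alpha3: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.alpha2, self.alpha3) < 0:
            raise ConfigurationError("objective weights must be non-negative")
        if self.alpha1 == self.alpha2 == self.alpha3 == 0:
            raise ConfigurationError("at least one objective weight must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.alpha3])


@dataclass
class ControlPlan:
    """Decision variables over fields x horizon x resource kinds, plus constraints."""

    actions: np.ndarray              # (m, T, n_u), >= 0
    budget: float
    env_cap: float
    dose_lower: np.ndarray           # (n_u,)
    dose_upper: np.ndarray           # (n_u,)

    @classmethod
    def zeros(cls, env: EnvironmentParams) -> "ControlPlan":
        return cls(
            actions=np.zeros((env.n_fields, env.horizon, env.n_actions)),
            budget=env.budget,
            env_cap=env.env_cap,
            dose_lower=np.asarray(env.dose_lower, dtype=float),
            dose_upper=np.asarray(env.dose_upper, dtype=float),
        )

    def copy(self) -> "ControlPlan":
        return ControlPlan(self.actions.copy(), self.budget, self.env_cap,
                           self.dose_lower.copy(), self.dose_upper.copy())


@dataclass(frozen=True)
class ObservationBundle:
    """Multi-modal model input for one (field, step)."""

    grid_stack: np.ndarray   # (H, W, C)
    sensor: np.ndarray       # point readings with additive noise
    weather: np.ndarray      # forecast = true e + declared error


# ---------------------------------------------------------------------------
# state construction
# ---------------------------------------------------------------------------

def baseline_state(env: EnvironmentParams, field_id: int = 0) -> FieldState:
    """The canonical healthy starting state used throughout tests and examples."""
    return FieldState(
        field_id=field_id,
        time=0,
        crop=np.array([0.1, 1.0, 0.7]),
        environment=np.array([env.temp_mean, env.humidity_mean, env.precip_mean]),
        resources=np.zeros(3),
        history=np.zeros(3),
        soil_moisture=0.5,
    )


def initial_states(env: EnvironmentParams, rng: np.random.Generator) -> list[FieldState]:
    """Per-field initial states with mild seeded variation around the baseline."""
    states = []
    for i in range(env.n_fields):
        s = baseline_state(env, field_id=i)
        s.soil_moisture = float(np.clip(0.5 + 0.1 * rng.standard_normal(), 0.05, 0.95))
        s.crop[HEALTH] = float(np.clip(1.0 - 0.1 * abs(rng.standard_normal()), 0.0, 1.0))
        states.append(s)
    return states


# ---------------------------------------------------------------------------
# transition, outcome, reward, objective
# ---------------------------------------------------------------------------

def _seasonal_precip(env: EnvironmentParams, t: int) -> float:
    return env.precip_mean * (1.0 + 0.5 * np.sin(2.0 * np.pi * t / env.horizon))


def _dose_gain(env: EnvironmentParams, action: np.ndarray) -> np.ndarray:
    """Per-resource saturating concave gain in [0, 1]; exactly flat above saturation."""
    sat = np.asarray(env.saturation_dose)
    frac = np.minimum(np.asarray(action, dtype=float), sat) / sat
    return 1.0 - (1.0 - frac) ** env.response_exponent


def _validate_action(env: EnvironmentParams, action: np.ndarray) -> np.ndarray:
    action = np.asarray(action, dtype=float)
    if action.shape != (env.n_actions,):
        raise ValueError(f"action must have shape ({env.n_actions},), got {action.shape}")
    if not np.all(np.isfinite(action)):
        raise ValueError("action must be finite")
    if np.any(action < 0):
        raise ValueError("action components must be non-negative")
    return action


def step(env: EnvironmentParams, state: FieldState, action: np.ndarray,
         rng: np.random.Generator | None = None) -> FieldState:
    """One application of ``S' = Phi(S, u) + eps`` for a single field.

    With ``env.noise_scale == 0`` the map is deterministic; otherwise ``eps``
    is zero-mean Gaussian with the configured per-component scales, and the
    bounded components are clipped after the noise is added.
    """
    action = _validate_action(env, action)
    if state.time >= env.horizon:
        raise ValueError(f"horizon exceeded: state at t={state.time}, T={env.horizon}")
    if rng is None:
        rng = np.random.default_rng(env.seed)

    ns = env.noise_scale
    noise = (lambda s: s * ns * rng.standard_normal()) if ns > 0 else (lambda s: 0.0)

    temp, humid, precip = state.environment

    # latent soil moisture: decay + irrigation inflow + rainfall
    moist = ((1.0 - env.moisture_decay) * state.soil_moisture
             + env.irrigation_efficiency * action[WATER]
             + env.rain_efficiency * precip)
    moist = float(np.clip(moist + noise(env.moisture_noise), 0.0, 1.0))

    # crop health relaxes toward the moisture-optimum target
    target = np.exp(-((state.soil_moisture - env.moisture_optimum)
                      / env.moisture_width) ** 2)
    health = state.crop[HEALTH] + env.health_rate * (target - state.crop[HEALTH])
    health = float(np.clip(health + noise(env.health_noise), 0.0, 1.0))

    growth = state.crop[GROWTH] + env.growth_rate * state.crop[HEALTH] * (
        1.0 - state.crop[GROWTH])
    growth = float(np.clip(growth, 0.0, 1.0))
    phenotype = float(np.clip(0.9 * state.crop[PHENOTYPE] + 0.1 * state.crop[HEALTH],
                              0.0, 1.0))

    # weather AR(1) around (seasonal) means
    new_temp = (env.temp_mean + env.temp_autocorr * (temp - env.temp_mean)
                + noise(env.temp_noise))
    new_humid = float(np.clip(
        env.humidity_mean + env.humidity_autocorr * (humid - env.humidity_mean)
        + noise(env.humidity_noise), 0.0, 1.0))
    new_precip = max(0.0, _seasonal_precip(env, state.time + 1)
                     + noise(env.precip_noise))

    out = outcome(env, state, action)
    resources = state.resources + np.array([action[WATER], action[FERT], 0.0])
    history = np.array([out.yield_, action[WATER], action[FERT]])

    return FieldState(
        field_id=state.field_id,
        time=state.time + 1,
        crop=np.array([growth, health, phenotype]),
        environment=np.array([new_temp, new_humid, new_precip]),
        resources=resources,
        history=history,
        soil_moisture=moist,
    )


def outcome(env: EnvironmentParams, state: FieldState, action: np.ndarray) -> Outcome:
    """Noiseless (Y, C, E) response to applying ``action`` in ``state``.

    Y is a saturating concave function of each dose (flat at and above the
    saturation point) scaled by crop health; C is linear in the dose; E is a
    convex penalty on dose in excess of the saturation point.
    """
    action = _validate_action(env, action)
    gain = _dose_gain(env, action)
    y = env.baseline_yield * state.crop[HEALTH] * (
        1.0 + float(np.dot(env.yield_gain, gain)))
    c = float(np.dot(env.unit_price, action))
    over = np.maximum(0.0, action - np.asarray(env.saturation_dose))
    e = float(np.dot(env.env_penalty, over ** 2))
    return Outcome(yield_=y, cost=c, env_impact=e)


def reward(out: Outcome, weights: ObjectiveWeights) -> float:
    """Per-step scalar reward  a1*Y - a2*C - a3*E."""
    return (weights.alpha1 * out.yield_ - weights.alpha2 * out.cost
            - weights.alpha3 * out.env_impact)


def objective(trajectory: Sequence[Sequence[Outcome]],
              weights: ObjectiveWeights) -> float:
    """Season objective J = sum_i sum_t [a1*Y - a2*C - a3*E].

    ``trajectory`` is an (m, T) nested sequence of :class:`Outcome`; equal by
    construction to the sum of per-step rewards.
    """
    lengths = {len(row) for row in trajectory}
    if len(lengths) > 1:
        raise ValueError(f"ragged trajectory: row lengths {sorted(lengths)}")
    return float(sum(reward(out, weights) for row in trajectory for out in row))


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstraintEntry:
    satisfied: bool
    worst_margin: float              # >= 0 when satisfied; most negative slack otherwise
    violations: tuple[tuple[int, int], ...]  # violating (field, step) indices


@dataclass(frozen=True)
class ConstraintReport:
    budget: ConstraintEntry
    agronomic: ConstraintEntry
    environmental: ConstraintEntry

    @property
    def feasible(self) -> bool:
        return (self.budget.satisfied and self.agronomic.satisfied
                and self.environmental.satisfied)


def check_constraints(plan: ControlPlan,
                      env_impacts: np.ndarray | None = None) -> ConstraintReport:
    """Check budget, agronomic dose bounds and the environmental cap.

    ``env_impacts`` is the (m, T) array of realized per-step E values; when
    omitted, the environmental entry is vacuously satisfied.  Violations are
    reported, never raised.
    """
    u = np.asarray(plan.actions, dtype=float)
    m, T, _ = u.shape

    total = float(u.sum())
    budget_margin = plan.budget - total
    budget_entry = ConstraintEntry(budget_margin >= -1e-12, budget_margin, ())

    lo, hi = plan.dose_lower, plan.dose_upper
    slack = np.minimum(u - lo, hi - u).min(axis=-1)  # (m, T)
    bad = np.argwhere(slack < -1e-12)
    agro_entry = ConstraintEntry(
        bad.size == 0, float(slack.min()),
        tuple((int(i), int(t)) for i, t in bad))

    if env_impacts is None:
        env_entry = ConstraintEntry(True, np.inf, ())
    else:
        e = np.asarray(env_impacts, dtype=float)
        margin = plan.env_cap - e
        bad_e = np.argwhere(margin < -1e-12)
        env_entry = ConstraintEntry(
            bad_e.size == 0, float(margin.min()),
            tuple((int(i), int(t)) for i, t in bad_e))

    return ConstraintReport(budget=budget_entry, agronomic=agro_entry,
                            environmental=env_entry)


# ---------------------------------------------------------------------------
# observation rendering
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Low-frequency zero-mean random field on an h x w grid (std ~ 1)."""
    coarse = rng.standard_normal((3, 3))
    return ndimage.zoom(coarse, (h / 3, w / 3), order=1, mode="nearest")


def render_observations(env: EnvironmentParams, state: FieldState,
                        rng: np.random.Generator | None = None) -> ObservationBundle:
    """Synthesize the multi-channel grid, sensor vector and weather forecast.

    Channels (vegetation index, soil moisture, precipitation, temperature,
    past resource use) are each the latent scalar driver modulated by a
    smooth spatial field whose amplitude scales with the noise level, plus
    per-cell observation noise; with ``noise_scale = 0`` every channel is
    exactly constant at its driver value.
    """
    if rng is None:
        rng = np.random.default_rng(env.seed)
    h, w = env.grid_h, env.grid_w
    ns = env.noise_scale

    temp, _, precip = state.environment
    drivers = np.array([
        state.crop[GROWTH] * state.crop[HEALTH],                      # vegetation index
        state.soil_moisture,                                          # soil moisture
        np.clip(precip / (2.0 * env.precip_mean + 1e-9), 0.0, 1.0),   # precipitation
        np.clip((temp - 10.0) / 25.0, 0.0, 1.0),                      # temperature
        np.clip(state.resources[WATER]
                / (env.horizon * env.saturation_dose[WATER] + 1e-9), 0.0, 1.0),
    ])[: env.n_channels]

    grid = np.empty((h, w, len(drivers)))
    for c, base in enumerate(drivers):
        layer = base * np.ones((h, w))
        if ns > 0:
            layer = base * (1.0 + env.spatial_amplitude * ns * _smooth_field(rng, h, w))
            layer = layer + env.obs_noise * ns * rng.standard_normal((h, w))
        grid[:, :, c] = np.clip(layer, 0.0, 1.0)

    # point sensors: vegetation and moisture channels at three fixed positions,
    # plus cumulative water/fertilizer application readings (flow-meter logs)
    pos = [(h // 4, w // 4), (h // 2, w // 2), (3 * h // 4, 3 * w // 4)]
    sat = np.asarray(env.saturation_dose)
    sensor = np.concatenate([
        [grid[i, j, c] for c in (0, 1) for (i, j) in pos],
        state.resources[:2] / (env.horizon * sat),
    ])
    if ns > 0:
        sensor = sensor + env.sensor_noise * ns * rng.standard_normal(sensor.shape)

    weather = state.environment.astype(float).copy()
    if ns > 0:
        weather = weather + np.asarray(env.forecast_noise) * ns * rng.standard_normal(3)

    return ObservationBundle(grid_stack=grid, sensor=sensor, weather=weather)


# ---------------------------------------------------------------------------
# rollouts
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Full record of one simulated season."""

    states: list[list[FieldState]]       # (T+1) x m
    actions: np.ndarray                  # (m, T, n_u)
    outcomes: list[list[Outcome]]        # m x T
    observations: list[list[ObservationBundle]] | None = None  # m x T

    def outcome_array(self) -> np.ndarray:
        """(m, T, 3) array of (Y, C, E)."""
        return np.array([[o.as_array() for o in row] for row in self.outcomes])


def rollout(env: EnvironmentParams,
            plan_or_policy: ControlPlan | Callable[[FieldState], np.ndarray],
            rng: np.random.Generator | None = None,
            init: Sequence[FieldState] | None = None,
            with_observations: bool = False) -> Trajectory:
    """Simulate one season for all fields under a fixed plan or a state policy.

    ``plan_or_policy`` is either a :class:`ControlPlan` (open loop) or a
    callable ``state -> action`` (closed loop).  Observations, when requested,
    are rendered from the pre-decision state at each step.
    """
    if rng is None:
        rng = np.random.default_rng(env.seed)
    states = initial_states(env, rng) if init is None else [s.copy() for s in init]

    m, T = env.n_fields, env.horizon
    actions = np.zeros((m, T, env.n_actions))
    outcomes: list[list[Outcome]] = [[] for _ in range(m)]
    observations: list[list[ObservationBundle]] | None = (
        [[] for _ in range(m)] if with_observations else None)
    all_states: list[list[FieldState]] = [[s.copy() for s in states]]

    for t in range(T):
        next_states = []
        for i, s in enumerate(states):
            if observations is not None:
                observations[i].append(render_observations(env, s, rng))
            if isinstance(plan_or_policy, ControlPlan):
                a = plan_or_policy.actions[i, t]
            else:
                a = np.asarray(plan_or_policy(s), dtype=float)
            actions[i, t] = a
            outcomes[i].append(outcome(env, s, a))
            next_states.append(step(env, s, a, rng))
        states = next_states
        all_states.append([s.copy() for s in states])

    return Trajectory(states=all_states, actions=actions, outcomes=outcomes,
                      observations=observations)


def state_features(state: FieldState, env: EnvironmentParams,
                   prev_action: np.ndarray | None = None) -> np.ndarray:
    """Flat, roughly unit-scaled feature vector (s_t includes u_{t-1})."""
    if prev_action is None:
        prev_action = np.zeros(env.n_actions)
    sat = np.asarray(env.saturation_dose)
    return np.concatenate([
        state.crop,
        [(state.environment[TEMP] - env.temp_mean) / 10.0,
         state.environment[HUMIDITY],
         state.environment[PRECIP] / (2 * env.precip_mean + 1e-9)],
        state.resources[:2] / (env.horizon * sat),
        state.history / np.array([env.baseline_yield * 2, sat[WATER], sat[FERT]]),
        [state.soil_moisture, state.time / env.horizon],
        np.asarray(prev_action) / sat,
    ])
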