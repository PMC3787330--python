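"""Stochastic agent-based interpreter for statechart models.

Discrete-time scheme: every step each agent samples, independently per
region, at most one enabled transition by competing-risks (first event wins
among the enabled exponential rates over dt).  Division resolves after the
region transitions; an agent cannot divide and differentiate in the same
step (if both fire, the flow wins and the division is dropped — an O(dt^2)
event).  Agents are visited in a freshly shuffled order each step; all
randomness comes from one seeded generator per world.

Two execution paths share the same per-flat-state transition tables:

* the agent path (:func:`step_world` / :func:`run_abm`) keeps Agent objects
  and a complete event log;
* the counts path (:func:`run_abm_counts`) exploits that non-spatial agents
  in the same flat state are exchangeable, so per-state counts evolve by
  multinomial draws over the joint per-step outcome distribution — exactly
  the same law, orders of magnitude faster.  It backs the mean-field
  comparison harness.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import SimulationError
from .ode import GANC_CHANNEL, compile_population_ode, integrate
from .statechart import (
    FlatState,
    StateChartModel,
    Transition,
    advance_assignment,
    flatten_product_states,
)


def rate_to_prob(rate: float, dt: float) -> float:
    """Probability 1 - e^(-rate*dt) that an exponential clock fires in dt."""
    if rate < 0:
        raise SimulationError(f"negative rate {rate}")
    if dt <= 0:
        raise SimulationError(f"dt must be > 0, got {dt}")
    return -math.expm1(-rate * dt)


# ---------------------------------------------------------------------------
# Per-flat-state transition tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Enabled:
    transition: Transition
    region: str
    rate: float


class StepTables:
    """Everything the scheduler needs, resolved per flat state."""

    def __init__(self, model: StateChartModel):
        self.model = model
        self.flats = flatten_product_states(model)
        self.index = {f.assignment: f.index for f in self.flats}
        self.by_mapping = {tuple(sorted(f.mapping.items())): f.index for f in self.flats}
        self.options: list[list[list[_Enabled]]] = []  # [k][region] -> enabled
        self.source_rates = np.zeros(len(self.flats))
        self.channels: list[str] = []
        for f in self.flats:
            assignment = f.mapping
            i_gen = model.generation_index(assignment)
            per_region = []
            for region in model.regions:
                enabled = []
                for t in region.transitions:
                    if t.source != assignment[region.name]:
                        continue
                    if t.guard is not None and not t.guard.test(assignment):
                        continue
                    rate = t.rate.value(model.parameters, i_gen)
                    if rate > 0:
                        enabled.append(_Enabled(t, region.name, rate))
                    if t.kind in ("death", "export"):
                        self._channel(t.default_channel())
                per_region.append(enabled)
            self.options.append(per_region)
            for src in model.sources:
                if src.into.test(assignment):
                    self.source_rates[f.index] += src.rate.value(model.parameters, i_gen)
        self._channel(GANC_CHANNEL)

    def _channel(self, name: str) -> int:
        if name not in self.channels:
            self.channels.append(name)
        return self.channels.index(name)

    def flat_index(self, assignment: dict[str, str]) -> int:
        key = tuple(sorted(assignment.items()))
        if key not in self.by_mapping:
            raise SimulationError(f"assignment {assignment} is excluded or unknown")
        return self.by_mapping[key]

    def total_rate(self, k: int) -> float:
        return sum(e.rate for per in self.options[k] for e in per)

    # -- daughter routing --------------------------------------------------
    def daughter_index(self, k: int, t: Transition, region_name: str) -> int:
        d = dict(self.flats[k].mapping)
        d[region_name] = t.target
        d.update(t.reset)
        if t.advance is not None:
            d = advance_assignment(self.model, d, t.advance)
        return self.flat_index(d)

    def flow_target_index(self, k: int, fired: list[_Enabled]) -> int:
        d = dict(self.flats[k].mapping)
        for e in fired:
            d[e.region] = e.transition.target
        for e in fired:
            d.update(e.transition.reset)
        return self.flat_index(d)

    # -- joint outcome distribution (counts path) --------------------------
    def joint_outcomes(self, dt: float):
        """Per flat state: (probs, results). A result is one of
        ('stay', k'), ('divide', daughter_k), ('remove', channel_idx)."""
        out = []
        for k, per_region in enumerate(self.options):
            menus = []
            for enabled in per_region:
                total = sum(e.rate for e in enabled)
                entries = [(math.exp(-total * dt) if total > 0 else 1.0, None)]
                if total > 0:
                    p_fire = rate_to_prob(total, dt)
                    for e in enabled:
                        entries.append((p_fire * e.rate / total, e))
                menus.append(entries)
            merged: dict[tuple, float] = {}
            for combo in itertools.product(*menus):
                prob = 1.0
                fired = []
                for p, e in combo:
                    prob *= p
                    if e is not None:
                        fired.append(e)
                if prob <= 0.0:
                    continue
                merged_key = self._resolve(k, fired)
                merged[merged_key] = merged.get(merged_key, 0.0) + prob
            results = list(merged.keys())
            probs = np.array([merged[r] for r in results])
            probs = probs / probs.sum()
            out.append((probs, results))
        return out

    def _resolve(self, k: int, fired: list[_Enabled]) -> tuple:
        deaths = [e for e in fired if e.transition.kind == "death"]
        exports = [e for e in fired if e.transition.kind == "export"]
        if deaths:
            return ("remove", self._channel(deaths[0].transition.default_channel()))
        if exports:
            return ("remove", self._channel(exports[0].transition.default_channel()))
        flows = [e for e in fired if e.transition.kind == "flow"]
        divisions = [e for e in fired if e.transition.kind == "division"]
        if divisions and not flows:
            e = divisions[0]
            return ("divide", self.daughter_index(k, e.transition, e.region))
        return ("stay", self.flow_target_index(k, flows))


# ---------------------------------------------------------------------------
# Agents and worlds
# ---------------------------------------------------------------------------


@dataclass
class Agent:
    id: int
    states: dict[str, str]
    generation: int = 1
    age: float = 0.0
    position: tuple[int, int] | None = None


@dataclass
class World:
    model: StateChartModel
    rng: np.random.Generator
    gamma: float | object = 1.0  # scalar or callable of t
    clock: float = 0.0
    agents: dict[int, Agent] = field(default_factory=dict)
    log: list[tuple] = field(default_factory=list)  # (t, agent id, event, detail)
    next_id: int = 0
    tables: StepTables | None = None

    def _tables(self) -> StepTables:
        if self.tables is None:
            self.tables = StepTables(self.model)
        return self.tables

    def gamma_at(self, t: float) -> float:
        return self.gamma(t) if callable(self.gamma) else float(self.gamma)

    def spawn(self, flat: FlatState, event: str = "source") -> Agent:
        a = Agent(self.next_id, dict(flat.mapping))
        gi = self.model.generation_index(a.states)
        a.generation = gi if gi is not None else 1
        self.next_id += 1
        self.agents[a.id] = a
        self.log.append((self.clock, a.id, event, flat.name))
        return a

    def counts_vector(self) -> np.ndarray:
        tables = self._tables()
        counts = np.zeros(len(tables.flats), dtype=np.int64)
        for a in self.agents.values():
            counts[tables.flat_index(a.states)] += 1
        return counts


def make_world(model: StateChartModel, init_counts, seed: int,
               gamma: float | object | None = None) -> World:
    """Seeded world with `init_counts` agents (dict flat-name -> n, or vector)."""
    world = World(model, np.random.default_rng(seed),
                  gamma=model.gamma if gamma is None else gamma)
    tables = world._tables()
    if isinstance(init_counts, dict):
        vec = np.zeros(len(tables.flats), dtype=np.int64)
        names = {f.name: f.index for f in tables.flats}
        for name, cnt in init_counts.items():
            if name not in names:
                raise SimulationError(f"unknown flat state {name!r}")
            vec[names[name]] = int(cnt)
    else:
        vec = np.asarray(init_counts, dtype=np.int64)
    for k, cnt in enumerate(vec):
        for _ in range(int(cnt)):
            world.spawn(tables.flats[k], event="init")
    return world


def divide_agent(world: World, agent: Agent, gamma: float,
                 transition: Transition | None = None) -> list[Agent]:
    """Resolve a division event for one agent.

    gamma=1: two daughters in the division target state (generation advanced,
    saturating); parent removed.  gamma=0: no daughters, parent removed and
    logged as ganciclovir apoptosis.
    """
    tables = world._tables()
    k = tables.flat_index(agent.states)
    if transition is None:
        cands = [e for per in tables.options[k] for e in per
                 if e.transition.kind == "division"]
        if not cands:
            raise SimulationError(
                f"agent {agent.id} is not in a division-enabled state ({agent.states})")
        enabled = cands[0]
        transition, region_name = enabled.transition, enabled.region
    else:
        region_name = next(r.name for r in world.model.regions
                           if transition in r.transitions)
        if agent.states[region_name] != transition.source:
            raise SimulationError(
                f"agent {agent.id} is not in the dividing state {transition.source!r}")
    del world.agents[agent.id]
    if gamma == 0:
        world.log.append((world.clock, agent.id, GANC_CHANNEL, None))
        return []
    dk = tables.daughter_index(k, transition, region_name)
    daughters = [world.spawn(tables.flats[dk], event="birth") for _ in range(2)]
    world.log.append((world.clock, agent.id, "divide", [d.id for d in daughters]))
    return daughters


def step_world(world: World, model: StateChartModel, dt: float,
               warn_dt: bool = False) -> World:
    """Advance the world by one step of length dt (see module docstring)."""
    tables = world._tables()
    rng = world.rng
    gamma = world.gamma_at(world.clock)

    if warn_dt:
        worst = max((tables.total_rate(k) for k in range(len(tables.flats))), default=0.0)
        if worst * dt >= 0.5:
            import warnings

            warnings.warn(f"dt too coarse: max total rate*dt = {worst * dt:.3f} >= 0.5")

    order = list(world.agents.keys())
    rng.shuffle(order)
    for aid in order:
        agent = world.agents.get(aid)
        if agent is None:
            continue
        k = tables.flat_index(agent.states)
        fired: list[_Enabled] = []
        for enabled in tables.options[k]:
            total = sum(e.rate for e in enabled)
            if total <= 0:
                continue
            if rng.random() < rate_to_prob(total, dt):
                u = rng.random() * total
                acc = 0.0
                for e in enabled:
                    acc += e.rate
                    if u < acc:
                        fired.append(e)
                        break
        if not fired:
            agent.age += dt
            continue
        deaths = [e for e in fired if e.transition.kind == "death"]
        exports = [e for e in fired if e.transition.kind == "export"]
        if deaths:
            del world.agents[aid]
            world.log.append((world.clock, aid, "death", deaths[0].transition.default_channel()))
            continue
        if exports:
            del world.agents[aid]
            world.log.append((world.clock, aid, "export", exports[0].transition.default_channel()))
            continue
        flows = [e for e in fired if e.transition.kind == "flow"]
        divisions = [e for e in fired if e.transition.kind == "division"]
        if divisions and not flows:
            divide_agent(world, agent, gamma, divisions[0].transition)
            continue
        new_k = tables.flow_target_index(k, flows)
        agent.states = dict(tables.flats[new_k].mapping)
        gi = model.generation_index(agent.states)
        agent.generation = gi if gi is not None else agent.generation
        agent.age += dt

    # influx
    for k, rate in enumerate(tables.source_rates):
        if rate > 0:
            for _ in range(rng.poisson(rate * dt)):
                world.spawn(tables.flats[k])
    world.clock += dt
    return world


@dataclass
class ABMResult:
    times: np.ndarray
    counts: np.ndarray  # (T, K) integer counts
    state_names: list[str]
    channel_names: list[str]
    channels: np.ndarray  # (T, m) cumulative removals per channel
    log: list[tuple] = field(default_factory=list)

    def conservation(self, initial: int) -> tuple[int, int, int]:
        """(births, deaths, exports) counted from the event log."""
        births = deaths = exports = 0
        for (_, _, event, detail) in self.log:
            if event in ("source", "birth"):
                births += 1
            elif event == "divide":
                deaths += 1  # the parent
            elif event in ("death", GANC_CHANNEL):
                deaths += 1
            elif event == "export":
                exports += 1
        return births, deaths, exports


def run_abm(model: StateChartModel, init_counts, t_end: float, dt: float,
            seed: int, gamma=None) -> ABMResult:
    """Agent-object simulation with a complete event log.

    Bit-for-bit reproducible for a fixed seed.
    """
    world = make_world(model, init_counts, seed, gamma)
    tables = world._tables()
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    counts = np.zeros((n_steps + 1, len(tables.flats)), dtype=np.int64)
    channels = np.zeros((n_steps + 1, len(tables.channels)), dtype=np.int64)
    counts[0] = world.counts_vector()
    chan_idx = {c: j for j, c in enumerate(tables.channels)}
    log_pos = len(world.log)
    for step in range(1, n_steps + 1):
        step_world(world, model, dt)
        counts[step] = world.counts_vector()
        channels[step] = channels[step - 1]
        for (_, _, event, detail) in world.log[log_pos:]:
            if event in ("death", "export"):
                channels[step, chan_idx[detail]] += 1
            elif event == GANC_CHANNEL:
                channels[step, chan_idx[GANC_CHANNEL]] += 1
        log_pos = len(world.log)
    return ABMResult(times, counts, [f.name for f in tables.flats],
                     list(tables.channels), channels, world.log)


def run_abm_counts(model: StateChartModel, init_counts, t_end: float, dt: float,
                   seed: int, gamma=None) -> ABMResult:
    """Counts-path simulation: identical law to run_abm for non-spatial
    models (agents are exchangeable), no per-agent log."""
    tables = StepTables(model)
    rng = np.random.default_rng(seed)
    if isinstance(init_counts, dict):
        vec = np.zeros(len(tables.flats), dtype=np.int64)
        names = {f.name: f.index for f in tables.flats}
        for name, cnt in init_counts.items():
            vec[names[name]] = int(cnt)
    else:
        vec = np.array(init_counts, dtype=np.int64).copy()
    gamma = model.gamma if gamma is None else gamma

    outcomes = tables.joint_outcomes(dt)
    n_steps = int(round(t_end / dt))
    K = len(tables.flats)
    times = np.arange(n_steps + 1) * dt
    counts = np.zeros((n_steps + 1, K), dtype=np.int64)
    channels = np.zeros((n_steps + 1, len(tables.channels)), dtype=np.int64)
    counts[0] = vec
    ganc_idx = tables.channels.index(GANC_CHANNEL)
    cur = vec.copy()
    for step in range(1, n_steps + 1):
        t = times[step - 1]
        g = gamma(t) if callable(gamma) else float(gamma)
        new = np.zeros(K, dtype=np.int64)
        chan = channels[step - 1].copy()
        for k in np.nonzero(cur)[0]:
            probs, results = outcomes[k]
            if len(results) == 1 and results[0] == ("stay", k):
                new[k] += cur[k]
                continue
            draws = rng.multinomial(cur[k], probs)
            for n_r, res in zip(draws, results):
                if n_r == 0:
                    continue
                kind = res[0]
                if kind == "stay":
                    new[res[1]] += n_r
                elif kind == "divide":
                    if g >= 0.5:
                        new[res[1]] += 2 * n_r
                    else:
                        chan[ganc_idx] += n_r
                else:  # remove
                    chan[res[1]] += n_r
        for k in np.nonzero(tables.source_rates)[0]:
            new[k] += rng.poisson(tables.source_rates[k] * dt)
        cur = new
        counts[step] = cur
        channels[step] = chan
    return ABMResult(times, counts, [f.name for f in tables.flats],
                     list(tables.channels), channels, log=[])


# ---------------------------------------------------------------------------
# Mean-field comparison
# ---------------------------------------------------------------------------


@dataclass
class MeanFieldReport:
    times: np.ndarray
    state_names: list[str]
    abm_mean: np.ndarray   # (T, K)
    abm_std: np.ndarray
    ode: np.ndarray        # (T, K)
    z: np.ndarray          # (T, K)
    flagged: list[str]     # states with any |z| > 4
    n_agents: int
    replicates: int

    @property
    def max_abs_z(self) -> float:
        return float(np.max(np.abs(self.z)))


def compare_mean_field(model: StateChartModel, n_agents: int, replicates: int,
                       t_grid: np.ndarray, seed: int, dt: float = 0.01,
                       init_counts=None, z_flag: float = 4.0) -> MeanFieldReport:
    """Run the ABM `replicates` times and compare per-state means with the
    compiled population ODE; flag states where any |z| exceeds `z_flag`.

    Replicate r uses seed + r.  Grid times are snapped to multiples of dt.
    """
    if not isinstance(model, StateChartModel):
        raise SimulationError("not comparable: model has no mean-field reduction")
    system = compile_population_ode(model)
    tables = StepTables(model)
    K = len(tables.flats)
    if init_counts is None:
        initial = {r.name: r.initial for r in model.regions}
        vec = np.zeros(K, dtype=np.int64)
        vec[tables.flat_index(initial)] = n_agents
    elif isinstance(init_counts, dict):
        vec = np.zeros(K, dtype=np.int64)
        names = {f.name: f.index for f in tables.flats}
        for name, cnt in init_counts.items():
            vec[names[name]] = int(cnt)
    else:
        vec = np.asarray(init_counts, dtype=np.int64)

    t_grid = np.asarray(t_grid, dtype=float)
    steps = np.unique(np.round(t_grid / dt).astype(int))
    steps = steps[steps >= 0]
    t_snap = steps * dt
    t_end = float(t_snap[-1])

    runs = np.zeros((replicates, len(steps), K))
    for r in range(replicates):
        res = run_abm_counts(model, vec, t_end, dt, seed + r)
        runs[r] = res.counts[steps]

    ode_grid = t_snap if t_snap[0] == 0.0 else np.concatenate([[0.0], t_snap])
    traj = integrate(system, vec.astype(float), ode_grid)
    ode_vals = traj.values[-len(steps):] if t_snap[0] != 0.0 else traj.values

    mean = runs.mean(axis=0)
    std = runs.std(axis=0, ddof=1) if replicates > 1 else np.zeros_like(mean)
    # floor the variance at the Poisson scale (var ~ mean for these counts)
    # so rare states with zero sample variance do not produce spurious flags
    var = np.maximum(std**2, np.maximum(ode_vals, 0.0))
    se = np.sqrt(var / replicates)
    diff = mean - ode_vals
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(np.abs(diff) < 1e-9, 0.0, np.inf))
    flagged = [nm for j, nm in enumerate(f.name for f in tables.flats)
               if np.any(np.abs(z[:, j]) > z_flag)]
    return MeanFieldReport(t_snap, [f.name for f in tables.flats], mean, std,
                           ode_vals, z, flagged, int(vec.sum()), replicates)
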