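"""Population (mean-field) backend: compile a statechart into a linear ODE
system on the flat product states, export the equations as text, and
integrate trajectories.

For every flat state i the compiled right-hand side implements

    dx_i/dt = sum(sources into i)
            + sum over division inflows   2*gamma * p * x_parent
            + sum over flow inflows       r * x_src
            - (sum of outgoing rates) * x_i

A division's outflow leaves the dividing compartment at rate p regardless
of gamma; with gamma = 0 the (absent) inflow is accounted as a
"ganciclovir_apoptosis" outflow channel so mass stays balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import CompileError, SimulationError
from .statechart import (
    EXIT,
    FlatState,
    StateChartModel,
    advance_assignment,
    flatten_product_states,
)

GANC_CHANNEL = "ganciclovir_apoptosis"


@dataclass(frozen=True)
class Flux:
    """One elementary mass flux of the compiled system.

    src is None for external sources; dst is None for outflow-only fluxes
    (death/export); division fluxes carry both the outflow from src and the
    2*gamma inflow into dst.
    """

    src: int | None
    dst: int | None
    rate_value: float
    rate_text: str
    kind: str  # 'source' | 'flow' | 'division' | 'death' | 'export'
    channel: str | None = None


@dataclass
class ODESystem:
    model: StateChartModel
    states: list[FlatState]
    fluxes: list[Flux]
    channels: list[str]
    A0: np.ndarray        # flows + every outflow (incl. division outflow)
    Adiv: np.ndarray      # division inflow coefficients, scaled by 2*gamma
    source_vec: np.ndarray
    Cmat: np.ndarray      # channel accrual rates (deaths/exports), (m, n)
    ganc_rates: np.ndarray  # division outflow rates, feeds GANC channel at (1-gamma)

    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def state_names(self) -> list[str]:
        return [f.name for f in self.states]

    def matrix(self, gamma: float) -> np.ndarray:
        return self.A0 + 2.0 * gamma * self.Adiv

    def rhs(self, x: np.ndarray, gamma: float) -> np.ndarray:
        return self.matrix(gamma) @ x + self.source_vec

    def channel_rates(self, x: np.ndarray, gamma: float) -> np.ndarray:
        out = self.Cmat @ x
        gi = self.channels.index(GANC_CHANNEL)
        out[gi] += (1.0 - gamma) * (self.ganc_rates @ x)
        return out

    def steady_state(self, gamma: float | None = None) -> np.ndarray:
        """Algebraic fixed point A x = -s (requires A nonsingular)."""
        g = self.model.gamma if gamma is None else gamma
        return np.linalg.solve(self.matrix(g), -self.source_vec)

    def flat_parameters(self) -> dict[str, float]:
        """Scalar view of the parameter table as used by the equation text."""
        out: dict[str, float] = {"gamma": float(self.model.gamma)}
        for k, v in self.model.parameters.items():
            if isinstance(v, (list, tuple)):
                for j, vj in enumerate(v, start=1):
                    out[f"{k}_{j}"] = float(vj)
            else:
                out[k] = float(v)
        return out


@dataclass
class Trajectory:
    times: np.ndarray                  # (T,)
    values: np.ndarray                 # (T, n) cell counts, >= 0
    state_names: list[str]
    channel_names: list[str] = field(default_factory=list)
    channels: np.ndarray | None = None  # (T, m) cumulative outflow

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.state_names.index(name)]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[:, self.channel_names.index(name)]


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------


def compile_population_ode(model: StateChartModel) -> ODESystem:
    """Compile a valid statechart into the linear population system."""
    flats = flatten_product_states(model)
    index = {f.assignment: f.index for f in flats}

    def flat_index(assignment: dict[str, str]) -> int:
        key = tuple((r.name, assignment[r.name]) for r in model.regions)
        return index[key]

    n = len(flats)
    fluxes: list[Flux] = []
    channels: list[str] = []

    def channel_id(name: str) -> int:
        if name not in channels:
            channels.append(name)
        return channels.index(name)

    has_division = False
    for f in flats:
        assignment = f.mapping
        i_gen = model.generation_index(assignment)
        for region in model.regions:
            cur = assignment[region.name]
            for t in region.transitions:
                if t.source != cur:
                    continue
                if t.guard is not None and not t.guard.test(assignment):
                    continue
                t.rate.check_affine()
                rate = t.rate.value(model.parameters, i_gen)
                text = t.rate.render(i_gen)
                if t.kind in ("death", "export"):
                    channel_id(t.default_channel())
                    fluxes.append(Flux(f.index, None, rate, text, t.kind, t.default_channel()))
                elif t.kind == "flow":
                    target = dict(assignment)
                    target[region.name] = t.target
                    target.update(t.reset)
                    if model.is_excluded(target):
                        raise CompileError(
                            f"flow {region.name}:{t.source}->{t.target} from {f.name} "
                            "targets an excluded flat state"
                        )
                    fluxes.append(Flux(f.index, flat_index(target), rate, text, "flow"))
                else:  # division
                    has_division = True
                    daughter = dict(assignment)
                    daughter[region.name] = t.target
                    daughter.update(t.reset)
                    if t.advance is not None:
                        daughter = advance_assignment(model, daughter, t.advance)
                    if model.is_excluded(daughter):
                        raise CompileError(
                            f"division {region.name}:{t.source}->{t.target} from {f.name} "
                            "routes daughters to an excluded flat state"
                        )
                    fluxes.append(Flux(f.index, flat_index(daughter), rate, text, "division"))
        for src in model.sources:
            if src.into.test(assignment):
                rate = src.rate.value(model.parameters, i_gen)
                fluxes.append(Flux(None, f.index, rate, src.rate.render(i_gen), "source"))

    channel_id(GANC_CHANNEL)  # always present so gamma=0 losses have a home
    del has_division

    A0 = np.zeros((n, n))
    Adiv = np.zeros((n, n))
    source_vec = np.zeros(n)
    Cmat = np.zeros((len(channels), n))
    ganc = np.zeros(n)
    for fl in fluxes:
        if fl.kind == "source":
            source_vec[fl.dst] += fl.rate_value
            continue
        A0[fl.src, fl.src] -= fl.rate_value
        if fl.kind == "flow":
            A0[fl.dst, fl.src] += fl.rate_value
        elif fl.kind == "division":
            Adiv[fl.dst, fl.src] += fl.rate_value
            ganc[fl.src] += fl.rate_value
        else:
            Cmat[channels.index(fl.channel), fl.src] += fl.rate_value
    return ODESystem(model, flats, fluxes, channels, A0, Adiv, source_vec, Cmat, ganc)


# ---------------------------------------------------------------------------
# Equation export
# ---------------------------------------------------------------------------


def export_equations(system: ODESystem, include_parameters: bool = False) -> str:
    """Human-readable equations, one line per flat state.

    Terms use parameter names (never numeric values); table lookups appear
    as flattened names like ``Us4_2`` and the division multiplier as
    ``2*gamma``.  With ``include_parameters`` a commented parameter block is
    prepended.
    """
    n = system.n
    inflows: list[list[str]] = [[] for _ in range(n)]
    outrates: list[list[str]] = [[] for _ in range(n)]
    var = [f.var_name for f in system.states]
    for fl in system.fluxes:
        if fl.kind == "source":
            inflows[fl.dst].append(fl.rate_text)
            continue
        outrates[fl.src].append(fl.rate_text)
        if fl.kind == "flow":
            inflows[fl.dst].append(f"({fl.rate_text})*{var[fl.src]}")
        elif fl.kind == "division":
            inflows[fl.dst].append(f"2*gamma*({fl.rate_text})*{var[fl.src]}")
    lines = []
    if include_parameters:
        for k, v in system.flat_parameters().items():
            lines.append(f"# {k} = {v!r}")
    for i in range(n):
        terms = list(inflows[i])
        if outrates[i]:
            terms.append("- (" + " + ".join(outrates[i]) + f")*{var[i]}")
        rhs = " + ".join(terms) if terms else "0"
        rhs = rhs.replace("+ - ", "- ")
        lines.append(f"d{var[i]}/dt = {rhs}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


class GammaSchedule:
    """Piecewise-constant gamma(t): 0 inside windows, base value outside."""

    def __init__(self, windows: list[tuple[float, float]] | None = None, base: float = 1.0):
        windows = sorted(windows or [])
        for (a, b) in windows:
            if not a < b:
                raise SimulationError(f"bad window ({a}, {b}): need t_on < t_off")
        for (a, b), (c, d) in zip(windows, windows[1:]):
            if c < b:
                raise SimulationError(f"overlapping windows ({a},{b}) and ({c},{d})")
        self.windows = windows
        self.base = base

    def __call__(self, t: float) -> float:
        for a, b in self.windows:
            if a <= t < b:
                return 0.0
        return self.base

    @property
    def breakpoints(self) -> list[float]:
        return sorted({x for w in self.windows for x in w})


def integrate(
    system: ODESystem,
    y0: np.ndarray,
    t_grid: np.ndarray,
    gamma: float | GammaSchedule | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate on a strictly increasing time grid.

    Negative solver values are clipped to zero on output only.  A
    time-dependent gamma is handled by restarting the integrator at each
    breakpoint so discontinuities do not degrade accuracy.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1 or np.any(np.diff(t_grid) <= 0):
        raise SimulationError("t_grid must be strictly increasing")
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (system.n,):
        raise SimulationError(f"y0 must have length {system.n}")

    if len(t_grid) == 1:
        return Trajectory(t_grid, np.clip(y0[None, :], 0.0, None), system.state_names,
                          list(system.channels), np.zeros((1, len(system.channels))))

    if gamma is None:
        gamma = float(system.model.gamma)
    if isinstance(gamma, (int, float)):
        sched = GammaSchedule([], base=float(gamma))
        sched.base = float(gamma)
        segments = [(t_grid[0], t_grid[-1])]
    else:
        sched = gamma
        cuts = [b for b in sched.breakpoints if t_grid[0] < b < t_grid[-1]]
        edges = [t_grid[0], *cuts, t_grid[-1]]
        segments = list(zip(edges, edges[1:]))

    m = len(system.channels)
    gi = system.channels.index(GANC_CHANNEL)

    times_out = [t_grid[0]]
    y_out = [y0.copy()]
    c_out = [np.zeros(m)]
    y_cur = np.concatenate([y0, np.zeros(m)])
    n = system.n

    for (a, b) in segments:
        g = sched((a + b) / 2.0)
        A = system.matrix(g)
        crow = system.Cmat.copy()
        crow[gi] += (1.0 - g) * system.ganc_rates

        def rhs(t, y):
            x = y[:n]
            return np.concatenate([A @ x + system.source_vec, crow @ x])

        def jac(t, y):
            J = np.zeros((n + m, n + m))
            J[:n, :n] = A
            J[n:, :n] = crow
            return J

        interior = t_grid[(t_grid > a) & (t_grid < b)]
        t_eval = np.unique(np.concatenate([[a], interior, [b]]))
        sol = solve_ivp(rhs, (a, b), y_cur, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol, jac=jac)
        if not sol.success:
            t_fail = sol.t[-1] if len(sol.t) else a
            raise SimulationError(f"solver failure: {sol.message}", t=t_fail)
        for k, t in enumerate(sol.t):
            if t <= times_out[-1] + 1e-15:
                continue
            if np.any(np.isclose(t_grid, t, rtol=0.0, atol=1e-12)):
                times_out.append(t)
                y_out.append(sol.y[:n, k])
                c_out.append(sol.y[n:, k])
        y_cur = sol.y[:, -1]

    values = np.clip(np.vstack(y_out), 0.0, None)
    chans = np.clip(np.vstack(c_out), 0.0, None)
    # cumulative channels must be non-decreasing; enforce against round-off
    chans = np.maximum.accumulate(chans, axis=0)
    return Trajectory(
        times=np.asarray(times_out),
        values=values,
        state_names=system.state_names,
        channel_names=list(system.channels),
        channels=chans,
    )


def total_counts(traj: Trajectory, grouping=None) -> np.ndarray:
    """Per-time sums over the flat states matched by ``grouping``.

    ``grouping`` is a predicate on the flat-state name (str -> bool), a list
    of names, or None for all states.
    """
    if grouping is None:
        mask = np.ones(len(traj.state_names), dtype=bool)
    elif callable(grouping):
        mask = np.array([bool(grouping(nm)) for nm in traj.state_names])
    else:
        wanted = set(grouping)
        mask = np.array([nm in wanted for nm in traj.state_names])
    if not mask.any():
        raise SimulationError("grouping matches no state")
    return traj.values[:, mask].sum(axis=1)


def export_flux(traj: Trajectory, system: ODESystem, channel: str) -> np.ndarray:
    """Instantaneous outflow (cells/time) into a named channel."""
    if channel not in system.channels:
        raise SimulationError(f"unknown channel {channel!r}")
    row = np.zeros(system.n)
    contributing = 0
    for fl in system.fluxes:
        if fl.kind in ("death", "export") and fl.channel == channel:
            row[fl.src] += fl.rate_value
            contributing += 1
    if contributing == 0:
        raise SimulationError(f"channel {channel!r} has no contributing states")
    return traj.values @ row
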