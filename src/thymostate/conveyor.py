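"""The conveyor-belt thymocyte differentiation model.

Cells enter as double-negative (DN) progenitors, progress through early and
late double-positive (DP) stages to the single-positive (SP4/SP8) stages,
and egress to the periphery.  Three orthogonal regions describe each cell:

* ``differentiation`` — DN -> DP_early -> DP_late -> {SP4, SP8} -> exit,
* ``cell_cycle``      — quiescence (G0) <-> cycling (SM), division in SM,
* ``generation``      — division generation g1..gmax, advanced by division.

With the default decomposition (DN: 4 generations, DP_early: 6, DP_late: 2
quiescent-only, SP4: 2, SP8: 2, each crossed with {G0, SM}) the flattened
system has exactly 30 states.

The ganciclovir perturbation sets the division-survival switch gamma to 0
inside treatment windows: cells entering division die instead of producing
two daughters.  Late-DP cells are exempt by construction — they have no
cycling states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ModelError, SimulationError
from .ode import GammaSchedule, ODESystem, Trajectory, export_flux
from .statechart import StateChartModel, parse_model

STAGES = ("DN", "DP_early", "DP_late", "SP4", "SP8")


@dataclass
class ConveyorConfig:
    """Generations per stage and the late-DP cycling exemption."""

    n_N: int = 4       # DN generations
    n_P: int = 6       # DP_early generations
    n_L: int = 2       # DP_late generations
    n_4: int = 2       # SP4 generations
    n_8: int = 2       # SP8 generations
    late_DP_quiescent_only: bool = True

    def generations(self, stage: str) -> int:
        return {"DN": self.n_N, "DP_early": self.n_P, "DP_late": self.n_L,
                "SP4": self.n_4, "SP8": self.n_8}[stage]

    @property
    def g_max(self) -> int:
        return max(self.n_N, self.n_P, self.n_L, self.n_4, self.n_8)

    def flat_count(self) -> int:
        total = 2 * (self.n_N + self.n_P + self.n_L + self.n_4 + self.n_8)
        if self.late_DP_quiescent_only:
            total -= self.n_L
        return total

    def validate(self) -> None:
        for stage in STAGES:
            if self.generations(stage) < 1:
                raise ModelError(f"stage {stage} needs >= 1 generation")


@dataclass
class ConveyorParams:
    """Rates of the population model (units: per day; influx cells/day).

    Default values are placeholders chosen for a stable steady state; the
    original fitted values are not shipped.  All are overridable through the
    model file.
    """

    Sn: float = 1e4            # progenitor influx into (DN, g1, G0)
    Pn: float = 0.2            # proliferation DN
    Pp: float = 0.2            # proliferation DP_early
    Ps: float = 0.2            # proliferation SP
    Dn: float = 0.05           # natural death DN
    Dp: float = 0.05           # natural death DP (early and late)
    Ds: float = 0.05           # natural death SP
    a4: float = 0.08           # late DP -> SP4 selection
    a8: float = 0.02           # late DP -> SP8 selection
    Us4: float = 0.5           # SP4 egress (per generation; scalar = constant)
    Us8: float = 0.5           # SP8 egress
    u0_DN: float = 0.05        # differentiation base rate, DN
    u0_DP: float = 0.05        # differentiation base rate, DP_early
    s: float = 0.05            # differentiation slope per generation
    act: float = 0.5           # G0 -> SM cycle entry
    gamma: float = 1.0

    def validate(self) -> None:
        for name in ("Sn", "Pn", "Pp", "Ps", "Dn", "Dp", "Ds", "a4", "a8",
                     "Us4", "Us8", "u0_DN", "u0_DP", "s", "act"):
            if getattr(self, name) < 0:
                raise ModelError(f"rate {name} must be >= 0")
        if self.gamma not in (0.0, 1.0):
            raise ModelError("gamma must be 0 or 1")


@dataclass
class PerturbationSchedule:
    """Disjoint (t_on, t_off) windows with gamma forced to 0."""

    windows: list[tuple[float, float]] = field(default_factory=list)


def differentiation_rate(stage: str, i: int, params: ConveyorParams,
                         config: ConveyorConfig | None = None) -> float:
    """u_i = u0_stage + s*(i-1); non-decreasing in the generation index i."""
    config = config or ConveyorConfig()
    if stage not in ("DN", "DP_early"):
        raise ModelError(f"stage {stage!r} has no generation-dependent differentiation rate")
    n = config.generations(stage)
    if not 1 <= i <= n:
        raise IndexError(f"generation index {i} out of range 1..{n} for stage {stage}")
    u0 = params.u0_DN if stage == "DN" else params.u0_DP
    return u0 + params.s * (i - 1)


def build_conveyor_document(config: ConveyorConfig | None = None,
                            params: ConveyorParams | None = None) -> dict:
    """The model document (dict form of the YAML dialect)."""
    config = config or ConveyorConfig()
    params = params or ConveyorParams()
    config.validate()
    params.validate()
    gens = [f"g{j}" for j in range(1, config.g_max + 1)]

    parameters = {k: getattr(params, k) for k in
                  ("Sn", "Pn", "Pp", "Ps", "Dn", "Dp", "Ds", "a4", "a8",
                   "Us4", "Us8", "u0_DN", "u0_DP", "s", "act")}

    diff_transitions = [
        {"from": "DN", "to": "DP_early", "rate": "u0_DN + s*(i - 1)",
         "kind": "flow", "reset": {"generation": "g1"}},
        # late DP cells are quiescent: cycling cells drop back to G0 on entry
        {"from": "DP_early", "to": "DP_late", "rate": "u0_DP + s*(i - 1)",
         "kind": "flow",
         "reset": ({"generation": "g1", "cell_cycle": "G0"}
                   if config.late_DP_quiescent_only else {"generation": "g1"})},
        {"from": "DP_late", "to": "SP4", "rate": "a4", "kind": "flow",
         "reset": {"generation": "g1"}},
        {"from": "DP_late", "to": "SP8", "rate": "a8", "kind": "flow",
         "reset": {"generation": "g1"}},
        {"from": "DN", "to": "EXIT", "rate": "Dn", "kind": "death"},
        {"from": "DP_early", "to": "EXIT", "rate": "Dp", "kind": "death"},
        {"from": "DP_late", "to": "EXIT", "rate": "Dp", "kind": "death"},
        {"from": "SP4", "to": "EXIT", "rate": "Ds", "kind": "death"},
        {"from": "SP8", "to": "EXIT", "rate": "Ds", "kind": "death"},
        {"from": "SP4", "to": "EXIT", "rate": "Us4", "kind": "export",
         "channel": "export_SP4"},
        {"from": "SP8", "to": "EXIT", "rate": "Us8", "kind": "export",
         "channel": "export_SP8"},
    ]

    cycle_guard_act = "differentiation != DP_late" if config.late_DP_quiescent_only else None
    cycle_transitions = [
        {"from": "G0", "to": "SM", "rate": "act", "kind": "flow",
         **({"guard": cycle_guard_act} if cycle_guard_act else {})},
        {"from": "SM", "to": "G0", "rate": "Pn", "kind": "division",
         "guard": "differentiation == DN", "advance": "generation"},
        {"from": "SM", "to": "G0", "rate": "Pp", "kind": "division",
         "guard": "differentiation == DP_early", "advance": "generation"},
        {"from": "SM", "to": "G0", "rate": "Ps", "kind": "division",
         "guard": "differentiation in [SP4, SP8]", "advance": "generation"},
    ]
    if not config.late_DP_quiescent_only:
        cycle_transitions.append(
            {"from": "SM", "to": "G0", "rate": "Pp", "kind": "division",
             "guard": "differentiation == DP_late", "advance": "generation"})

    exclusions = []
    for stage in STAGES:
        n_stage = config.generations(stage)
        if n_stage < config.g_max:
            extra = ", ".join(gens[n_stage:])
            exclusions.append(f"differentiation == {stage} and generation in [{extra}]")
    if config.late_DP_quiescent_only:
        exclusions.append("differentiation == DP_late and cell_cycle == SM")

    return {
        "name": "conveyor_belt",
        "generation_region": "generation",
        "gamma": params.gamma,
        "parameters": parameters,
        "regions": [
            {"name": "differentiation", "states": list(STAGES), "initial": "DN",
             "transitions": diff_transitions},
            {"name": "cell_cycle", "states": ["G0", "SM"], "initial": "G0",
             "transitions": cycle_transitions},
            {"name": "generation", "states": gens, "initial": "g1",
             "transitions": []},
        ],
        "sources": [
            {"into": "differentiation == DN and cell_cycle == G0 and generation == g1",
             "rate": "Sn"},
        ],
        "exclusions": exclusions,
    }


def build_conveyor_model(config: ConveyorConfig | None = None,
                         params: ConveyorParams | None = None) -> StateChartModel:
    return parse_model(build_conveyor_document(config, params))


def apply_ganciclovir(params: ConveyorParams,
                      schedule: PerturbationSchedule) -> GammaSchedule:
    """Time-dependent gamma(t): 0 inside treatment windows, 1 outside.

    Late-DP cells are structurally exempt (no SM states), so no extra guard
    is needed here.  Raises on overlapping windows.
    """
    return GammaSchedule(list(schedule.windows), base=params.gamma)


def thymic_export_flux(traj: Trajectory, system: ODESystem) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous SP4 and SP8 export to the periphery (cells/time)."""
    if not any(nm.startswith("SP4.") for nm in traj.state_names):
        raise SimulationError("trajectory lacks SP states")
    flux4 = export_flux(traj, system, "export_SP4")
    flux8 = export_flux(traj, system, "export_SP8")
    return flux4, flux8


def stage_totals(traj: Trajectory) -> dict[str, np.ndarray]:
    """Per-stage population totals over time."""
    out = {}
    for stage in STAGES:
        mask = [nm.split(".")[0] == stage for nm in traj.state_names]
        cols = np.array(mask)
        out[stage] = traj.values[:, cols].sum(axis=1)
    return out
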