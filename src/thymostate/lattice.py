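"""Spatial thymus model: a 2-D lattice of thymic tissue with an epithelial
cell network and static chemokine gradients.

Thymocyte agents enter at the subcapsular zone, migrate down chemokine
gradients appropriate to their differentiation stage (DN/DP follow CXCL12
toward the cortex, SP follow CCL19/CCL21 toward the medulla, mature SP
follow S1P toward exit sites), bind transiently to epithelial cells through
TCR/MHC contacts, and accumulate an interaction history that drives
positive selection, death by neglect, negative selection, the CD4-vs-CD8
lineage decision (signal-duration rule), and finally egress.

Geometry: rectangular row-major grid, Moore (8-neighbor) neighborhood,
reflecting boundaries.  Anatomy is banded: subcapsular rows on top, cortex
in the middle, medulla at the bottom with exit sites on the outermost
medullary row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SimulationError
from .abm import rate_to_prob

REGION_SUBCAPSULAR = 0
REGION_CORTEX = 1
REGION_MEDULLA = 2
REGION_EXIT = 3
REGION_NAMES = {REGION_SUBCAPSULAR: "subcapsular", REGION_CORTEX: "cortex",
                REGION_MEDULLA: "medulla", REGION_EXIT: "exit"}

CHEMOKINES = ("CXCL12", "CCL19_21", "S1P")

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _chebyshev_distance_to(mask: np.ndarray) -> np.ndarray:
    """Chessboard distance of every site to the nearest True site (BFS)."""
    h, w = mask.shape
    dist = np.full((h, w), -1, dtype=int)
    frontier = list(zip(*np.nonzero(mask)))
    for (r, c) in frontier:
        dist[r, c] = 0
    d = 0
    while frontier:
        nxt = []
        for (r, c) in frontier:
            for dr, dc in _MOORE:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and dist[rr, cc] < 0:
                    dist[rr, cc] = d + 1
                    nxt.append((rr, cc))
        frontier = nxt
        d += 1
    return dist


@dataclass
class ChemokineField:
    kind: str
    concentrations: np.ndarray  # (h, w), >= 0, maximal inside the attractor
    attractor: np.ndarray       # boolean mask


class ThymusLattice:
    """2-D grid with region labels, epithelial occupancy and chemokine fields."""

    def __init__(self, width: int, height: int, epithelial_fraction: float, seed: int):
        if width < 8 or height < 8:
            raise SimulationError("lattice must be at least 8x8")
        if not 0 < epithelial_fraction < 0.5:
            raise SimulationError(
                f"epithelial_fraction must be in (0, 0.5), got {epithelial_fraction}")
        self.width = width
        self.height = height
        rng = np.random.default_rng(seed)

        # banded anatomy: subcapsular | cortex | medulla, exit = last row
        self.region = np.full((height, width), REGION_CORTEX, dtype=int)
        n_sub = max(1, height // 6)
        n_med = max(2, height // 3)
        self.region[:n_sub, :] = REGION_SUBCAPSULAR
        self.region[height - n_med:, :] = REGION_MEDULLA
        self.region[height - 1, :] = REGION_EXIT

        n_epi = int(epithelial_fraction * width * height)
        flat = rng.choice(width * height, size=n_epi, replace=False)
        self.epithelium = np.zeros((height, width), dtype=bool)
        self.epithelium.ravel()[flat] = True

        self.occupant = np.full((height, width), -1, dtype=int)  # thymocyte id

        self.fields: dict[str, ChemokineField] = {}
        for kind, attractor in (
            ("CXCL12", self.region == REGION_CORTEX),
            ("CCL19_21", (self.region == REGION_MEDULLA) | (self.region == REGION_EXIT)),
            ("S1P", self.region == REGION_EXIT),
        ):
            dist = _chebyshev_distance_to(attractor)
            diameter = max(width, height)
            conc = np.maximum(0.0, 1.0 - dist / diameter)
            self.fields[kind] = ChemokineField(kind, conc, attractor)

    # -- helpers -----------------------------------------------------------
    def in_bounds(self, site: tuple[int, int]) -> bool:
        r, c = site
        return 0 <= r < self.height and 0 <= c < self.width

    def neighbors(self, site: tuple[int, int]) -> list[tuple[int, int]]:
        r, c = site
        return [(r + dr, c + dc) for dr, dc in _MOORE if self.in_bounds((r + dr, c + dc))]

    def vacant(self, site: tuple[int, int]) -> bool:
        return self.occupant[site] < 0

    def adjacent_epithelium(self, site: tuple[int, int]) -> list[tuple[int, int]]:
        return [s for s in self.neighbors(site) if self.epithelium[s]]

    def region_name(self, site: tuple[int, int]) -> str:
        return REGION_NAMES[int(self.region[site])]

    def is_exit(self, site: tuple[int, int]) -> bool:
        return self.region[site] == REGION_EXIT

    def epithelial_id(self, site: tuple[int, int]) -> int:
        return int(site[0] * self.width + site[1])


def build_thymus_lattice(width: int, height: int, epithelial_fraction: float,
                         seed: int) -> ThymusLattice:
    """Deterministic for a fixed seed; exactly floor(fraction*sites)
    epithelial cells placed uniformly at random."""
    return ThymusLattice(width, height, epithelial_fraction, seed)


# ---------------------------------------------------------------------------
# Interaction accounting and selection rules
# ---------------------------------------------------------------------------


@dataclass
class InteractionLog:
    """TCR/MHC contact history of one thymocyte."""

    total_bound_time: float = 0.0
    count: int = 0                       # number of binding events
    partners: dict[int, list] = field(default_factory=dict)  # id -> [count, duration]
    longest: float = 0.0                 # longest single interaction
    stage_clock: float = 0.0             # time since entering the current stage
    current_partner: int | None = None
    current_duration: float = 0.0

    def begin(self, partner: int) -> None:
        self.count += 1
        self.partners.setdefault(partner, [0, 0.0])[0] += 1
        self.current_partner = partner
        self.current_duration = 0.0

    def accrue(self, dt: float) -> None:
        assert self.current_partner is not None
        self.total_bound_time += dt
        self.current_duration += dt
        self.partners[self.current_partner][1] += dt
        self.longest = max(self.longest, self.current_duration)

    def end(self) -> None:
        self.longest = max(self.longest, self.current_duration)
        self.current_partner = None
        self.current_duration = 0.0


@dataclass
class SelectionThresholds:
    """Per-stage selection parameters (placeholder defaults)."""

    theta_pos: dict[str, int] = field(default_factory=lambda: {"DP": 5, "SP": 3})
    t_neglect: dict[str, float] = field(default_factory=lambda: {"DP": 30.0, "SP": 20.0})
    t_neg: float = 12.0        # cumulative bound-time ceiling -> negative selection
    tau_lineage: float = 2.0   # longest-interaction cutoff: >= tau -> CD4

    def stage_key(self, stage: str) -> str:
        if stage == "DP":
            return "DP"
        if stage in ("SP", "SP4", "SP8"):
            return "SP"
        raise SimulationError(f"unknown stage {stage!r} for selection thresholds")


def stage_chemokine(stage: str, mature: bool = False) -> str:
    """Which gradient orients migration for a differentiation stage."""
    if mature:
        if stage not in ("SP4", "SP8"):
            raise SimulationError("only SP cells mature for egress")
        return "S1P"
    if stage in ("DN", "DP"):
        return "CXCL12"
    if stage in ("SP4", "SP8"):
        return "CCL19_21"
    raise SimulationError(f"unknown stage {stage!r}")


def selection_decision(log: InteractionLog, thresholds: SelectionThresholds,
                       stage: str) -> str:
    """Priority order: negative > positive > death_by_neglect > none."""
    key = thresholds.stage_key(stage)
    if log.total_bound_time > thresholds.t_neg:
        return "negative"
    if log.count >= thresholds.theta_pos[key]:
        return "positive"
    if log.stage_clock > thresholds.t_neglect[key]:
        return "death_by_neglect"
    return "none"


def lineage_decision(log: InteractionLog, tau_lineage: float) -> str:
    """Signal-duration rule: longest interaction >= tau -> CD4, else CD8."""
    if log.count == 0:
        raise SimulationError("lineage decision requires at least one interaction")
    return "CD4" if log.longest >= tau_lineage else "CD8"


# ---------------------------------------------------------------------------
# Agents and movement
# ---------------------------------------------------------------------------


@dataclass
class Thymocyte:
    id: int
    stage: str = "DN"  # DN | DP | SP4 | SP8
    position: tuple[int, int] = (0, 0)
    mature: bool = False          # positively selected SP, heading for exit
    bound_to: tuple[int, int] | None = None
    log: InteractionLog = field(default_factory=InteractionLog)
    cortex_dwell: float = 0.0
    fate: str | None = None       # positive | death_by_neglect | negative | exported
    age: float = 0.0

    @property
    def bound(self) -> bool:
        return self.bound_to is not None


def move_agent(agent: Thymocyte, lattice: ThymusLattice, noise: float,
               rng: np.random.Generator) -> tuple[int, int]:
    """One migration step for an unbound agent.

    With probability 1-noise: greedy chemotaxis to the vacant neighbor with
    the highest stage-appropriate concentration, only if strictly higher
    than the current site (ties broken uniformly); with probability noise: a
    uniformly random vacant neighbor.  Stays put when boxed in.
    """
    if agent.bound:
        raise SimulationError(f"agent {agent.id} is bound and cannot move")
    field_ = lattice.fields[stage_chemokine(agent.stage, agent.mature)]
    here = agent.position
    vacant = [s for s in lattice.neighbors(here) if lattice.vacant(s)]
    if not vacant:
        return here
    if rng.random() < noise:
        dest = vacant[rng.integers(len(vacant))]
    else:
        conc = field_.concentrations
        best = max(conc[s] for s in vacant)
        if best <= conc[here]:
            return here
        candidates = [s for s in vacant if conc[s] == best]
        dest = candidates[rng.integers(len(candidates))]
    lattice.occupant[here] = -1
    lattice.occupant[dest] = agent.id
    agent.position = dest
    return dest


def update_binding(agent: Thymocyte, lattice: ThymusLattice, dt: float,
                   rng: np.random.Generator, k_on: float, k_off: float) -> bool:
    """TCR/MHC binding kinetics for one step; returns the new bound state.

    Unbound + adjacent epithelium: bind with prob 1-e^(-k_on*dt) to a
    uniformly chosen adjacent epithelial cell.  Bound: accrue dt of contact,
    then unbind with prob 1-e^(-k_off*dt).
    """
    if agent.bound:
        agent.log.accrue(dt)
        if rng.random() < rate_to_prob(k_off, dt):
            agent.log.end()
            agent.bound_to = None
        return agent.bound
    epis = lattice.adjacent_epithelium(agent.position)
    if not epis:
        return False
    if rng.random() < rate_to_prob(k_on, dt):
        site = epis[rng.integers(len(epis))]
        agent.bound_to = site
        agent.log.begin(lattice.epithelial_id(site))
    return agent.bound


def egress_check(agent: Thymocyte, lattice: ThymusLattice,
                 log: list | None = None, t: float = 0.0) -> bool:
    """True iff a mature (positively selected) SP stands on an exit site;
    removes the agent and logs an export event when true."""
    if agent.stage not in ("SP4", "SP8") or not agent.mature:
        return False
    if not lattice.is_exit(agent.position):
        return False
    lattice.occupant[agent.position] = -1
    agent.fate = "exported"
    if log is not None:
        log.append((t, agent.id, "export", "CD4" if agent.stage == "SP4" else "CD8"))
    return True


# ---------------------------------------------------------------------------
# Whole-thymus simulation
# ---------------------------------------------------------------------------


@dataclass
class ThymusConfig:
    width: int = 40
    height: int = 40
    epithelial_fraction: float = 0.15
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    k_on: float = 5.0
    k_off: float = 1.0
    noise: float = 0.2
    dt: float = 0.1
    dn_cortex_dwell: float = 10.0   # DN -> DP after this much time in cortex
    influx_per_step: int = 1        # new DN agents per step

    @classmethod
    def from_document(cls, data: dict) -> "ThymusConfig":
        data = dict(data.get("spatial", data))
        th = data.pop("thresholds", None)
        cfg = cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})
        if th:
            cfg.thresholds = SelectionThresholds(
                theta_pos={"DP": int(th.get("theta_pos_DP", 5)),
                           "SP": int(th.get("theta_pos_SP", 3))},
                t_neglect={"DP": float(th.get("t_neglect_DP", 30.0)),
                           "SP": float(th.get("t_neglect_SP", 20.0))},
                t_neg=float(th.get("t_neg", 12.0)),
                tau_lineage=float(th.get("tau_lineage", 2.0)),
            )
        return cfg


@dataclass
class SpatialResult:
    times: np.ndarray
    stage_counts: dict[str, np.ndarray]
    fates: dict[str, int]      # exported_CD4, exported_CD8, neglect, negative, death... counts
    log: list[tuple]
    agents: dict[int, Thymocyte]
    snapshots: list[dict] = field(default_factory=list)


class ThymusWorld:
    """Driver binding the migration/selection rules together."""

    def __init__(self, config: ThymusConfig, seed: int):
        self.config = config
        self.rng = np.random.default_rng(seed)
        self.lattice = build_thymus_lattice(config.width, config.height,
                                            config.epithelial_fraction,
                                            seed=int(self.rng.integers(2**31)))
        self.agents: dict[int, Thymocyte] = {}
        self.log: list[tuple] = []
        self.clock = 0.0
        self.next_id = 0
        self.fates = {"exported_CD4": 0, "exported_CD8": 0,
                      "death_by_neglect": 0, "negative": 0, "influx": 0}

    def _spawn_dn(self) -> Thymocyte | None:
        sub = np.argwhere((self.lattice.region == REGION_SUBCAPSULAR)
                          & (self.lattice.occupant < 0))
        if len(sub) == 0:
            return None
        site = tuple(sub[self.rng.integers(len(sub))])
        agent = Thymocyte(self.next_id, stage="DN", position=site)
        self.next_id += 1
        self.agents[agent.id] = agent
        self.lattice.occupant[site] = agent.id
        self.log.append((self.clock, agent.id, "influx", "DN"))
        self.fates["influx"] += 1
        return agent

    def _remove(self, agent: Thymocyte, fate: str) -> None:
        self.lattice.occupant[agent.position] = -1
        agent.fate = fate
        del self.agents[agent.id]
        self.log.append((self.clock, agent.id, fate, agent.stage))
        if fate in self.fates:
            self.fates[fate] += 1

    def step(self) -> None:
        cfg = self.config
        dt = cfg.dt
        for _ in range(cfg.influx_per_step):
            self._spawn_dn()
        order = list(self.agents.keys())
        self.rng.shuffle(order)
        for aid in order:
            agent = self.agents.get(aid)
            if agent is None:
                continue
            agent.age += dt
            agent.log.stage_clock += dt
            update_binding(agent, self.lattice, dt, self.rng, cfg.k_on, cfg.k_off)
            if not agent.bound:
                move_agent(agent, self.lattice, cfg.noise, self.rng)

            if agent.stage == "DN":
                if self.lattice.region[agent.position] == REGION_CORTEX:
                    agent.cortex_dwell += dt
                if agent.cortex_dwell >= cfg.dn_cortex_dwell:
                    agent.stage = "DP"
                    agent.log.stage_clock = 0.0
                    self.log.append((self.clock, agent.id, "differentiate", "DP"))
                continue

            if agent.stage == "DP":
                outcome = selection_decision(agent.log, cfg.thresholds, "DP")
                if outcome == "negative":
                    self._remove(agent, "negative")
                elif outcome == "death_by_neglect":
                    self._remove(agent, "death_by_neglect")
                elif outcome == "positive":
                    lineage = lineage_decision(agent.log, cfg.thresholds.tau_lineage)
                    agent.stage = "SP4" if lineage == "CD4" else "SP8"
                    agent.log.stage_clock = 0.0
                    self.log.append((self.clock, agent.id, "positive", lineage))
                continue

            # SP stages
            if not agent.mature:
                outcome = selection_decision(agent.log, cfg.thresholds, "SP")
                if outcome == "negative":
                    self._remove(agent, "negative")
                    continue
                if outcome == "death_by_neglect":
                    self._remove(agent, "death_by_neglect")
                    continue
                if outcome == "positive":
                    agent.mature = True
                    self.log.append((self.clock, agent.id, "mature", agent.stage))
            if agent.mature and egress_check(agent, self.lattice, self.log, self.clock):
                lineage = "CD4" if agent.stage == "SP4" else "CD8"
                self.fates[f"exported_{lineage}"] += 1
                del self.agents[agent.id]
        self.clock += dt

    def snapshot(self) -> dict:
        sites = []
        for (r, c) in zip(*np.nonzero(self.lattice.occupant >= 0)):
            aid = int(self.lattice.occupant[r, c])
            sites.append({"row": int(r), "col": int(c),
                          "region": self.lattice.region_name((r, c)),
                          "agent_stage": self.agents[aid].stage})
        return {"t": self.clock, "sites": sites,
                "agents": [{"id": a.id, "stage": a.stage, "mature": a.mature,
                            "row": int(a.position[0]), "col": int(a.position[1])}
                           for a in self.agents.values()]}


def run_thymus_abm(config: ThymusConfig, t_end: float, seed: int,
                   snapshot_every: int = 0) -> SpatialResult:
    """Run the spatial simulation; reproducible for a fixed seed."""
    world = ThymusWorld(config, seed)
    n_steps = int(round(t_end / config.dt))
    times = np.arange(n_steps + 1) * config.dt
    stages = ("DN", "DP", "SP4", "SP8")
    stage_counts = {s: np.zeros(n_steps + 1, dtype=int) for s in stages}
    snaps = []
    for step in range(n_steps + 1):
        for s in stages:
            stage_counts[s][step] = sum(1 for a in world.agents.values() if a.stage == s)
        if snapshot_every and step % snapshot_every == 0:
            snaps.append(world.snapshot())
        if step < n_steps:
            world.step()
    return SpatialResult(times, stage_counts, dict(world.fates), world.log,
                         dict(world.agents), snaps)
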