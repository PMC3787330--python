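"""Parallel state-transition (statechart) models.

A model is a set of orthogonal *regions*, each an ordinary state machine.
A cell occupies one state per region simultaneously; the population/agent
backends operate on the cross product of the regions' state sets (the
*flat* states), minus combinations declared non-existent by exclusion
predicates.

Cross-region coupling is expressed through transition *guards* (predicates
over the other regions' current states).  Transitions of kind ``division``
may additionally *advance* a designated region by one state (daughters move
to the next generation, saturating at the last admissible state) and any
flow transition may *reset* other regions to fixed states.

The textual encoding is a small YAML dialect, see :func:`parse_model`.
"""

from __future__ import annotations

import io
import itertools
import re
from dataclasses import dataclass, field

import sympy
import yaml

from .errors import ModelError

EXIT = "EXIT"

KINDS = ("flow", "division", "export", "death")

_IDENT = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


# ---------------------------------------------------------------------------
# Predicates (guards and exclusion selectors)
# ---------------------------------------------------------------------------

_ATOM = re.compile(
    r"^\s*(?P<region>[A-Za-z_][A-Za-z0-9_]*)\s*"
    r"(?P<op>==|!=|not\s+in|in)\s*"
    r"(?P<value>.+?)\s*$"
)


@dataclass(frozen=True)
class PredicateAtom:
    region: str
    op: str  # '==', '!=', 'in', 'not in'
    values: tuple[str, ...]

    def test(self, assignment: dict[str, str]) -> bool:
        state = assignment[self.region]
        member = state in self.values
        if self.op in ("==", "in"):
            return member
        return not member

    def render(self) -> str:
        if self.op in ("==", "!="):
            return f"{self.region} {self.op} {self.values[0]}"
        inner = ", ".join(self.values)
        return f"{self.region} {self.op} [{inner}]"


@dataclass(frozen=True)
class Predicate:
    """Conjunction of equality/membership tests on region states."""

    atoms: tuple[PredicateAtom, ...]

    def test(self, assignment: dict[str, str]) -> bool:
        return all(a.test(assignment) for a in self.atoms)

    def render(self) -> str:
        return " and ".join(a.render() for a in self.atoms)


def parse_predicate(text: str) -> Predicate:
    atoms = []
    for chunk in re.split(r"\s+and\s+", text.strip()):
        m = _ATOM.match(chunk)
        if m is None:
            raise ModelError(f"cannot parse predicate atom {chunk!r}")
        op = re.sub(r"\s+", " ", m.group("op"))
        raw = m.group("value").strip()
        if op in ("in", "not in"):
            if not (raw.startswith("[") and raw.endswith("]")):
                raise ModelError(f"membership test needs a [list] in {chunk!r}")
            values = tuple(v.strip() for v in raw[1:-1].split(",") if v.strip())
        else:
            values = (raw,)
        for v in values:
            if not _IDENT.match(v):
                raise ModelError(f"bad state identifier {v!r} in predicate {chunk!r}")
        atoms.append(PredicateAtom(m.group("region"), op, values))
    return Predicate(tuple(atoms))


# ---------------------------------------------------------------------------
# Rate expressions
# ---------------------------------------------------------------------------

_I = sympy.Symbol("i")


class RateExpr:
    """A transition rate: constant, per-generation table, or affine in ``i``.

    ``i`` is the 1-based index of the flat state's generation-region state.
    Only affine (and table-lookup) forms are admitted so compiled population
    systems stay linear in the state vector.
    """

    def __init__(self, raw, parameters: dict):
        self.raw = raw
        self._table_name = None
        self._const = None
        self._expr = None
        if isinstance(raw, (int, float)):
            self._const = float(raw)
            return
        text = str(raw).strip()
        if _IDENT.match(text):
            if text not in parameters:
                raise ModelError(f"unknown parameter {text!r}")
            val = parameters[text]
            if isinstance(val, (list, tuple)):
                self._table_name = text
            else:
                self._table_name = None
                self._expr = sympy.Symbol(text)
            return
        try:
            expr = sympy.sympify(text, rational=False)
        except (sympy.SympifyError, SyntaxError) as exc:
            raise ModelError(f"cannot parse rate expression {raw!r}: {exc}") from exc
        for sym in expr.free_symbols:
            if sym is not _I and str(sym) not in parameters:
                raise ModelError(f"unknown parameter {sym!r} in rate {raw!r}")
            if str(sym) in parameters and isinstance(parameters[str(sym)], (list, tuple)):
                raise ModelError(f"table parameter {sym!r} may not appear in expression {raw!r}")
        self._expr = expr

    @property
    def uses_generation(self) -> bool:
        if self._table_name is not None:
            return True
        if self._expr is not None:
            return _I in self._expr.free_symbols
        return False

    def check_affine(self) -> None:
        """Raise CompileError if not affine in the generation index."""
        from .errors import CompileError

        if self._expr is not None and _I in self._expr.free_symbols:
            poly = sympy.Poly(sympy.expand(self._expr), _I)
            if poly.degree() > 1:
                raise CompileError(f"nonlinear rate expression {self.raw!r} (degree {poly.degree()} in i)")

    def value(self, parameters: dict, i: int | None = None) -> float:
        if self._const is not None:
            return self._const
        if self._table_name is not None:
            table = parameters[self._table_name]
            if i is None or not (1 <= i <= len(table)):
                raise ModelError(
                    f"generation index {i} out of range for table parameter {self._table_name!r}"
                )
            return float(table[i - 1])
        subs = {sympy.Symbol(k): v for k, v in parameters.items() if not isinstance(v, (list, tuple))}
        if _I in self._expr.free_symbols:
            if i is None:
                raise ModelError(f"rate {self.raw!r} needs a generation region")
            subs[_I] = i
        return float(self._expr.subs(subs))

    def render(self, i: int | None = None) -> str:
        """Symbolic text using parameter names (``i`` substituted numerically)."""
        if self._const is not None:
            return repr(self._const)
        if self._table_name is not None:
            return f"{self._table_name}_{i}"
        expr = self._expr
        if i is not None and _I in expr.free_symbols:
            expr = expr.subs(_I, i)
        return str(expr)

    def __repr__(self):
        return f"RateExpr({self.raw!r})"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Transition:
    source: str
    target: str  # state name or EXIT
    rate: RateExpr
    kind: str = "flow"
    guard: Predicate | None = None
    advance: str | None = None  # region advanced by one state on division
    reset: dict[str, str] = field(default_factory=dict)
    channel: str | None = None

    def default_channel(self) -> str:
        if self.channel:
            return self.channel
        return "deaths" if self.kind == "death" else "exports"


@dataclass
class Region:
    name: str
    states: list[str]
    initial: str
    transitions: list[Transition] = field(default_factory=list)


@dataclass
class Source:
    into: Predicate
    rate: RateExpr


@dataclass
class StateChartModel:
    name: str
    parameters: dict
    regions: list[Region]
    sources: list[Source] = field(default_factory=list)
    exclusions: list[Predicate] = field(default_factory=list)
    generation_region: str | None = None
    gamma: float = 1.0

    # -- lookups ----------------------------------------------------------
    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise ModelError(f"unknown region {name!r}")

    @property
    def region_names(self) -> list[str]:
        return [r.name for r in self.regions]

    def is_excluded(self, assignment: dict[str, str]) -> bool:
        return any(p.test(assignment) for p in self.exclusions)

    def generation_index(self, assignment: dict[str, str]) -> int | None:
        if self.generation_region is None:
            return None
        reg = self.region(self.generation_region)
        return reg.states.index(assignment[self.generation_region]) + 1


@dataclass(frozen=True)
class FlatState:
    """One point of the regions' cross product."""

    assignment: tuple[tuple[str, str], ...]  # (region name, state name) pairs
    index: int

    @property
    def mapping(self) -> dict[str, str]:
        return dict(self.assignment)

    @property
    def name(self) -> str:
        return ".".join(state for _, state in self.assignment)

    @property
    def var_name(self) -> str:
        return "x_" + "_".join(state for _, state in self.assignment)


@dataclass
class Diagnostic:
    severity: str  # 'error' | 'warning'
    message: str
    location: str

    def __str__(self):
        return f"{self.severity}: {self.message} [{self.location}]"


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ModelError(msg)


def parse_model(doc) -> StateChartModel:
    """Parse a model document (YAML text, file object, or mapping).

    Raises :class:`ModelError` with messages naming the offending element:
    "unknown state", "unknown parameter", "duplicate region", ...
    """
    if hasattr(doc, "read"):
        doc = doc.read()
    if isinstance(doc, (str, bytes)):
        data = yaml.safe_load(io.StringIO(doc if isinstance(doc, str) else doc.decode()))
    else:
        data = doc
    _require(isinstance(data, dict), "model document must be a mapping")
    name = data.get("name", "model")

    parameters = dict(data.get("parameters") or {})
    for pname, val in parameters.items():
        _require(_IDENT.match(pname) is not None, f"bad parameter name {pname!r}")
        if isinstance(val, (list, tuple)):
            parameters[pname] = [float(v) for v in val]
        else:
            parameters[pname] = float(val)

    regions: list[Region] = []
    seen_regions: set[str] = set()
    for rdata in data.get("regions") or []:
        rname = rdata["name"]
        _require(_IDENT.match(rname) is not None, f"bad region name {rname!r}")
        if rname in seen_regions:
            raise ModelError(f"duplicate region {rname!r}")
        seen_regions.add(rname)
        states = list(rdata.get("states") or [])
        _require(len(states) > 0, f"region {rname!r} has no states")
        _require(len(set(states)) == len(states), f"duplicate state in region {rname!r}")
        for s in states:
            _require(_IDENT.match(s) is not None and s != EXIT, f"bad state name {s!r} in region {rname!r}")
        initial = rdata.get("initial", states[0])
        _require(initial in states, f"unknown state: initial {initial!r} not in region {rname!r}")
        transitions = []
        for tdata in rdata.get("transitions") or []:
            src, tgt = tdata["from"], tdata["to"]
            kind = tdata.get("kind", "flow")
            _require(kind in KINDS, f"unknown transition kind {kind!r} in region {rname!r}")
            if src not in states:
                raise ModelError(f"unknown state {src!r} in region {rname!r}")
            if tgt != EXIT and tgt not in states:
                raise ModelError(f"unknown state {tgt!r} in region {rname!r}")
            if kind in ("export", "death"):
                _require(tgt == EXIT, f"{kind} transition {src!r} must target EXIT (region {rname!r})")
            else:
                _require(tgt != EXIT, f"{kind} transition from {src!r} may not target EXIT (region {rname!r})")
            rate = RateExpr(tdata["rate"], parameters)
            guard = parse_predicate(tdata["guard"]) if tdata.get("guard") else None
            reset = dict(tdata.get("reset") or {})
            advance = tdata.get("advance")
            if advance is not None:
                _require(kind == "division", f"'advance' is only valid on division transitions (region {rname!r})")
            transitions.append(
                Transition(src, tgt, rate, kind, guard, advance, reset, tdata.get("channel"))
            )
        sigs = [(t.source, t.target, t.rate.render(None) if not t.rate.uses_generation else str(t.rate.raw)) for t in transitions]
        _require(len(set(sigs)) == len(sigs), f"duplicate (source,target,label) transition in region {rname!r}")
        regions.append(Region(rname, states, initial, transitions))

    model = StateChartModel(
        name=name,
        parameters=parameters,
        regions=regions,
        generation_region=data.get("generation_region"),
        gamma=float(data.get("gamma", 1.0)),
    )

    region_states = {r.name: set(r.states) for r in regions}

    def check_predicate(pred: Predicate, where: str) -> None:
        for atom in pred.atoms:
            if atom.region not in region_states:
                raise ModelError(f"unknown region {atom.region!r} in {where}")
            for v in atom.values:
                if v not in region_states[atom.region]:
                    raise ModelError(f"unknown state {v!r} of region {atom.region!r} in {where}")

    for r in regions:
        for t in r.transitions:
            if t.guard is not None:
                check_predicate(t.guard, f"guard of {r.name}:{t.source}->{t.target}")
                for atom in t.guard.atoms:
                    _require(atom.region != r.name, f"guard in region {r.name!r} may not test its own region")
            for reg, st in t.reset.items():
                _require(reg in region_states, f"unknown region {reg!r} in reset")
                _require(st in region_states[reg], f"unknown state {st!r} in reset of region {reg!r}")
                _require(reg != r.name, f"reset may not target the transition's own region {reg!r}")
            if t.advance is not None:
                _require(t.advance in region_states, f"unknown region {t.advance!r} in advance")

    for sdata in data.get("sources") or []:
        pred = parse_predicate(sdata["into"])
        check_predicate(pred, "source selector")
        model.sources.append(Source(pred, RateExpr(sdata["rate"], parameters)))
    for text in data.get("exclusions") or []:
        pred = parse_predicate(text)
        check_predicate(pred, "exclusion")
        model.exclusions.append(pred)

    if model.generation_region is not None:
        model.region(model.generation_region)  # raises if unknown
    else:
        for r in regions:
            for t in r.transitions:
                if t.rate.uses_generation:
                    raise ModelError(
                        f"rate {t.rate.raw!r} uses the generation index but no "
                        "generation_region is declared"
                    )
    return model


def serialize_model(model: StateChartModel) -> str:
    """Serialize back to the YAML dialect (parse∘serialize is the identity)."""

    def rate_out(r: RateExpr):
        return r.raw

    data: dict = {"name": model.name}
    if model.generation_region is not None:
        data["generation_region"] = model.generation_region
    data["gamma"] = model.gamma
    data["parameters"] = {
        k: (list(v) if isinstance(v, (list, tuple)) else v) for k, v in model.parameters.items()
    }
    data["regions"] = []
    for r in model.regions:
        rd: dict = {"name": r.name, "states": list(r.states), "initial": r.initial, "transitions": []}
        for t in r.transitions:
            td: dict = {"from": t.source, "to": t.target, "rate": rate_out(t.rate), "kind": t.kind}
            if t.guard is not None:
                td["guard"] = t.guard.render()
            if t.advance is not None:
                td["advance"] = t.advance
            if t.reset:
                td["reset"] = dict(t.reset)
            if t.channel is not None:
                td["channel"] = t.channel
            rd["transitions"].append(td)
        data["regions"].append(rd)
    if model.sources:
        data["sources"] = [{"into": s.into.render(), "rate": rate_out(s.rate)} for s in model.sources]
    if model.exclusions:
        data["exclusions"] = [p.render() for p in model.exclusions]
    return yaml.safe_dump(data, sort_keys=False)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_model(model: StateChartModel) -> list[Diagnostic]:
    """Return diagnostics; an empty list means the model is fully valid.

    Errors: negative rate values anywhere in the admissible generation range.
    Warnings: states unreachable from the region's initial state (following
    declared transitions, division 'advance' chains, reset targets and
    source selectors).
    """
    diags: list[Diagnostic] = []
    gen_range = [None]
    if model.generation_region is not None:
        gen_range = list(range(1, len(model.region(model.generation_region).states) + 1))

    for r in model.regions:
        for t in r.transitions:
            loc = f"{r.name}:{t.source}->{t.target}"
            for i in gen_range:
                try:
                    v = t.rate.value(model.parameters, i)
                except ModelError:
                    continue  # table shorter than the full range; checked where used
                if v < 0:
                    diags.append(Diagnostic("error", f"rate {t.rate.raw!r} is negative ({v}) at i={i}", loc))
                    break

    # advance targets: which regions are advanced by some division transition
    advanced = {t.advance for r in model.regions for t in r.transitions if t.advance}
    reset_targets: dict[str, set[str]] = {}
    for r in model.regions:
        for t in r.transitions:
            for reg, st in t.reset.items():
                reset_targets.setdefault(reg, set()).add(st)
    source_states: dict[str, set[str]] = {}
    for s in model.sources:
        for atom in s.into.atoms:
            if atom.op in ("==", "in"):
                source_states.setdefault(atom.region, set()).update(atom.values)

    for r in model.regions:
        seeds = {r.initial}
        seeds |= reset_targets.get(r.name, set())
        seeds |= source_states.get(r.name, set())
        edges: dict[str, set[str]] = {s: set() for s in r.states}
        for t in r.transitions:
            if t.target != EXIT:
                edges[t.source].add(t.target)
        if r.name in advanced:
            for a, b in zip(r.states, r.states[1:]):
                edges[a].add(b)
        reached = set()
        frontier = list(seeds)
        while frontier:
            s = frontier.pop()
            if s in reached:
                continue
            reached.add(s)
            frontier.extend(edges[s])
        for s in r.states:
            if s not in reached:
                diags.append(Diagnostic("warning", f"state {s!r} unreachable from initial", r.name))
    return diags


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------


def flatten_product_states(model: StateChartModel) -> list[FlatState]:
    """Cross product of all regions' states minus excluded combinations.

    Ordering is lexicographic by region declaration order then state
    declaration order; indices are 0..K-1 and stable across runs.
    """
    names = model.region_names
    flats: list[FlatState] = []
    for combo in itertools.product(*(r.states for r in model.regions)):
        assignment = tuple(zip(names, combo))
        if model.is_excluded(dict(assignment)):
            continue
        flats.append(FlatState(assignment, len(flats)))
    if not flats:
        raise ModelError("empty model: exclusions eliminate all flat states")
    return flats


def advance_assignment(model: StateChartModel, assignment: dict[str, str], region_name: str) -> dict[str, str]:
    """Move `region_name` one state forward, saturating before excluded combos."""
    reg = model.region(region_name)
    idx = reg.states.index(assignment[region_name])
    if idx + 1 >= len(reg.states):
        return dict(assignment)
    candidate = dict(assignment)
    candidate[region_name] = reg.states[idx + 1]
    if model.is_excluded(candidate):
        return dict(assignment)
    return candidate
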