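"""Independent oracles used by the test suite.

These deliberately avoid the compiled-matrix path: the RHS oracle walks the
model structure term by term, and the equation evaluator re-parses the
exported text with sympy.  They share only the model *definition* objects
(predicates, rate expressions) with the package.
"""

from __future__ import annotations

import re

import numpy as np
import sympy

from thymostate.statechart import EXIT, flatten_product_states


def brute_force_rhs(model, x, gamma):
    """Enumerate every individual flux of the flattened system by hand."""
    flats = flatten_product_states(model)
    index = {f.name: f.index for f in flats}
    dx = np.zeros(len(flats))

    def resolve(assignment, region_name, target, reset, advance):
        a = dict(assignment)
        a[region_name] = target
        a.update(reset)
        if advance is not None:
            reg = model.region(advance)
            pos = reg.states.index(a[advance])
            if pos + 1 < len(reg.states):
                trial = dict(a)
                trial[advance] = reg.states[pos + 1]
                if not model.is_excluded(trial):
                    a = trial
        return ".".join(a[r.name] for r in model.regions)

    for f in flats:
        assignment = f.mapping
        i = model.generation_index(assignment)
        for src in model.sources:
            if src.into.test(assignment):
                dx[f.index] += src.rate.value(model.parameters, i)
        for region in model.regions:
            for t in region.transitions:
                if t.source != assignment[region.name]:
                    continue
                if t.guard is not None and not t.guard.test(assignment):
                    continue
                r = t.rate.value(model.parameters, i)
                dx[f.index] -= r * x[f.index]
                if t.kind == "flow":
                    tgt = resolve(assignment, region.name, t.target, t.reset, None)
                    dx[index[tgt]] += r * x[f.index]
                elif t.kind == "division":
                    tgt = resolve(assignment, region.name, t.target, t.reset, t.advance)
                    dx[index[tgt]] += 2.0 * gamma * r * x[f.index]
                else:
                    assert t.target == EXIT
    return dx


def evaluate_equation_text(text, flat_parameters, state_names, x):
    """Re-evaluate exported equation lines at a state vector with sympy."""
    values = dict(flat_parameters)
    for nm, xv in zip(state_names, x):
        values["x_" + nm.replace(".", "_")] = xv
    out = np.zeros(len(state_names))
    lines = [ln for ln in text.splitlines() if ln.startswith("d")]
    assert len(lines) == len(state_names)
    for ln in lines:
        m = re.match(r"^d(x_\w+)/dt = (.*)$", ln)
        assert m, ln
        var, rhs = m.groups()
        # name->Symbol map: avoids collisions with sympy builtins (gamma, S, ...)
        local = {k: sympy.Symbol(k) for k in values}
        expr = sympy.sympify(rhs, locals=local)
        val = float(expr.evalf(subs={sympy.Symbol(k): v for k, v in values.items()
                                     if sympy.Symbol(k) in expr.free_symbols}))
        out[[("x_" + nm.replace(".", "_")) for nm in state_names].index(var)] = val
    return out
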