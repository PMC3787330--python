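"""Random statechart documents for property tests.

The generator always produces a *valid* model: every state reachable,
rates nonnegative, guards and resets well-formed, optional division
transitions and a generation region.  Deterministic per seed.
"""

from __future__ import annotations

import numpy as np
import yaml


def generate_fixture_model(seed: int, n_regions: int = 2, max_states: int = 4) -> str:
    """A random valid model document (YAML text)."""
    if not 1 <= n_regions <= 4:
        raise ValueError("n_regions must be in 1..4")
    if not 1 <= max_states <= 5:
        raise ValueError("max_states must be in 1..5")
    rng = np.random.default_rng(seed)

    parameters: dict[str, float | list[float]] = {}

    def new_param(prefix: str, lo=0.01, hi=1.0) -> str:
        name = f"{prefix}{len(parameters)}"
        parameters[name] = round(float(rng.uniform(lo, hi)), 4)
        return name

    region_specs = []
    for r in range(n_regions):
        n_states = int(rng.integers(1, max_states + 1))
        region_specs.append((f"r{r}", [f"r{r}s{j}" for j in range(n_states)]))

    # maybe designate the last multi-state region as a generation region
    gen_region = None
    if n_regions >= 2 and len(region_specs[-1][1]) >= 2 and rng.random() < 0.5:
        gen_region = region_specs[-1][0]

    regions = []
    for rname, states in region_specs:
        transitions = []
        if rname != gen_region:
            # forward chain keeps every state reachable
            for a, b in zip(states, states[1:]):
                t = {"from": a, "to": b, "rate": new_param("k"), "kind": "flow"}
                if rng.random() < 0.3 and n_regions > 1:
                    other, ostates = region_specs[0] if rname != region_specs[0][0] else region_specs[1]
                    t["guard"] = f"{other} == {ostates[int(rng.integers(len(ostates)))]}"
                transitions.append(t)
            # occasional extras
            if len(states) > 1 and rng.random() < 0.5:
                transitions.append({"from": states[-1], "to": states[0],
                                    "rate": new_param("k"), "kind": "flow"})
            if rng.random() < 0.5:
                transitions.append({"from": states[int(rng.integers(len(states)))],
                                    "to": "EXIT", "rate": new_param("d"), "kind": "death"})
            if rng.random() < 0.3:
                transitions.append({"from": states[-1], "to": "EXIT",
                                    "rate": new_param("e"), "kind": "export"})
            if rng.random() < 0.4:
                src = states[int(rng.integers(len(states)))]
                tgt = states[int(rng.integers(len(states)))]
                t = {"from": src, "to": tgt, "rate": new_param("p"), "kind": "division"}
                if gen_region is not None:
                    t["advance"] = gen_region
                transitions.append(t)
            if gen_region is not None and transitions and rng.random() < 0.5:
                # make one flow rate affine in the generation index
                flows = [t for t in transitions if t["kind"] == "flow"]
                if flows:
                    base, slope = new_param("u", 0.01, 0.5), new_param("s", 0.0, 0.2)
                    flows[0]["rate"] = f"{base} + {slope}*(i - 1)"
            if gen_region is not None and rng.random() < 0.3:
                n_gen = len(dict(region_specs)[gen_region])
                name = f"tab{len(parameters)}"
                parameters[name] = [round(float(v), 4)
                                    for v in rng.uniform(0.01, 1.0, size=n_gen)]
                transitions.append({"from": states[0], "to": "EXIT",
                                    "rate": name, "kind": "death"})
        regions.append({"name": rname, "states": states, "initial": states[0],
                        "transitions": transitions})

    doc: dict = {"name": f"fixture_{seed}", "gamma": 1.0}
    if gen_region is not None:
        doc["generation_region"] = gen_region
    doc["parameters"] = parameters
    doc["regions"] = regions
    if rng.random() < 0.7:
        doc["sources"] = [{"into": f"{region_specs[0][0]} == {region_specs[0][1][0]}",
                           "rate": new_param("S", 1.0, 50.0)}]
        doc["parameters"] = parameters  # S param added after
    return yaml.safe_dump(doc, sort_keys=False)
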