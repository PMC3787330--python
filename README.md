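# thymostate

Executable parallel state-transition (statechart) models of thymocyte
dynamics, with two interchangeable backends:

* a **population compiler** that flattens the parallel regions into a
  product-state vector, emits one linear ODE per flat state (with the
  division flux `2*gamma*p*x_parent`), exports human-readable equations,
  and integrates trajectories;
* a **stochastic agent interpreter** that executes the same statechart
  per cell in discrete time with competing-risks sampling, division,
  death, export, and an exact event log — plus a mean-field comparison
  harness (agent replicate means vs the compiled ODE, per-state z-scores).

Two concrete models ship in `models/`:

* `conveyor_belt.yaml` — conveyor-belt thymocyte differentiation:
  DN → DP (early/late) → SP4/SP8 across division generations, a parallel
  G0/SM cell-cycle region, progenitor influx, egress, and the ganciclovir
  perturbation (`gamma = 0` kills dividing cells; quiescent late-DP cells
  are structurally exempt).  The default decomposition flattens to exactly
  30 ODEs.
* `thymus_lattice.yaml` — a 2-D spatial model: banded thymic anatomy
  (subcapsular / cortex / medulla / exit row), a random epithelial network,
  static chemokine gradients (CXCL12, CCL19/CCL21, S1P) steering
  stage-dependent migration, TCR/MHC binding with interaction accounting,
  positive selection / death by neglect / negative selection, the
  signal-duration CD4-vs-CD8 lineage rule, and egress.

Rate values in both model files are placeholders with plausible magnitudes,
not fitted values; everything is overridable in the YAML.

## CLI

```sh
thymostate compile       --model models/conveyor_belt.yaml
thymostate equations     --model models/conveyor_belt.yaml          # 30 lines
thymostate simulate-ode  --model models/conveyor_belt.yaml --t-end 50 --dt 0.5 --out traj.csv
thymostate simulate-abm  --model models/conveyor_belt.yaml --agents 1000 \
                         --t-end 5 --dt 0.01 --seed 1 --out counts.csv --log events.jsonl
thymostate simulate-abm  --model models/thymus_lattice.yaml --t-end 50 --seed 1 --out stages.csv
thymostate deplete       --model models/conveyor_belt.yaml --t-on 5 --t-off 10 --out deplete.csv
thymostate compare       --model models/conveyor_belt.yaml --seed 1
```

Exit codes: 0 success, 2 usage error, 1 model error.  Every seeded run is
bit-for-bit reproducible.

## Model document dialect

YAML with top-level keys `name`, `parameters` (scalar or per-generation
list), `regions` (each `{name, states, initial, transitions}`), `sources`,
`exclusions`, optional `generation_region` and `gamma`.  Transitions are
`{from, to, rate, kind, guard?, reset?, advance?, channel?}` with
`kind ∈ {flow, division, export, death}`; `to: EXIT` for export/death.
Guards and exclusion selectors are conjunctions of `region == state`,
`region != state`, `region in [a, b]` tests on the *other* regions.  Rates
are parameter names, per-generation table lookups, or expressions affine in
the generation index `i` (e.g. `u0 + s*(i - 1)`).

## Layout

```
src/thymostate/
  statechart.py   parse/validate/serialize/flatten parallel statecharts
  ode.py          population compiler, equation export, LSODA integration
  conveyor.py     conveyor-belt model builder + ganciclovir experiment
  abm.py          agent interpreter, counts-path scheduler, mean-field report
  lattice.py      2-D thymus lattice, migration/binding/selection rules
  fixtures.py     random valid model documents for property tests
  io.py, cli.py   CSV/JSONL writers, click CLI
models/           shipped model documents
tests/            pytest suite (tests/test_acceptance.py = acceptance criteria)
scripts/          acceptance.py
```
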