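# Conveyor-belt thymocyte differentiation model (default decomposition:
# DN x4 generations, DP_early x6, DP_late x2 quiescent-only, SP4 x2, SP8 x2,
# each crossed with the G0/SM cell-cycle region -> 30 flat states).
# Rate values are placeholders chosen for a stable steady state; override freely.
name: conveyor_belt
generation_region: generation
gamma: 1.0
parameters:
  Sn: 10000.0
  Pn: 0.2
  Pp: 0.2
  Ps: 0.2
  Dn: 0.05
  Dp: 0.05
  Ds: 0.05
  a4: 0.08
  a8: 0.02
  Us4: 0.5
  Us8: 0.5
  u0_DN: 0.05
  u0_DP: 0.05
  s: 0.05
  act: 0.5
regions:
- name: differentiation
  states:
  - DN
  - DP_early
  - DP_late
  - SP4
  - SP8
  initial: DN
  transitions:
  - from: DN
    to: DP_early
    rate: u0_DN + s*(i - 1)
    kind: flow
    reset:
      generation: g1
  - from: DP_early
    to: DP_late
    rate: u0_DP + s*(i - 1)
    kind: flow
    reset:
      generation: g1
      cell_cycle: G0
  - from: DP_late
    to: SP4
    rate: a4
    kind: flow
    reset:
      generation: g1
  - from: DP_late
    to: SP8
    rate: a8
    kind: flow
    reset:
      generation: g1
  - from: DN
    to: EXIT
    rate: Dn
    kind: death
  - from: DP_early
    to: EXIT
    rate: Dp
    kind: death
  - from: DP_late
    to: EXIT
    rate: Dp
    kind: death
  - from: SP4
    to: EXIT
    rate: Ds
    kind: death
  - from: SP8
    to: EXIT
    rate: Ds
    kind: death
  - from: SP4
    to: EXIT
    rate: Us4
    kind: export
    channel: export_SP4
  - from: SP8
    to: EXIT
    rate: Us8
    kind: export
    channel: export_SP8
- name: cell_cycle
  states:
  - G0
  - SM
  initial: G0
  transitions:
  - from: G0
    to: SM
    rate: act
    kind: flow
    guard: differentiation != DP_late
  - from: SM
    to: G0
    rate: Pn
    kind: division
    guard: differentiation == DN
    advance: generation
  - from: SM
    to: G0
    rate: Pp
    kind: division
    guard: differentiation == DP_early
    advance: generation
  - from: SM
    to: G0
    rate: Ps
    kind: division
    guard: differentiation in [SP4, SP8]
    advance: generation
- name: generation
  states:
  - g1
  - g2
  - g3
  - g4
  - g5
  - g6
  initial: g1
  transitions: []
sources:
- into: differentiation == DN and cell_cycle == G0 and generation == g1
  rate: Sn
exclusions:
- differentiation == DN and generation in [g5, g6]
- differentiation == DP_late and generation in [g3, g4, g5, g6]
- differentiation == SP4 and generation in [g3, g4, g5, g6]
- differentiation == SP8 and generation in [g3, g4, g5, g6]
- differentiation == DP_late and cell_cycle == SM
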