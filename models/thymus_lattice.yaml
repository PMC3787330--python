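# 2-D thymus migration/selection model: lattice geometry, epithelial network
# density, TCR/MHC binding kinetics and selection thresholds.
# Threshold values are placeholders (the originally fitted values are not
# shipped); override freely.
name: thymus_lattice
spatial:
  width: 40
  height: 40
  epithelial_fraction: 0.15
  k_on: 5.0         # binding rate to an adjacent epithelial cell (1/time)
  k_off: 1.0        # unbinding rate (1/time)
  noise: 0.2        # probability of a random (non-chemotactic) move
  dt: 0.1
  dn_cortex_dwell: 10.0   # DN -> DP after this much time spent in cortex
  influx_per_step: 1      # new DN agents entering at the subcapsular zone
  thresholds:
    theta_pos_DP: 5       # interactions needed for DP positive selection
    theta_pos_SP: 3       # interactions needed for SP maturation
    t_neglect_DP: 30.0    # DP time limit before death by neglect
    t_neglect_SP: 20.0
    t_neg: 12.0           # cumulative bound-time ceiling -> negative selection
    tau_lineage: 2.0      # longest single interaction >= tau -> CD4, else CD8
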