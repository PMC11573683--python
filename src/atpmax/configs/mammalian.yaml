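# Mammalian (cultured cell) two-pathway energy metabolism.
# Yields are the canonical constants (2 / 24 ATP per glucose); the
# glycolysis-to-respiration ratio of ATP-production specific activity is
# the published 3.1-fold, anchored at a representative respiratory rate of
# 1.8 umol ATP mg pathway^-1 min^-1; phi_total_atp 0.10 is a representative
# ATP-producing proteome share for cultured cell lines.
organism: mammalian
phi_total_atp: 0.10
pathways:
  - name: fermentation
    gamma: 2
    vmax: 2.79            # umol glucose min^-1 (mg pathway protein)^-1
    o2_per_glucose: 0
    byproduct_per_glucose: 2
    byproduct_name: lactate
  - name: respiration
    gamma: 24
    vmax: 0.075
    o2_per_glucose: 6
    byproduct_per_glucose: 0
    byproduct_name: ""
etc_stoichiometry:
  respiration:
    h_per_electron: {CI: 2, CIII: 1, CIV: 2}
    nadh_total: 10
    fadh2_total: 2
    nadh_route: [CI, CIII, CIV]
    fadh2_route: [CIII, CIV]
    nadh_shuttled: 2
    shuttle_cost_h: 1
    leak_fraction: 0.25
    h_per_atp_synthase: 3
    h_per_atp_transport: 1
    substrate_level_atp: 4
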