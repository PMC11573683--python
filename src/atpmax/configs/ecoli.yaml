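# E. coli three-pathway energy metabolism.
# Yields are the canonical stoichiometric constants (2 / 10 / 20 ATP per
# glucose); specific activities anchor respiration's ATP rate at
# 34 umol ATP mg pathway^-1 min^-1 with the published fold-differences
# (fermentation 0.54x, Pta-AckA 2.1x respiration); phi_total_atp is the
# average ATP-producing proteome share (12%).
organism: ecoli
phi_total_atp: 0.12
pathways:
  - name: fermentation
    gamma: 2
    vmax: 9.18            # umol glucose min^-1 (mg pathway protein)^-1
    o2_per_glucose: 0
    byproduct_per_glucose: 2
    byproduct_name: acetate
  - name: pta_acka
    gamma: 10
    vmax: 7.14
    o2_per_glucose: 2
    byproduct_per_glucose: 2
    byproduct_name: acetate
  - name: respiration
    gamma: 20
    vmax: 1.7
    o2_per_glucose: 6
    byproduct_per_glucose: 0
    byproduct_name: ""
etc_stoichiometry:
  respiration:
    h_per_electron: {NDH-I: 2, bo3: 2}
    nadh_total: 10
    fadh2_total: 2
    nadh_route: [NDH-I, bo3]
    fadh2_route: [bo3]
    leak_fraction: 0.25
    h_per_atp_synthase: 4
    h_per_atp_transport: 0
    substrate_level_atp: 4
  pta_acka:
    h_per_electron: {NDH-I: 2, bo3: 2}
    nadh_total: 4
    fadh2_total: 0
    nadh_route: [NDH-I, bo3]
    fadh2_route: []
    leak_fraction: 0.25
    h_per_atp_synthase: 4
    h_per_atp_transport: 0
    substrate_level_atp: 4
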