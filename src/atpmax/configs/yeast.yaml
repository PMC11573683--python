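# S. cerevisiae two-pathway energy metabolism.
# Yields are the canonical constants (2 / 16 ATP per glucose); specific
# activities of ATP production are 7.5 (fermentation) and 4.6 (respiration)
# umol ATP mg pathway^-1 min^-1, consistent with published estimates;
# phi_total_atp 0.15 is a representative ATP-producing proteome share.
organism: yeast
phi_total_atp: 0.15
pathways:
  - name: fermentation
    gamma: 2
    vmax: 3.75            # umol glucose min^-1 (mg pathway protein)^-1
    o2_per_glucose: 0
    byproduct_per_glucose: 2
    byproduct_name: ethanol
  - name: respiration
    gamma: 16
    vmax: 0.2875
    o2_per_glucose: 6
    byproduct_per_glucose: 0
    byproduct_name: ""
etc_stoichiometry:
  respiration:
    h_per_electron: {Ndi1: 0, CIII: 1, CIV: 2}
    nadh_total: 10
    fadh2_total: 2
    nadh_route: [Ndi1, CIII, CIV]
    fadh2_route: [CIII, CIV]
    nadh_shuttled: 2
    shuttle_cost_h: 1
    leak_fraction: 0.25
    h_per_atp_synthase: 3
    h_per_atp_transport: 1
    substrate_level_atp: 4
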