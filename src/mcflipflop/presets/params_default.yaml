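# Reference (calibrated) parameter set for the symmetric consortium.
# Units: concentrations mmol/ml, inputs ug/ml, rates 1/s unless noted.
F_tot: 1.0e-09
K_L: 5.9e-16
K_u: 40.0
beta_c: 3.1622776601683794e-12
cell_density: 5000000.0
d_Z: 0.0007
d_m: 0.0005
d_p: 0.0001
gamma: 3.1622776601683794e-12
hill_in: 2.0
hill_rep: 3.0
input_conc: 192.0
k34: 0.0005623413251903491
k_act: 0.01
k_alpha_deg: 0.134
k_deact: 0.003
k_gfp: 1.0
k_gfp_deg: 0.00215
k_sec: 0.001
k_tl: 0.01
k_tx: 2.0e-12
k_tx0: 1.0e-16
z_scale: 2.4e-11
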