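# Template for transcribing an externally sourced rate-constant table.
# Every key matches a CircuitParams field; delete a line to keep the
# calibrated default. Units: concentrations mmol/ml, external inputs
# ug/ml, rates 1/s unless noted.
gamma: 3.162e-12        # prepro alpha-factor transcription rate, mmol/(ml s)
beta_c: 3.162e-12       # repression constant, mmol/ml
k34: 5.623e-4           # pathway-activated repressor production, 1/s
k_alpha_deg: 0.134      # medium alpha-factor elimination, 1/s
k_gfp_deg: 0.00215      # GFP degradation, 1/s
input_conc: 192.0       # input concentration at logical 1, ug/ml
cell_density: 5.0e+6    # cells/ml
hill_rep: 3.0
hill_in: 2.0
K_u: 40.0               # ug/ml
k_tx: 2.0e-12           # mmol/(ml s)
k_tx0: 1.0e-16          # mmol/(ml s)
k_tl: 1.0e-2
k_sec: 1.0e-3
d_m: 5.0e-4
d_p: 1.0e-4
k_act: 1.0e-2
k_deact: 3.0e-3
K_L: 5.9e-16            # mmol/ml
F_tot: 1.0e-9           # mmol/ml
d_Z: 7.0e-4
z_scale: 2.4e-11        # mmol/ml
k_gfp: 1.0
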