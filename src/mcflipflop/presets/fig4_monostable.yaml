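# Transient-memory regime: high medium clearance.
params:
  k_alpha_deg: 30.0
  input_conc: 192.0
protocol: canonical:3h,12h,x1
lam: 0.4
stability:
  horizon_h: 300.0
out_dir: out/fig4_monostable
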