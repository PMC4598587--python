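# Persistent-memory regime: 30-h protocol plus a 300-h stability scan.
params:
  k_alpha_deg: 0.134
  input_conc: 40.0
protocol: canonical:3h,12h,x1
lam: 0.4
stability:
  horizon_h: 300.0
out_dir: out/fig4_bistable
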