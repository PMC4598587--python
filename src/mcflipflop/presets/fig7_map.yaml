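# Quality map over the molecular control points (gamma, beta_c).
protocol: canonical:3h,12h,x1
lam: 0.4
sweep:
  x: gamma:1.0e-13:5.6234e-12:log:30
  y: beta_c:1.0e-13:7.0795e-10:log:30
out_dir: out/fig7_map
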