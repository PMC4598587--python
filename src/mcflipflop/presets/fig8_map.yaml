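# Quality map over (gamma, k34).
protocol: canonical:3h,12h,x1
lam: 0.4
sweep:
  x: gamma:1.0e-13:5.6234e-12:log:30
  y: k34:1.7783e-6:5.6234e-4:log:30
out_dir: out/fig8_map
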