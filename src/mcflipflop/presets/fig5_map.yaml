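# Quality map over externally tunable knobs: input concentration and
# medium clearance rate.
protocol: canonical:3h,12h,x1
lam: 0.4
sweep:
  x: k_alpha_deg:0.005:500:log:30
  y: input_conc:10:300:lin:30
out_dir: out/fig5_map
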