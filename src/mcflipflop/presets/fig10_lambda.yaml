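# Lambda scan: quality along k_alpha_deg for the full response-vs-memory
# weighting range.
protocol: canonical:3h,12h,x1
lam: 0.4
sweep:
  x: k_alpha_deg:0.005:500:log:30
  lambdas: [0.0, 0.25, 0.5, 0.75, 1.0]
out_dir: out/fig10_lambda
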