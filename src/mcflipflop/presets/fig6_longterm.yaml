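# 138-h long-term run: three write/hold cycles, GFP readout.
params:
  k_alpha_deg: 0.134
  input_conc: 192.0
  k_gfp_deg: 0.00215
protocol: canonical:3h,20h,x3
lam: 0.4
out_dir: out/fig6_longterm
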