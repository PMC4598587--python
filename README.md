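# mcflipflop

ODE simulator of a four-cell yeast consortium that behaves as a set-reset
(SR) flip-flop, together with the bespoke quality statistics used to grade
its digital behavior, stability/memory-time analysis and parameter-sweep
drivers.

Two sender cells respond to the external inputs R and S and secrete two
orthogonal alpha-factor pheromones into a well-mixed medium; two NOT cells
sense one pheromone each and, via a pheromone-pathway-driven repressor,
shut down production of the other pheromone. The resulting cross-repression
loop latches: the readout `Phi(t) = phi_x(t) - phi_y(t)` (difference of the
prepro alpha-factor pools of the two NOT cells) is driven negative by a
(1, 0) write, positive by (0, 1), and holds its sign under (0, 0).

Package layout (one module per concern):

| module          | contents |
|-----------------|----------|
| `circuit_model` | `CircuitParams`, state layout, ODE right-hand side, repressible-promoter kinetics, per-cell overrides for asymmetric circuits |
| `schedule`      | piecewise-constant input protocols (`InputSchedule`, `canonical_sequence`), 7-h pre-equilibration without cell communication |
| `simulate`      | adaptive stiff integration restarted at input breakpoints, `Trajectory`/`PhiSeries`, CSV export |
| `quality`       | real/perfect areas, `S_r`, `S_m`, `Theta_S = lam*S_r + (1-lam)*S_m`, amplitude-weighted `Theta_A`, zero-quality rules, ideal-signal fixtures |
| `stability`     | bistable/monostable classification from multi-initial-condition 300-h runs, memory time, window-boundary bisection |
| `sweeps`        | 1-D/2-D quality maps with sweep-wide amplitude normalizers, lambda scans |
| `cli_io`        | YAML config loading, run manifests, `mcflipflop` CLI |

## CLI

```sh
# 30-h canonical protocol: (1,0) 3 h / (0,0) 12 h / (0,1) 3 h / (0,0) 12 h
mcflipflop simulate --protocol canonical:3h,12h,x1 --out traj.csv --phi-out phi.csv

# score a Phi series (breakpoints in minutes)
mcflipflop score --phi phi.csv --lambda 0.4 --out score.json

# stability classification along a clearance-rate scan
mcflipflop stability --scan-k 0.005:500:log:20 --out report.json

# 2-D quality map
mcflipflop sweep --x k_alpha_deg:0.005:500:log:30 --y input_conc:10:300:lin:30 \
    --lambda 0.4 --out map.csv

# full configured run (simulate + optional sweep/stability)
mcflipflop run --config src/mcflipflop/presets/fig6_longterm.yaml
```

Parameter files are flat YAML with keys matching `CircuitParams` fields;
`src/mcflipflop/presets/params_default.yaml` holds the calibrated reference
set and `params_template.yaml` is a commented template. The presets
directory also ships ready-made configs (`fig4_bistable`, `fig4_monostable`,
`fig5_map`, `fig6_longterm`, `fig7_map`, `fig8_map`, `fig10_lambda`).

## Notes on the model

The reference kinetics are a coarse-grained stand-in for the full
pheromone-pathway model: each sender cell is input-Hill-activated
transcription -> translation -> secretion; each NOT cell is saturable
pathway activation `F`, repressor production at `k34 * F / F_tot`, and
repressible prepro-alpha-factor transcription
`gamma / (1 + (Z / beta_c)^h)`; the medium pools are fed by secretion
scaled with cell density and cleared at `k_alpha_deg`. Auxiliary rate
constants were calibrated so that, at the reference operating point
(input 192 ug/ml), the circuit is bistable at `k_alpha_deg = 0.134 1/s`,
monostable at `30 1/s`, and the bistable window spans roughly
`0.08 .. 8.7 1/s`. All state concentrations are mmol/ml, external inputs
ug/ml, time seconds.
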