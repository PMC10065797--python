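# lgkinetics

Quantification of blood-progenitor proliferation and differentiation
kinetics from long-term live imaging of the *Drosophila* larval lymph
gland (LG).

The LG is the larval hematopoietic organ: its primary lobe holds a niche
(the posterior signaling centre, PSC), JAK-STAT-positive blood progenitors
(marked by dome-MESO-GFP) and differentiated plasmatocytes (marked by
eater-dsRed). Long-term recordings of whole cultured LGs yield per-cell,
two-channel intensity and position tracks; this package turns those tracks
— or synthetic stand-ins with the same statistical structure — into the
quantitative read-outs of hematopoietic kinetics:

* **Differentiation trajectories.** Each track's channels are jointly
  min-max normalized, `Norm.G_t = (G_t − min(G,R)) / (max(G,R) − min(G,R))`
  (same for `R_t`), and the dsRed:GFP ratio is followed over time. Cells
  differentiate along one of two modes: a *sigmoid* trajectory (a slow
  phase, then a rapid switch — the ratio is a rising logistic
  `b + A/(1 + exp(−(t − t₀)/τ))`) or a *linear* trajectory (a constant-rate
  ratio change in cells that already co-express both reporters). The class
  is chosen by corrected-AIC model selection with sanity constraints; the
  differentiation rate is the slope ΔR/ΔT of the ratio — over the 10–90%
  fast phase of the logistic (duration `ln(81)·τ`) for sigmoid cells, over
  the whole track for linear cells.
* **Division kinetics and orientation.** Mitosis duration (breakdown to
  daughter-nuclei reformation plus a 40-frame ≈ 10 min onset offset),
  critical cell size, daughter regrowth, and the division axis classified
  in a cylindrical organ frame: ρ-mitoses radiate from the dorsal–ventral
  axis, z-mitoses run along it; ρ-mitoses carry an angle θ ∈ [0°, 180°) to
  the heart tube, with a Q-Q normality report for orientation bias.
* **Spatial heat maps.** Lobes are rotated/mirrored into a heart-tube-
  aligned frame; event locations are binned into a 5×5 grid over the lobe
  bounding box; per-video maps are summed and compared by Pearson r with
  the category table none/weak/moderate/strong at 0.25/0.5/0.75.
* **Histo-cytometry.** Scale-normalized Laplacian-of-Gaussian nucleus
  detection on two-channel sections (slices at 25/50/75% depth), seeded
  random subsampling, and quadrant gating into
  GFP^high/low × dsRed^high/low populations.
* **FUCCI phase calling.** G1/S/G2/M calls from E2f1-GFP and CycB-RFP
  degron reporters, with population phase proportions over time.
* **Synthetic data.** Every generator is a pure function of (parameters,
  seed) and is calibrated to the reported cohort statistics (mitosis
  duration 57.74 ± 27.58 min, critical size 71.96 ± 10.00 µm², ~90%
  ρ-axis divisions), so every stage is testable without microscopy data.

## Worked example

Simulate one wild-type sigmoid differentiation track, normalize it and
classify its trajectory:

```python
from lgkinetics import synthetic
from lgkinetics.differentiation import classify_trajectory, normalize_dual_channel

model = synthetic.DifferentiationModel.for_kind("sigmoid_wt", noise_cv=0.1)
track = synthetic.simulate_differentiation_track(model, n_frames=1280, seed=42)
fit = classify_trajectory(normalize_dual_channel(track))
print(fit.summary().to_string())
```

```
cell_id           sigmoid_wt_42
class                   sigmoid
b                      0.013881
A                      3.628803
t0                    160.54045
tau                   14.589932
intercept              -0.82291
slope                  0.016536
delta_aicc           1696.77729
rate_per_min           0.045279
fast_start_min       128.483093
fast_end_min         192.597807
resid_sd               0.359275
```

The track is called sigmoid: the fitted logistic switches at t₀ ≈ 161 min
(the generative red-reporter midpoint is 160 min) with timescale
τ ≈ 14.6 min (generative 15 min). The fast phase — the 10–90% amplitude
window — runs from ≈ 128 to ≈ 193 min, and the differentiation rate over
it is ≈ 0.045 ratio units/min. `delta_aicc` ≫ 0 says the logistic model is
overwhelmingly preferred over a straight line for this cell.

The same stages are available from the shell via the `lgk` command
(`lgk simulate | normalize | classify | divisions | heatmap | histocyto |
fucci`); each subcommand takes `--config`, input/output paths and, where
randomness is involved, `--seed`. Exit code 2 signals a validation error.

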