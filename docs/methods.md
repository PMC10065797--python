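# Methods

This note documents the models and procedures implemented in `lgkinetics`,
the choices made where the underlying experimental workflow was manual or
under-specified, and what the synthetic-data tests do and do not establish
about real recordings.

## Track normalization and the dsRed:GFP ratio

Each cell's two reporter channels are min-max normalized **jointly**: one
minimum and one maximum are taken across both markers of that cell's own
time course,

    Norm.G_t = (G_t − min(G,R)) / (max(G,R) − min(G,R))
    Norm.R_t = (R_t − min(G,R)) / (max(G,R) − min(G,R)),

so between-channel differences are preserved and one frame attains 0 and
one attains 1 across the two channels jointly. Normalization is per track
(per cell), which makes all downstream quantities invariant to overall
intensity scale but also means normalized values are not comparable in
absolute units across cells — only shapes and ratios are.

The dsRed:GFP ratio is computed from the **raw** intensities,
`R_t / max(G_t, floor)`, not from the normalized channels. This matters:
for a linear-type cell the joint per-track minimum is the terminal green
value, so a normalized-green denominator would vanish at the end of every
linear track and the ratio would diverge there, destroying the constant-rate
shape that defines the class. The floor is `ratio_floor × max(G,R)`
(default `ratio_floor = 0.01`), expressed relative to the track's joint
maximum so the ratio remains scale-invariant; frames where the floor
engaged are flagged and counted against the 80%-usable-frames requirement
of the classifier. Intensities are used as exported (mean grey values);
no background subtraction or smoothing is applied by default (an optional
moving-average window exists, off by default).

## Trajectory classification

Differentiating progenitors follow one of two modes: **sigmoid** (high
green / low red start; a slow phase, then a rapid switch in the ratio) or
**linear** (both reporters already expressed; constant-rate ratio change).
In the original manual workflow the ratio-curve shape was categorized by eye. The
package operationalizes this as model selection between

* a 4-parameter logistic `b + A / (1 + exp(−(t − t₀)/τ))`, and
* a straight line `a + s·t`,

both least-squares fitted to ratio vs time, compared by corrected AIC
(Gaussian likelihood; k = 5 vs 3 parameters counting the error variance)
with an ambiguity margin (default 2).

A sigmoid call additionally requires the fitted switch to be *observed*:

* the 10–90% fast phase `t₀ ± τ·ln 9` must lie inside the recorded window,
* it must be resolved by at least 3 frames,
* the amplitude must rise (`A > 0`) and exceed twice the residual SD.

These admissibility constraints are what make the margin workable. With
~10³ frames per track, the logistic's two extra parameters absorb
about χ²(2) of pure noise, so for a genuinely linear track the AICc
difference lands within the ambiguity margin roughly a third of the time;
the spurious "logistic" in those cases is a near-line with a huge τ whose
crossings extrapolate far outside the window, or a single-frame step.
Rejecting inadmissible logistics outright (class = linear) removes both
failure modes without touching the margin. A consequence is that a true
switch occurring at the very edge of a recording is classified linear —
the conservative choice. A non-convergent logistic fit also falls back to
linear, with a warning.

The fit is deterministic: Levenberg–Marquardt from data-derived initial
values (baseline = min, amplitude = range, midpoint = first half-amplitude
crossing) with two fixed timescale starts, best RSS kept; a negative-τ
solution is flipped to its equivalent τ > 0 parameterization.

## Differentiation rate and fast phase

The rate is the slope ΔR/ΔT of the ratio. For linear cells it is the
ordinary least-squares slope over the whole track. For sigmoid cells it is
the **secant** slope of the fitted logistic across the fast phase — the
window between the `b + 0.1·A` and `b + 0.9·A` crossings, whose duration
is exactly `ln(81)·τ` — giving `0.8·A/(ln 81·τ)` when unclipped. The
secant, not the OLS slope over the window, is used deliberately: the OLS
slope of a logistic over its own 10–90% window is ~13% steeper than the
average rise, whereas the secant is the change-over-time quantity the rate
is defined as. Fast-phase crossings outside the observed window are clipped
to it with a warning, and the secant is then evaluated at the clipped
bounds.

## Division kinetics and orientation

* **Duration** = (t_complete − t_breakdown) + onset offset. The onset
  offset (default 40 frames at 15 s = 10 min) encodes the convention that
  mitosis begins ~10 min before the visible nuclear-envelope breakdown; it
  is configuration, so durations are reproducible from the two annotated
  times alone.
* **Axis class.** The division axis (unit vector daughter1 → daughter2) is
  compared with the dorsal–ventral axis: α = arccos(|axis·ẑ|). α ≤ 45°
  (boundary inclusive) is a z-mitosis, otherwise ρ-mitosis. The 45° cone is
  a symmetric operationalization of a visual classification; the threshold
  is exposed in the run configuration.
* **Orientation θ.** The axis is projected onto the ρ–ϕ plane and θ is the
  unsigned angle |φ| ∈ [0°, 180°) between the directed projection and the
  heart-tube direction, with φ = ±180° mapped to 0°. Relabelling the
  daughters maps θ → 180° − θ (mod 180°); which daughter anchors the ray is
  taken from the input ordering and documented rather than guessed.
  Axes within 10⁻⁶ of vertical have no in-plane direction and are an error.
* **Q-Q normality report.** Sample orientation quantiles are paired with
  N(mean, sd) quantiles at Blom-type plotting positions; the reference line
  passes through the first/third-quartile pairs and linearity is summarized
  as r², the squared Pearson correlation of the quantile pairs. Under a
  true normal at n = 50, r² < 0.95 occurs in under 5% of runs (pinned by
  simulation in the test suite); bimodal orientation samples fall well
  below.
* **Critical size.** Mother area 10 min pre-mitosis; combined daughter area
  at the frame nearest +3 h; per-daughter growth fraction
  (area(4 h) − area(0))/area(0). Missing daughter series yield explicit
  absent fields rather than errors.
* **Distances** are perpendicular point-to-line distance to the tube axis
  and Euclidean distance to the posterior end (the niche landmark);
  **mitotic index** is the exact pH3⁺dome⁺ / dome⁺ ratio.

## Spatial heat maps

Alignment applies the smallest-magnitude rotation taking the heart-tube
direction onto the y-axis (about the tube point), then mirrors about the
tube line if the lobe centroid lies to its left, so all lobes face right.
The transform is recorded and invertible. The aligned lobe boundary's
bounding box is divided into grid_n × grid_n cells (default 5 × 5, i.e.
20% of width/height each); bins are half-open with the last bin closed,
row 0 nearest the heart tube. Events outside the boundary polygon are
excluded *and counted*; `binned + excluded = input` is asserted on every
map, so no event is silently dropped. Maps combine by raw element-wise
summation (no per-video normalization), and two maps are compared by
Pearson r of the flattened counts with categories none/weak/moderate/strong
at 0.25/0.5/0.75 (boundaries upward; negative r is reported raw and
categorized as none — the sign is never hidden).

## Histo-cytometry

Sections at 25/50/75% of stack depth are selected as
`round(q·(n_slices − 1))` half-up; the smallest stack with three distinct
indices is 5 slices. Detection runs scale-normalized Laplacian-of-Gaussian
filtering (σ = diameter/(2√2), default diameter 13 px) on the channel sum,
so dim-green/bright-red nuclei are not missed, followed by local-maximum
extraction with minimum separation diameter/2. The response is
unit-normalized: an ideal isotropic Gaussian blob of matched σ and unit
peak scores exactly 1 (the −2σ²·LoG of a matched Gaussian at its centre is
1/2, hence the factor 2). The tracking software's raw "quality 2.5" is not
portable across implementations; the unit-normalized threshold (default
0.2) is, and the non-equivalence is deliberate. Per-cell intensities are
disc means of radius diameter/2 per channel. Subsampling is a seeded
shuffle-and-take (uniform without replacement, randomized order). Quadrant
gates default to per-channel Otsu thresholds on log₁₀ intensity pooled
across the conditions being compared — reproducible and
condition-symmetric — and can be overridden by fixed values.

## FUCCI phase calling

A channel is "present" in a frame when its intensity reaches
`presence_fraction` (default 0.2) of that channel's per-trace maximum —
relative, because absolute FUCCI intensity scales vary per cell. Green-only
frames are G1, red-only S, both-present G2. Both reporters drop during
mitosis (nuclear-envelope breakdown), so a both-absent run is called M only
when flanked by a both-present (G2-like) run before and a green-only
(G1-like) run after; otherwise it is unknown. Runs shorter than
`min_run_frames` (default 4, i.e. 1 min at 15 s frames) are merged into the
longer neighbour before the M decision, enforcing temporal coherence. The
per-trace-relative threshold is degenerate for a channel that is never
expressed but fluctuates around a low value: its own maximum then defines
"presence". Truly absent channels should read ~0; this is a documented
limitation of relative thresholding. Population phase proportions at a
query time are taken over called (non-unknown) cells at the nearest frame
and sum to 1.

## Synthetic-data generator

All generators are pure functions of (parameters, seed) with one explicit
RNG stream per call.

**Differentiation tracks.** Sigmoid kinds: green falls as a logistic
(midpoint 100 min, timescale 12 min from G0 = 100 to G1 = 25 a.u.) and red
rises as a delayed logistic (delay 60 min; R0 = 2 to R1 = 90; timescale
τ = 15 min wild type). The infected sigmoid variant inserts a 120-min
low/low intermediary plateau before the red rise and switches more slowly
(τ = 25 min), so its fast phase starts later and its rate is lower. Linear
kinds start with red already high (R0 = 60 ≥ 0.5·G0): red reaches its
plateau within the first ~20 min (at 1.5× the wild-type plateau for the
infected variant, encoding the ~50% higher final dsRed:GFP ratio) and green
declines as the reciprocal of a linear ramp, so the dsRed:GFP ratio changes
at an exactly constant rate — the defining property of the class. A
straight-line green with constant red would give a hyperbolic, not linear,
ratio; the ratio, not the green curve, is what the class is defined by.
Track lengths default to the recorded spans (~320 min sigmoid, ~440 min
infected sigmoid, ~560 min linear, at 15 s frames). Noise is multiplicative
Gaussian, `x·(1 + N(0, cv²))` clipped at 0, approximating the
heteroscedastic look of fluorescence traces; the default cv = 0.1 is a
choice (no SNR was reported for the recordings) and is flagged in the
config docs.

**Division cohorts.** Durations and pre-mitotic mother areas are drawn from
left-truncated normals whose parent parameters are solved (moment matching)
so the *realized* mean and SD equal the stated values — naive truncation of
N(57.74, 27.58²) at the bound would inflate the mean by ~1.2 min and
shrink the SD by ~1.4 min, de-calibrating the cohort. The truncation bound
is the 10-min onset offset, below which a total duration is unrepresentable
(completion would precede breakdown). Defaults: duration 57.74 ± 27.58 min
(optional per-class means 53.90 ρ / 75.04 z), area 71.96 ± 10.00 µm²,
ρ-axis probability 0.9, ρ-orientations from a truncated normal
(90° ± 30° on [0°, 180°)), small off-plane/off-axis tilts (|N(0, 10°)|
clipped at 30°), positions uniform in the lobe polygon with z within the
dorsal–ventral half-thickness, symmetric daughters growing 20–30% over 4 h.

**Images** are sums of isotropic Gaussian spots with given peak intensities
plus additive Gaussian background noise clipped at 0 — no PSF model, no
photobleaching (none was observed in the recordings this emulates).
**FUCCI traces** follow an explicit (phase, duration) plan with per-phase
channel levels (green 100/red 5 in G1, 5/100 in S, 100/100 in G2, 5/5
in M).

What passing tests show — and don't. The generator reproduces the
*statistical structure* the analysis assumes: calibrated moments, known
labels, known blob positions, known phase plans. It does not emulate
segmentation/tracking errors, cell movement, overlapping nuclei, uneven
illumination, or photobleaching, so test performance (e.g. 100% classifier
agreement at cv = 0.1, detector recall 1.0 on separated blobs) bounds what
clean data allow and does not certify performance on degraded recordings.

## Problem sizes and numerical choices

Monte-Carlo suites use n = 10 000 division events (duration mean within
1 min, ρ fraction within its binomial interval), 500 tracks per trajectory
kind at cv = 0.1 for classifier agreement, 1 000 random tracks for the
normalization-formula check, 400 pure-noise tracks for classifier
specificity, and 200 blobs for detector recall/precision — sizes at which
the checked tolerances are several standard errors wide. Logistic fits cap
at 5 000 function evaluations; AICc uses the small-sample correction;
track CSVs round-trip bit-exactly (`%.17g` out, round-trip parsing in).
Seeds are explicit everywhere; identical inputs give identical outputs.

## Known limitations

* Tracks are consumed, not produced: cell tracking itself (and manual
  annotations such as breakdown/completion frames and daughter centroids)
  is upstream of this package, as it was in the original workflow.
* The sigmoid/linear decision is conservative near the edges of a
  recording; switches not fully observed are classified linear.
* Quadrant gates and the ρ/z cone are operationalizations of visual
  judgements; both are exposed in the run configuration rather than fixed.
* Histo-cytometry count bookkeeping is asserted internally
  (quadrant counts sum to the gated records); externally reported tables that
  are internally inconsistent cannot be — and are not — reproduced.
* No 3D segmentation, kernel-smoothed maps, hierarchical multi-cell fits,
  or crystal-cell lineage calls.
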