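# Methods

This note documents the models, conventions and numerical choices behind
`nprrquant`, in the order data flows through the package.

## Trace model (synthetic reporter recordings)

No quantitative model of dense-core-vesicle (DCV) release at the NMJ is
established, so the generator is deliberately minimal: the simplest
mechanism that produces all three published phases of the reporter response.
Per ROI, with a normalized releasable pool *P* (P(0)=1), released-signal *R*
and cumulative unreplenished release *D*:

```
drive(t) = sigmoid((f − f_thr)·k) · g_trial          while a trial is on
dP/dt = −r_dep · drive · P                            during stimulation
dP/dt = (1 − P) / τ_rep                               otherwise
dR/dt = g_rel · f · drive · P − R / τ_clr
dD/dt = release flux − replenish flux                 (so D ≡ 1 − P)
ΔF/F  = R − u·D + ε,  ε ~ N(0, σ²) i.i.d. per frame and ROI
F     = F₀ · (1 + ΔF/F), clipped at 0
```

Interpretation: stimulation releases the pool at a rate proportional to the
frequency-dependent drive; released reporter fluoresces, then is cleared by
diffusion out of the imaged region (τ_clr); the pool replenishes slowly from
axonal transport (τ_rep); the depleted, not-yet-replenished fraction *D*
depresses fluorescence below baseline — the undershoot. The model is
phenomenological and descriptive, not mechanistic.

### Defaults (chosen once, as the emulated study conditions)

| parameter | symbol | default | unit | rationale |
|---|---|---|---|---|
| baseline fluorescence | F₀ | 100 | a.u. | arbitrary scale |
| release gain | g_rel | 0.01 | ΔF/F per Hz | ≈1 ΔF/F peak at 70 Hz |
| pool depletion rate | r_dep | 0.12 | 1/s | pool largely spent within an 18 s trial, so the falling phase starts before offset |
| pool replenish τ | τ_rep | 12 | s | undershoot decays to within ~1% of baseline across a ~40 s interval |
| signal clearance τ | τ_clr | 2 | s | peak latency of ~3 s at 70 Hz, inside the reported 0.5–5 s window |
| undershoot coupling | u | 0.3 | ΔF/F per pool unit | undershoot ~25–30% of peak |
| frequency threshold / slope | f_thr, k | 45 Hz, 0.15/Hz | — | "Type III" mode: responses below 30 Hz are small; a "Type Ib" preset (15 Hz) responds from 10–20 Hz |
| noise sd | σ | 0.02 | ΔF/F | typical frame-to-frame noise of averaged ROIs |
| ROIs per set | — | 8 | — | typical preparation count per condition |

Per-trial gain schedules are *descriptive*: a uniform default, plus presets
for the two published patterns (first peak lowest; progressive decline).
They model the observed trial-to-trial modulation without asserting a
mechanism.

Two edge conventions deserve note:

* **Release block.** Zero release gain means no fusion; physically, nothing
  is then released, so the pool neither depletes nor leaves an undershoot.
  The generator short-circuits to a flat trace (plus noise) rather than
  integrating a pool that could never have fused.
* **Integration.** Classical RK4 on a fixed grid of 10 sub-steps per frame,
  with the whole sub-step classified as stimulated or not by its midpoint —
  the drive is piecewise-constant, and letting RK4 stages straddle a trial
  boundary degrades the scheme to first order exactly where the trace turns.
  With midpoint classification the frame-time solution agrees with a
  100×-finer integration to ~5·10⁻⁸ relative; the tests require 1%.

The calcium-control ("GCaMP") mode is closed-form per trial: saturating rise
(τ = 0.3 s, effectively instantaneous at 1 frame/s), mild adaptation toward
a 90% plateau (τ = 5 s), exponential decay after offset with τ_clr, never
negative. Its amplitude uses the same gain × frequency × drive scale so the
two modes are comparable.

What the generator does **not** emulate: photobleaching, motion/contraction
artifacts, slow baseline drift, spatial structure within ROIs, correlated
noise across ROIs, and saturation of the indicator. Tests passing on these
traces therefore validate the *estimators* under clean, known kinetics; they
do not certify performance on drifting or motion-contaminated recordings.

## ΔF/F conventions

* Baseline window: recording start to 2 s before the first trial onset
  (a baseline span is always marked before the first burst; its exact length
  is a free choice, and the 2 s guard keeps stimulus-onset frames out).
  The baseline statistic is the **mean** (a median variant would differ only
  under artifacts the generator does not produce).
* Per-trial "corrected" variant: each trial is re-expressed relative to the
  mean ΔF/F of its own 5 s pre-onset span. Implemented as *subtraction*, not
  division — after an undershoot the pre-trial mean is near 0, where a
  quotient is unstable — matching the "peak height above pre-stimulation
  baseline" reading. The shift applies from the start of the trial's
  pre-span to the start of the next trial's pre-span, so all pre-trial means
  are exactly 0 afterwards and the operation is idempotent.
* Aggregation is the per-frame mean with s.e.m. = sd(n−1)/√n; a single-ROI
  set reports s.e.m. 0 with a warning instead of failing.
* Screening rule: a candidate passes at fold = signal/reference ≥ 2.

## Release metrics

* Peaks are searched over [onset, offset] only (in-stimulation peaks);
  post-offset maxima are ignored. Ties resolve to the earliest frame.
* Integrals are trapezoids over actual frame times, with values interpolated
  at the window boundaries so constant and piecewise-linear traces integrate
  exactly; both raw (ΔF/F·s) and per-second variants are emitted since
  published integral units are often left arbitrary.
* Phase segmentation runs on a 3-frame centered moving average. Falling
  onset = first post-peak time from which the smoothed trace declines for
  ≥2 consecutive frames; undershoot = maximal contiguous ISI span below
  −ε (default ε = 0.01 ΔF/F, a small fraction of typical peak amplitude);
  recovery = re-entry into [−ε, ε] before the next onset. Flat trials are
  flagged undefined, not raised.
* Frequency responses are reported as 100·peak/peak(70 Hz). Note that a
  peak statistic carries a positive noise bias (a maximum over frames), so
  with many preparations even sub-threshold frequencies can formally reject
  "= 0"; the magnitude column, not the star, carries the information there.
* Bouton/inter-bouton ratio: frame-wise ratio of class means over trial
  windows, excluding frames where the denominator < 0.01 ΔF/F (near-zero
  denominators explode the quotient); the excluded fraction is always
  reported, and a fully-excluded trial yields an undefined flag, not a
  number. Floor and ε are configurable.

## Stereology

Compartments are assigned per gold particle with priority
**DCV > membrane > cytoplasm > outside**: within 50 nm of a DCV center;
within 20 nm of the outline on *either* side (sidedness is not specified in
the field convention "within 20 nm of the membrane", so the band is
symmetric, area = perimeter × 40 nm with curvature ignored at these scales);
inside the polygon; else outside. DCV wins overlaps because DCV-proximal
gold is its own category in the counting protocol. Counts always partition
the total.

Areas: DCV = n·πr²; cytoplasm = bouton − DCV − band; outside = image −
bouton − outer half-band. The bouton area is a grid-intersection estimate:
points at grid-cell *centers* (origin + (i+½)·spacing), count × spacing².
Center-anchoring makes each point represent exactly one cell, so
grid-aligned rectangles are estimated exactly and the estimate converges to
the true polygon area as spacing shrinks; spacing defaults to 50 nm and an
exact-polygon-area mode exists for comparison.

The headline DCV/bouton ratio divides pooled DCV density by pooled cytoplasm
density. Because published tables rarely state the averaging scheme, the
report also emits the per-image-mean ratio (upward-biased at low counts) and
a variant whose cytoplasm denominator does not subtract DCV/band area, so an
external table can be matched to whichever convention produced it.
Background density = total control gold / total control area, compared to a
0.6 gold/µm² ceiling. An optional aggregate filter collapses clusters
(≥4 neighbors within 15 nm) to centroids; off by default.

The synthetic micrograph draws per-compartment Poisson counts using the
*same* area formulas as the estimators, with positions uniform in each
geometric region, so density recovery is unbiased by construction; the
bouton is a convex blob (radius-perturbed 16-gon scaled to an exact target
area), DCV centers are rejection-sampled with pairwise distance ≥ 2r and a
bounded retry budget (a capacity error otherwise).

## Statistics

Mann–Whitney U uses midranks; p is exact — full enumeration of all
C(n_a+n_b, n_a) rank arrangements — whenever both groups have ≤ 8
observations and the pooled sample is tie-free, else a normal approximation
with tie correction and 0.5 continuity correction. Two-sided exact p is the
symmetric two-tail mass. The one-sample t is standard (df = n−1), with a
zero-variance sample rejected as degenerate. Sidedness defaults to
two-sided and is recorded in every result; no multiple-testing correction
is applied (per-comparison stars: \*, \*\*, \*\*\*, \*\*\*\* at 0.05, 0.01,
0.001, 0.0001).

Calibration: the null rejection rate of the t test is exact at any n; the
rank test is *conservative* at small n (discrete statistic plus continuity
correction — measured ≈0.043 at α=0.05 with 12–25 per group), which is
correct behavior, so the 10,000-replicate type-I-error check runs at n = 40
per group where both effects are negligible.

## Known limitations

* The trace model's falling phase begins shortly after the peak (~3 s into
  a trial), earlier than the published 1–5 s pre-offset lead; only the sign
  of the lead is treated as a constraint. A plateau term could match the
  timing at the cost of two more free parameters.
* The per-image-mean density ratio is biased upward when per-image counts
  are small; prefer the pooled ratio.
* The membrane band area formula ignores curvature and corner effects;
  for 20 nm bands on µm-scale outlines the error is ≪1%.
* Exact Mann–Whitney enumeration grows combinatorially; above 8 per group
  the implementation switches to the corrected normal approximation rather
  than attempting network/shift algorithms.
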