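# Methods

## The measurement being modeled

A single pancreatic islet is held at a channel constriction under continuous
perfusion and imaged label-free once per minute; granule-dense β-cells
backscatter strongly, so the image carries a bright-patch signature of the
insulin store. Stimulus switches (low → high glucose, then KCl
depolarization) trigger exocytosis, depleting granules and producing abrupt
decreases in patch intensity, while the downstream perfusate is collected in
5-minute fractions for insulin quantification. `isletscope` implements the
computational half of that experiment: motion stabilization, the normalized
intensity readout, step detection, and a ground-truth phantom generator for
validating all of it.

## Stabilization

**Model.** Perfusion-induced motion is treated as pure in-plane translation;
rotation and deformation are out of scope. Shifts are estimated
*sequentially* (each frame against its immediate predecessor) rather than
all-to-reference: consecutive frames are most similar, at the cost of a
random-walk accumulation of per-step errors, which the tests quantify
directly (see below).

**Estimator.** Phase correlation — the peak of the inverse-transformed
normalized cross-power spectrum — with subpixel refinement by local Fourier
upsampling (default `upsample=10`, i.e. 0.1 px precision; delegated to
`skimage.registration.phase_cross_correlation` with `normalization="phase"`).
On noiseless integer-rolled images the correlation peak is exact, giving
zero-error recovery at `upsample=1`. An optional Hann window suppresses edge
leakage for stacks with strong content at the border; it is off by default
because the islet sits well inside the field.

**Sign and geometry conventions.** `ShiftSeries.cumulative[t]` is the
*content displacement* of frame `t` relative to frame 0 (dy positive
downward, dx positive rightward, origin top-left, row-major); stabilization
undoes it, so a stabilized pixel `(r, c)` of frame `t` pulls from raw
position `(r + dy_t, c + dx_t)`. Integer shifts are applied by pure index
moves (bit-exact); fractional shifts use bilinear interpolation — bounded
support that cannot ring into the zero-filled border. Out-of-view pixels are
exactly 0.

**Crop window.** The stabilized stack is cropped to the maximal axis-aligned
rectangle valid in *every* frame. A pixel is valid when its source position,
including the full bilinear support for fractional shifts, lies inside the
raw frame; ceil/floor are chosen so no partially interpolated border pixel
is admitted. The tests check this against a brute-force oracle (shift a
ones-image per frame, intersect near-unity pixels) including one-pixel
tightness on every binding side.

**Accuracy.** On the standard drift benchmark (64 frames, 256 × 256,
random-walk drift σ = 1 px/frame, default detector noise) cumulative-shift
RMSE stays below 0.5 px in every seeded replicate (typically ~0.1–0.35 px).
Because sequential errors accumulate as a random walk, re-stabilizing a
stabilized stack finds near-zero *per-step* residuals (≤ 0.25 px) but cannot
remove the first pass's accumulated residual; idempotence is therefore
stated per step.

## Normalized readout

`values[t] = mean(frame_t) / mean(frame_t[background ROI])`, computed on the
cropped stabilized stack so zero-filled pixels never enter either mean. The
whole-frame mean *includes* the ROI pixels (recorded in the trace
provenance); the ratio cancels any per-frame multiplicative gain exactly, up
to float rounding, and that is the entire photometric correction — no
detrending or bleaching model is applied. The ROI is fixed in reference
coordinates for all frames; polygon ROIs are rasterized with a
boundary-inclusive pixel-centers-inside rule. Frame indices are the
canonical time axis; minutes are derived metadata via the frame interval.

## Step detection

The trace is smoothed by a centered 3-frame moving average (edges use the
shrinking window so the series keeps full length). The event metric at frame
`t` is `mean(s[t−pre..t−1]) − mean(s[t+1..t+post])` with `pre = post = 3`;
frame `t` belongs to neither window. Decreases give positive values. Edge
frames lacking a full window — plus the `(smooth−1)/2` frames whose smoothed
value used a shrunken edge window — are invalid (NaN, exported as empty
cells), deliberately *not* computed with shrunken windows, which would
change the metric's scale near the edges.

**Calibration.** With the symmetric-exclusion convention the response to an
ideal step of height Δ is exactly Δ unsmoothed and (8/9)·Δ after 3-frame
smoothing. `step_attenuation(smooth, pre, post)` computes this factor for
any window combination by running the actual smoother and metric on a unit
step, and `DetectedEvent.step_size = amplitude / attenuation` is the
calibrated estimate of the underlying trace step. Without this correction
the known 11% attenuation consumes most of any reasonable amplitude-accuracy
budget; with it, detected step sizes on the noisy-trace benchmark fall
within 20% of truth in ≥ 95% of replicates.

**Peak picking.** Local maxima of the valid metric (plateaus included) are
accepted greedily in descending amplitude under a minimum separation
(default `pre + post` = 6 frames), ties broken toward the earlier frame.
With a stimulation protocol supplied, `top_k` defaults to the number of
stimulus switches; otherwise a threshold of 3 × the median absolute
deviation of the valid metric applies. Peaks below 1 × 10⁻¹² — double-
precision rounding noise for an O(1) ratio metric — are never reported. An
ideal instantaneous step yields a two-frame plateau (the windows flank the
step at both `k−1` and `k`), so onsets are localized to within about one
frame of the true transition; protocol matching therefore attributes an
event to a phase boundary within 3 frames of its onset, falling back to the
containing phase.

**Display scaling.** For visual comparison the metric is min-subtracted and
divided by the post-shift maximum, mapping valid values onto [0, 1]. The
min-subtraction reading is used even when the minimum is positive (literal
addition of |min| would not reach [0, 1]); this choice is recorded here and
in the output provenance.

## Synthetic phantom generator

The generator emulates what the analysis consumes, not the optics:

- **Scene** — a disk-shaped islet (default radius 180 px in a 512 × 512
  frame ≈ a 100 µm islet at 0.28 µm/px; benchmarks use a 256 × 256 frame
  with radius 80) of base intensity 300 over background 60, carrying
  granule-rich patches whose intensity is `islet_base × gain` (gains
  2.5–4). A frozen multiplicative log-normal speckle (band-limited white
  noise, correlation length `texture_grain` = 3 px, fractional contrast
  0.35) textures the islet so registration has stable features —
  backscatter contrast is quasi-static between frames.
- **Drift** — a Gaussian random walk (default σ = 1 px/frame) or an explicit
  path. Each frame is produced by a *single* bilinear shift of the master
  scene, so true shifts are exact by construction; scene generation fails
  with the first offending frame named if the islet ever leaves the frame.
- **Depletion** — each scheduled event multiplies the currently retained
  granule-excess fraction by `1 − relative_drop`, ramping linearly over
  `transition_frames` (1 = instantaneous). Release per frame is proportional
  to that frame's drop in total excess intensity and is summed into
  consecutive bins (default 5 minutes of frames; trailing partial bin
  flagged). Total effluent equals total release exactly.
- **Noise** — gain multiplies the clean signal (per-frame log-normal, mean
  1, σ = 1%), Poisson sampling follows (`photon_scale` = 2 counts per
  intensity unit, ≈ 4% shot noise at islet intensity), additive Gaussian
  read noise (σ = 2 units) comes last, and values clip at 0 — the standard
  detector ordering.
- **Seeding** — one top-level seed fans out through `SeedSequence.spawn`
  into independent texture/drift/noise streams, so components vary
  independently and identical configurations reproduce stacks bit for bit.

What the phantom does **not** emulate: point-spread function, confocal
sectioning, wavelength dependence, cell-scale morphology changes,
out-of-plane motion, or multiple islets. Passing tests therefore demonstrate
correctness of the *pipeline arithmetic* under realistic drift/noise/step
magnitudes — not robustness to optical artifacts absent from the model.

## Benchmarks and problem sizes

The standard conditions, fixed in `isletscope.benchmark`:

- *Drift benchmark*: 64 frames, 256 × 256, random-walk σ = 1 px/frame,
  default noise; 20 seeded replicates for the RMSE bound.
- *GSIS benchmark*: 75 frames at one frame per minute covering the standard
  protocol (low glucose 15 min, high glucose 30 min, low glucose 15 min,
  KCl 15 min), with 10% and 15% depletion steps at the high-glucose and KCl
  onsets (frames 15 and 60) — as an image stack (drift σ = 0.5 px/frame)
  and as a directly synthesized trace with 1% baseline noise (200 seeded
  replicates for the localization statistics).

The magnitude of the synthetic intensity drops is a free parameter of the
generator (the phenomenon's published traces are graphical); 10–15% was
chosen once as a plausible moderate depletion and is part of the fixed
benchmark definition.

## Numerical choices and degenerate inputs

- Shifts within 10⁻⁹ of an integer are snapped, keeping the bit-exact
  integer path and stable ceil/floor crop arithmetic.
- Constant frames make correlation undefined and raise immediately, as do
  empty masks, zero background means (the offending frame is named),
  all-equal metrics in display rescaling, and protocols with non-positive
  durations.
- CSV floats are written with a fixed `%.12g` format so identically seeded
  pipeline runs are byte-identical.
- Double interpolation (one bilinear pass at phantom rendering, one at
  resampling) smooths the islet's sharp edge twice; fractional-shift
  recovery is therefore validated in RMS (< 3% of dynamic range) rather
  than by a max-abs bound, and exactly for integer shifts.

## Known limitations

- Sequential registration accumulates error ∝ √n_frames; very long
  acquisitions may warrant periodic re-anchoring, which is not implemented.
- The whole-frame readout mixes all cells; no per-cell or per-region traces.
- The windowed detector is scale-calibrated only for steps well separated
  relative to `pre + post`; overlapping events within ~6 frames merge.
- Amplitudes are dimensionless ratio changes; no conversion to insulin mass
  is attempted.
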