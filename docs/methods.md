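# Methods

## Signal model and assumptions

The pipeline assumes each pixel's raw series is a non-negative
intensity trace sampled uniformly (default 0.58 s/frame, 12-bit counts)
containing at most one first-pass bolus peak possibly followed by
recirculation peaks, on an approximately constant pre-arrival baseline.
It is model-free: no functional form is fitted to the data.  The
analysis is purely per pixel — no spatial smoothing or coupling — so a
map is exactly the per-trace analysis broadcast over the grid.

Processing order per pixel:

1. restrict to the analysis window (first `analysis.n_frames` frames,
   default 40 ≈ 23.2 s);
2. Savitzky–Golay smoothing on the native frame grid
   (`smoothing.window` 7 frames, `smoothing.order` 3);
3. natural cubic-spline resampling to `interpolation.dt` (11.6 ms);
4. half-intensity anchor: T_half = first time the intensity ≥ median of
   the window (even-length windows: mean of the two central order
   statistics);
5. backward trace to T_arrival: step to earlier samples while each is
   *strictly* lower; any tie or rise terminates the trace.  Forward
   trace to the first peak T_peak symmetrically.  Plateaus therefore
   terminate tracing; exact ties are rare after smoothing and
   interpolation;
6. T_rising = T_peak − T_arrival, BFI = (I_peak − I_arrival)/T_rising;
7. baseline = mean intensity before T_arrival (≥ 3 samples, else the
   trace minimum with a warning); MTT = center of gravity of the
   baseline-zeroed trace over τ ∈ [0, `mtt.window_s` = 20 s] after
   arrival, by trapezoidal quadrature on the interpolated grid.  τ is
   time *since arrival*; the alternative absolute-time reading was
   rejected because transit time is meaningful only relative to bolus
   arrival.  When the acquisition ends before the full window (a late
   arrival inside a 23.2 s acquisition), the window is clipped with a
   warning rather than failing the pixel.

Failures (flat trace, truncated peak, non-positive integral mass, zero
rise) yield an invalid record with a reason code, never an exception on
a QC-passed pixel; invalid pixels hold NaN in the float maps.

## Parameters

| key | default | unit | meaning |
| --- | --- | --- | --- |
| acquisition.frame_interval | 0.58 | s | time between frames |
| acquisition.pixel_size | — | mm/px | needed only for ROI geometry |
| analysis.n_frames | 40 | frames | map-generation window |
| smoothing.window | 7 | frames | SG window (odd, > order) |
| smoothing.order | 3 | — | SG polynomial order |
| interpolation.dt | 0.0116 | s | interpolated resolution |
| mtt.window_s | 20.0 | s | post-arrival integration window |
| qc.snr_threshold | 5.0 | — | amplitude / noise-σ cutoff |

The smoothing window length is not dictated by the acquisition
protocol; 7 frames (≈ 4.1 s) suppresses CCD noise while staying below
twice the ≈ 2.7 s cortical rise so the first peak is not flattened.
Both it and the spline boundary condition (natural: zero second
derivative, since no end-derivative information exists) are
configuration choices, not physical constants.

## Numerical choices

* Savitzky–Golay is applied as a precomputed n×n matrix (one matmul
  smooths a whole stack).  Near the edges the window shrinks
  symmetrically while ≥ order+2 points remain; the first/last points
  use an asymmetric fit over the nearest order+2 samples.  This avoids
  padding artifacts in the early frames that contain the bolus foot.
* Frame k is at t = k × frame_interval with t = 0 at the first frame.
  Pixel coordinates are (row, col), row 0 at the image top.
* Flatness is detected with a relative tolerance
  (peak-to-peak ≤ 1e-9 × scale), so float fuzz introduced by smoothing
  a constant trace still registers as flat.
* Display scaling maps [lo, hi] linearly to gray 0–255 with clipping;
  the automatic range is the 1st–99th percentile of valid pixels so
  single hot pixels do not crush contrast.  Masked pixels render as
  gray 0 and the sidecar records the range and sentinel.  BFI maps are
  divided by their valid-pixel maximum for display only, never for
  analysis.
* ROI footprints: a size of s mm at p mm/px spans ⌈s/p⌉ pixels;
  half-pixel placement ties are rounded away from bregma.  Mirroring
  reflects column c to 2·midline − c (an exact involution).  The
  unpaired hemisphere test is the classical pooled-variance Student
  t-test (Welch behind a flag); degenerate zero-variance inputs resolve
  to t = 0, p = 1 (equal constants) or p = 0 with a flag.

## Quality-control mask

A pixel receives parameters only if its smoothed bolus amplitude —
max minus median over the frames where the full smoothing window
applies — is at least `qc.snr_threshold` × a robust noise σ.  The σ is
1.4826 × MAD of the raw-minus-smoothed residuals, divided by the
filter's residual attenuation factor √(1 − 2S_mm + Σ_j S_mj²) so it
estimates the raw camera noise.  Median-based statistics absorb the
minority of frames around the bolus where the residual reflects
smoothing model error rather than noise.  Under pure noise the
statistic has mean ≈ 2.3 σ with P(> 5 σ) ≈ 2×10⁻⁴ per pixel, so the
default threshold of 5 rejects background while a noiseless bolus
passes at any realistic threshold.

## Synthetic phantom

The generator emulates: a gamma-variate first pass
g(t) = A·((t−t0)/(αβ))^α·e^(α−(t−t0)/β) (peak-normalized: value A
exactly at t0+αβ), recirculation as delayed, amplitude-scaled,
dispersion-widened copies, exponential clearance damping of all dye
components, a constant tissue baseline, Gaussian camera noise, and
12-bit quantization.  Tissue presets: cerebrum (earliest arrival,
2.7 s rise), sagittal vein (sharp high-amplitude pass), skeletal
muscle (first peak *lower* than recirculation, so the first-peak/global
-max distinction is exercised), and ischemic cortex (onset delayed
2.9 s, 4.5 s rise, reduced amplitude).  Recirculation timing is
systemic (heart–lung transit), so the ischemic preset's recirculation
arrives at the same absolute time as the healthy side's, i.e. at a
shorter delay after its own late onset.  The default scene is 64×64,
40 frames at 0.58 s: two cortical hemispheres, a midline vein strip, a
muscle band, and a dark border; small enough that a full map computes
in roughly a second, which also sets the problem sizes used by the
test suite and the acceptance script.

Ground truth comes from the model, not the data: t_arrival = t0;
t_peak, I_peak and BFI from the closed-form first-pass maximum (with
clearance c > 0 the peak shifts to t0 + αβ/(1+βc)); MTT by fine-grid
quadrature of the noiseless baseline-free curve over
min(20 s, acquisition end − t0) — the same clipped-window definition
the analyzer uses.

The phantom does **not** emulate scalp/skull optics, depth mixing of
vertically stacked vessels (beyond an optional additive extracerebral
component with a stated weight), motion, photobleaching, or spatially
correlated noise.  Passing recovery tests therefore demonstrates the
correctness of the computation under the stated signal model, not
robustness to every property of in-vivo recordings.

## Known limitations

* **Sub-frame onset localization is not possible.**  With 0.58 s
  sampling, a model-free trace of the interpolated curve cannot place
  the bolus foot more precisely than the native frame spacing: the
  spline rings slightly at the foot, and native-grid smoothing spreads
  the onset backward by up to ≈ 1.5 frames, so absolute T_arrival (and
  hence T_rising, BFI and MTT, which inherit the arrival anchor)
  carries a systematic, shape-dependent offset of order one frame.
  Because the offset is common-mode for regions with similar bolus
  shapes, *differences* of arrival between regions are recovered to
  within one interpolated step (11.6 ms), and orderings between
  ischemic and healthy tissue are preserved — which is how the
  parameters are meant to be used.  Recovering absolute onsets at
  millisecond precision would require fitting the bolus model, which
  this method deliberately avoids.
* All parameters are relative; no arterial input function is measured,
  so no absolute CBF in mL/100 g/min and no 3D information.
* The 20 s MTT window is clipped for arrivals later than ≈ 2.6 s into
  a 40-frame acquisition; MTT values of late-arriving (e.g. ischemic)
  pixels are computed over a slightly shorter window and are best
  compared at similar arrival times.
* The classical t-tests assume approximately normal ROI values; no
  multiple-testing correction is applied (none is part of the
  protocol).
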