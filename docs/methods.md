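# Methods

This note documents the models and procedures implemented in nemasleep,
the parameters that matter, the design choices made where the underlying
methods description leaves room, and what the synthetic-data generators
do and do not emulate.

## Behavioral sleep scoring

Sleep is scored as movement quiescence. The raw signal is a per-frame
speed trace from one of two sources:

* **Frame subtraction** (label-free DIC stacks, 0.2 frames/s): the mean
  over pixels of the absolute intensity difference between consecutive
  frames, assigned to the later frame. Absolute differences are used —
  signed differences cancel and would flatten the trace for a moving
  worm. The value is in arbitrary units; only its within-worm dynamics
  matter because the trace is normalized per worm.
* **Centroid tracking** (fluorescence recordings, ~0.17 frames/s): the
  Euclidean displacement of the tracked neuron centroid converted to
  μm/s. Frames with failed detection, and the first frame of a
  recording, carry missing values (~0.03% of frames in practice).

Processing steps, in order:

1. **Interpolation.** Missing values are linearly interpolated; edge
   gaps take the nearest observed value.
2. **Smoothing.** Savitzky–Golay filter, window 40 frames (200 s at
   0.2 FPS), polynomial order 3 (the order is a package default; it is
   not dictated by the procedure and is configurable). The smoothed
   trace is clipped at zero before normalization: speed is physically
   non-negative, and the filter's polynomial undershoot at sharp
   wake→sleep transitions would otherwise set the normalization floor
   and lift the quiescent level off zero, fragmenting bouts.
3. **Normalization.** Min–max to [0, 1] per worm over the whole
   recording. A zero-variance trace (up to a relative tolerance of 1e-9,
   absorbing filter round-off) maps to all-zeros — an immobile worm —
   with a warning.
4. **Thresholding.** Normalized speed below θ (default 0.2; sensible
   range 0.1–0.3) is quiescent (0), at or above is moving (1); a frame
   exactly at θ is moving, since quiescence is defined as speed *below*
   the threshold.
5. **Two-minute rule.** Maximal quiescent runs of ≥ 120 s are sleep
   bouts; shorter runs are wake.
6. **Twitch refinement.** For each bout, the 120 s window before its
   start and after its end is examined; if the window contains at least
   one quiescent frame and its mean smoothed speed is below θ, the bout
   extends across the whole window. Overlapping bouts merge and the pass
   repeats until no boundary changes (cap: 100 iterations, with a
   warning on non-convergence — the procedure converges in a handful of
   passes in practice because extension is monotone). The mean is taken
   over the smoothed, normalized speed — the same scale on which θ is
   defined. Edge bouts are checked on the in-recording side only.
   Refinement only extends or merges bouts, never shortens them.

### Resolution limits of the scoring procedure

Two systematic effects follow from the prescribed smoothing and minimum
duration, and are worth knowing when interpreting scored output:

* The 200 s window erodes each bout edge by roughly 20–40 s (where the
  smoothed ramp crosses θ), so bouts barely above the 2-minute minimum
  can fall below it and be missed entirely. Bouts of ≥ ~3 min are
  recovered reliably.
* A twitch splits a bout only if its smoothed bump crosses θ, which for
  a single-frame spike requires an amplitude of roughly 2–3× the wake
  speed; the refinement pass absorbs such isolated twitches. Two
  twitches inside one smoothing window produce a bump whose flank mean
  exceeds θ and are *not* absorbed — the refinement rule, taken as
  stated, leaves them as a wake gap. Dense twitching (intervals shorter
  than the smoothing window) therefore degrades scoring for any
  boundary-based rule.

## Ratiometric neuron-trace extraction

Per frame and per channel: Gaussian blur (σ = 2 px, configurable; the
blur only serves thresholding), Yen threshold on the blurred image,
contours of the super-threshold region, and selection of the contour
enclosing the largest area (shoelace formula on the contour polygon; ties
broken by scan order). The mask is rasterized from the selected contour;
intensity means are always taken on the original, non-blurred image.
Segmentation operates per frame rather than on a global histogram —
illumination and expression drift over hours make per-frame thresholds
the safer choice. Yen's threshold is computed on a 256-bin histogram, so
masks are invariant to affine intensity rescaling up to binning.

Worm movement between the two channel exposures shifts the soma between
the reference (mKate2) and activity (GCaMP) images. The activity channel
is therefore segmented independently to obtain its centroid, and the
reference mask is translated by the integer-rounded centroid displacement
before reading out the activity mean — integer shifting preserves mask
size and shape exactly (up to clipping at the image border); sub-pixel
interpolation would not. Frames where reference segmentation fails, or
the shifted mask leaves the image, are flagged and carry NaNs; a warning
is raised if more than 1% of frames fail (observed failure rates on real
recordings are well below 0.1%).

The per-frame readout is R_t = ⟨activity⟩/⟨reference⟩ within the mask.
Any per-frame factor common to both channels — focus drift, expression
level — cancels in the ratio.

## Transient detection and event alignment

Calcium transients are detected on a heavily smoothed copy of the ratio
trace (SG window 120, order 3): local maxima with topographic prominence
≥ 0.02 (ratio units). The heavy window suppresses noise bumps but shifts
peaks; the corrected position of each peak is the argmax of the lightly
smoothed trace (window 20) within an interval extending left and right of
the raw position by the peak's half-prominence width plus 25 frames.
Argmax ties take the earliest frame. Prominence is not recomputed after
correction, and peaks with overlapping search intervals are all kept.
Per-animal transient frequency is peaks per hour of recording.

Event-triggered ensembles cut windows from 15 min before to 25 min after
each event (sleep-bout onset or transient peak) on the recording's frame
grid. The signal is lightly smoothed (window 20) before cutting; binary
sleep labels are not smoothed. Windows truncated by the recording edges
contribute NaNs, excluded position-wise from means. Averaging is
hierarchical: per animal over its own events, then across animals with
equal weight — each worm is one n. Interval statistics take each animal's
mean over a relative-time interval (inclusive bounds) and compare groups
with a two-sided Wilcoxon rank-sum test.

## Statistics

* **Wilcoxon rank-sum**: exact null distribution when both groups have
  n < 20 and the pooled sample is tie-free; otherwise the normal
  approximation with tie correction. The reported statistic is the rank
  sum of the first group.
* **Fisher's exact test** (two-sided) compares alive/dead counts at the
  median-survival day: the first day on which the shortest-living
  group's *smoothed* alive fraction reaches ≤ 0.5 (smoothed because
  that is the curve being plotted; configurable to raw). Interpolation
  between days is not attempted. Pairwise tests are not
  multiplicity-corrected by default (single planned comparisons); a
  Bonferroni option exists.
* **Adjacent averaging** of survival curves: centered moving mean,
  window 5 days, truncated at the curve edges (no data is fabricated
  beyond the observation range).
* **Reporter quantification**: Otsu threshold per ROI; the readout is
  the mean of pixels strictly above threshold. A flag is raised when the
  between-class variance at the threshold is below 25 intensity² (≈ a
  class separation of 5 intensity levels) — such an ROI is effectively
  unimodal and the threshold unreliable. ΔF/F is (F_d − F_0)/F_0 per
  worm; worms with F_0 ≤ 0 are excluded. Group comparisons use the
  per-worm mean over the last four recorded days.
* **Effective drug concentration**: c = c_stock · v_added /
  (v_added + v_bath); e.g. 10 μL of 5 mM aldicarb into ~600 μL agarose
  gives ≈ 0.08 mM.

## Synthetic data

The generators are pure functions of their parameter sets (including the
seed) and return ground truth alongside the data.

**Locomotion** (`gen_locomotion_trace`). Wake and sleep alternate with
exponentially distributed dwell times — the minimal renewal model, chosen
because it makes recovery tests analyzable; real bout-length
distributions are not matched. Defaults: 10 h at 0.2 FPS; mean dwell
900 s (sleep) and 2100 s (wake), i.e. a sleep fraction near 0.3 with
bouts on the tens-of-minutes scale that quiescence scoring is built for
(the event-alignment windows span −15…+25 min around bout onsets);
speed = state mean (1.0 wake / 0.05 sleep, a.u.) + Gaussian noise
(sd 0.1), clipped at zero; twitches are single-frame spikes of
amplitude 2.5 at 0.001 events/s during sleep — occasional brief
movements strong enough to split a naive score but sparse and isolated
enough for boundary refinement to absorb, the regime the refinement
step exists for (see the resolution notes above for why dense or
extreme twitching leaves that regime); frames go missing with
probability 3e-4, matching the observed missing-frame rate.

**Two-channel scene** (`gen_calcium_stack`). One isotropic Gaussian blob
(σ = 3 px) on a reflected Gaussian random walk (0.5 px/frame) inside a
128×128 field, margin 3σ. The reference channel has constant amplitude
1000; the activity channel is baseline 400 plus transients of the
double-exponential form (1 − e^(−t/rise)) · e^(−t/decay) (rise 5,
decay 30 frames), normalized to unit peak so the amplitude parameter
(600) is the peak elevation — the kernel maximum sits
rise·ln(1 + decay/rise) frames after onset, a closed form the tests use.
The activity blob is offset by per-frame Gaussian channel jitter; noise
is additive Gaussian (not Poisson — simplicity; the sd is configurable)
and frames are quantized to 8 or 16 bits. The true ratio is the
amplitude ratio, which equals the ratio of in-mask means for identical
blob shapes.

**Reporter snapshots** (`gen_reporter_image`). A synthetic stand-in for
single-worm reporter ROIs: a thick sinusoid "worm" of uniform intensity
over uniform background plus Gaussian noise. It tests thresholding and
ΔF/F plumbing, not worm morphology.

**Survival** (`gen_survival_counts`). Daily binomial deaths under a
constant hazard; alive + dead is conserved. Day-d survival has the
closed form (1 − h)^d used by the tests.

What the generators do **not** emulate: worm posture and shape in DIC,
photobleaching, focus drift, Poisson photon statistics, multi-worm
scenes, non-exponential bout structure, and state-dependent speed
autocorrelation. Passing recovery tests therefore demonstrates that the
algorithms invert the generative model they assume — not that they are
robust to every artifact of real microscopy.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale versions of each
analysis: 20-worm, 10 h behavioral cohorts; 20 two-channel stacks of
500 frames at 128×128 with 2% noise and 1.5 px jitter; 100 seeds of
3000-frame ratio traces with 8 transients at 5× noise amplitude; oracle
checks for all Wilcoxon group sizes ≤ 6 and Fisher margins ≤ 60. These
sizes keep a full run within a couple of minutes on one CPU while leaving
every statistical conclusion comfortably powered.

Savitzky–Golay windows are used exactly as specified (40/120/20 samples)
even though they are even-length; an even window evaluates the fit half a
sample off-center, which can displace detected extrema by one frame —
the position-correction step absorbs this. All image analysis is done in
floating point regardless of acquisition bit depth; no background
subtraction is applied anywhere (none is part of the procedure).
Half-open, 0-based conventions are used for all frame and ROI intervals.

## Known limitations

* Scoring accuracy degrades for bout lengths near the 2-minute minimum
  and for twitch rates approaching one event per smoothing window
  (see resolution notes above); both are properties of the prescribed
  method, not of this implementation.
* The prominence threshold (0.02) is defined on the GCaMP/mKate2 ratio
  scale of the original recordings; its absolute value does not transfer
  to differently normalized data.
* Mask transfer corrects translation only; rotation or deformation
  between channel exposures is not modeled.
* The pipeline driver parallelizes nothing; cohorts of hundreds of worms
  are still fast, but whole-image motion quantification of long stacks
  is I/O-bound and streams frames lazily instead.
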