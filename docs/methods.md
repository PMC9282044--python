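# Methods

## The measurement problem

A child seated in front of a webcam drums on the surface in front of
them for six 20-s trials: an unpaced trial (spontaneous motor tempo,
SMT), four trials paced by a video drumming at a target inter-onset
interval (IOI) of 400, 500, 600 or 700 ms (order counterbalanced:
400-600-500-700 or 700-500-600-400), and a final unpaced trial.  A
markerless pose model turns each video frame into keypoint triples
`(x, y, confidence)` in image pixels — 25 body points and 21 per hand —
with `(0,0,0)` marking an undetected point.  The quantity of interest
per trial is the drumming rate: the dominant frequency of the vertical
motion of the drumming hand, reported as IOI = 1000/f ms, and, on paced
trials, the tempo mismatch (drummed IOI − target IOI; positive = slower
than the stimulus).

## Pipeline model and assumptions

**Collation.**  One JSON document per frame, ordered by the zero-padded
counter in the file name; frame *k* is assigned time *k*/fps with fps
taken from trial metadata (webcam JSON carries no timestamps, so fps is
a required input, never inferred).  Missing frames in the index range
become fully missing samples.  The person dimension is padded to the
per-trial maximum; padding persons are entirely missing.

**Identity cleaning.**  Pose models label people per frame, so labels
switch between frames.  Each frame is matched against the previous
relabelled frame by minimum-cost assignment on either body-centroid
distance (centroid = mean of *detected body* keypoints only — hands
drop out too often) or figure size (height of the detected-body
bounding box).  The assignment is exact: brute-force enumeration over
injections for ≤ 4 persons (ties resolve to identity order), Hungarian
above that.  A match costing more than 25% of the frame diagonal
(location matching) is rejected and the person starts a fresh track,
preventing teleporting matches after occlusions.  Ghost tracks —
present in < 20% of frames or with mean confidence < 0.3 (both
configurable) — are flagged; a CSV correction ledger (swap / delete /
set_child over half-open frame ranges, applied in listed order) carries
the manual decisions.  The documented workflow is ledger-driven child
identification; the variance fallback (the unflagged track with the
largest vertical hand variance) is a logged convenience for synthetic
and well-behaved data.

**Hand signal.**  Per frame, the hand position is the mean of the
side's wrist body keypoint plus its 21 hand keypoints, weighted by
detection confidence over the detected members (the natural weighting
for pose-model output; logged in metadata).  The vertical signal is
the negated image *y*, so up is positive and a strike is a local
minimum.  Interior gaps are filled linearly between flanking observed
samples; leading/trailing gaps hold the nearest observed value (linear
extrapolation would invent trends at the spectrally sensitive edges).
Gaps longer than `max_gap_s` (default 1.0 s — longer than a drumming
period, hence spectrum-distorting) flag the trial for review without
aborting it.  The signal is then mean-centered.

**Spectrum and tempo.**  One-sided squared-magnitude DFT on the native
grid *k*/duration Hz (0.05 Hz for a 20-s trial) — no taper and no
zero-padding by default, both available as options; bursty drumming
after mean subtraction is the design regime and the rectangular window
keeps the peak bin interpretable.  Power below 1 Hz is discarded
(slow postural movement); the argmax of the remainder is the tempo,
with exact ties going to the lowest frequency (prefer the fundamental).
If everything above the cutoff is at or below a floor of 1e-12 × total
spectral power the trial gets an explicit *no-tempo* result instead of
a spurious peak.  The upper limit is Nyquist (fps/2).  Of the two
hands, the one with the larger spectral peak ("best hand") represents
the trial; an exact tie goes to the right hand (logged).

**Strikes and retention.**  Strikes are local minima with prominence
≥ 25% of the signal's peak-to-peak range (assistive only; a manual
coding table, when supplied, is authoritative for visibility, hand
used, interference, and strike counts).  A trial is retained as
drumming iff some run of ≥ 4 consecutive strikes has every gap
< 2000 ms.  Excluded trials carry exactly one primary reason code, in
priority order: off-camera, interference, no-drumming, no-tempo.

**Statistics.**  The export is trial-level (one row per retained
trial), so per-child averaging and mixed-effects models (drumming rate
~ trial type + (1 | participant), and the mismatch analogue) can be
fitted downstream with standard tools; re-implementing those fits here
would add nothing pipeline-specific.  Condition summaries use the
sample SD (n−1) and SE = SD/√N, with N counting retained trials with a
valid tempo.

## Synthetic cohorts

The generator emulates the study conditions, not the pixels: figures
are keypoint skeletons (caregiver full-scale and higher in frame,
child at 0.6 scale — giving size matching a real signal), and the
child's drumming hand follows a lift-and-hit cycle train.  Strike
times live on one continuous lattice spanning the trial — successive
gaps are IOI + N(0, motor-noise) — of which only strikes inside
drumming bursts (default three 5-s bursts separated by 2-s rests) are
expressed; the motor clock ticking through rests keeps bursts
phase-coherent, as a real child's steady tempo does.  Within a cycle
the lift is a squared raised cosine (smooth up, sharp contact),
exercising harmonic content against the 1 Hz cutoff; a pure-sine
waveform is selectable.  The drummed IOI is
`adaptation·target + (1−adaptation)·SMT` on paced trials and the
child's SMT (drawn once per child from Normal(550, 80) ms, spanning
the SMT range reported for this age group) on unpaced ones.  Defaults:
30 fps, 20-s trials, 40 px amplitude, 0.5 px coordinate noise, 30 ms
motor jitter, adaptation 0.5.

Corruptions are applied with known rates and logged completely —
per-frame listing permutations (identity switches), episodic static
low-confidence ghosts (episodes of 3–9 frames starting at rate
ghost_rate/6 per frame, ≈ ghost_rate frame coverage), and independent
zeroing of keypoint triples — so replaying the log on clean data
reproduces the corrupted data exactly.  What the generator does *not*
model: correlated pose-model error (whole-limb failures, left/right
confusions), camera motion, lighting, children leaving the frame, or
tempo drift within a trial.  Passing tests therefore demonstrate the
pipeline's algebra and its robustness to the modelled pathologies, not
performance on arbitrary home video — which is what the manual coding
and ledger workflow exist for.

## Missing-data accounting

Two rates are reported per trial.  `missing_frac` is the fraction of
contributing marker samples (wrist + 21 hand keypoints per frame)
undetected — the marker-level rate that confidence reweighting and
interpolation absorb, and the analogue of a "% of data interpolated"
figure.  `gap_fraction` is the fraction of whole signal samples with
*no* detected member, the quantity the signal-level interpolator
actually filled.  Under independent keypoint dropout the former tracks
the dropout rate while the latter stays near zero; both are in the
tidy export.

## Numerical choices

- Spectral bin = 1/duration Hz; "within one bin" tolerances are
  evaluated in Hz and converted to ms at the true frequency.
- Assignment costs are capped at the rejection threshold *during*
  optimisation (then pairs are filtered on the raw cost): when a track
  leaves the scene as another enters, the doomed pairing would
  otherwise be traded against good matches just to shrink the total.
- Peak ties → lowest frequency; best-hand ties → right hand; assignment
  ties → identity order.  All deterministic, all logged.
- Mean-centering tolerance: |mean| ≤ 1e-9 · max|v|.
- Parseval bookkeeping for the one-sided spectrum doubles interior
  bins (DC and, for even N, Nyquist are unpaired):
  `P0 + P_nyq + 2·ΣP_k = N²·var(v)` for a centered signal.
- Degenerate inputs: < 2 observed samples is an unusable-trial error;
  an all-flat signal yields an empty strike train; an empty spectrum
  above the cutoff yields a flagged no-tempo result, not an exception.

## Validation problem sizes

The validation suite (tests/test_acceptance.py and
scripts/acceptance.py) uses: 100 noiseless paced trials (25 per
target) through the full JSON path; 200 two-person trials at 10%
swap rate checked frame-by-frame against a brute-force tracker; 200
trials at 1% missing / 5% ghost / 10% swap; 20 replicates of a
50-child cohort (6,000 trials) for the tempo-flexibility trend;
exhaustive retention-rule enumeration (3,907 strike trains); and 100
random multi-tone signals for the spectral identities.  These sizes
give binomial slack well below the pass thresholds while keeping a
full run in the low minutes on one CPU.

## Known limitations

- Matching uses only the previous frame; a track that vanishes for
  even one frame is re-minted rather than re-identified (the ledger
  repairs such cases).  Re-identification across trials is out of
  scope.
- A spurious detection that happens to overlap a real figure is
  indistinguishable from it by location or size and can take over its
  track; such trials show an elevated reported missing fraction and
  are repaired with the ledger.
- The retention rule runs on automatically detected strikes unless a
  coding table supplies counts; on real data the manual coding remains
  authoritative.
- A single tempo per trial: time-varying tempo (burst-wise tempograms)
  and phase asynchrony are out of scope.
- The 1 Hz cutoff means drumming slower than 1000 ms IOI is
  unmeasurable by design.
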