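# Methods

## The procedure

`ecgpsr` implements a nonlinear-dynamics approach to detecting
cardiovascular abnormality from a single-lead ECG. Instead of feeding
whole beats to a classifier, the method watches three *localized
features* of each beat — the PR interval (P onset → QRS onset), the QRS
complex (QRS onset → offset) and the QT interval (QRS onset → T
offset) — and quantifies how *disordered* their phase-space trajectories
become:

1. **Conditioning.** The record is band-limited with a cascade of
   zero-phase Butterworth filters (1 Hz high-pass, 40 Hz low-pass,
   order 4 each) and min–max normalized onto [0, 1]:
   `x_n(t) = (x(t) − min x)/(max x − min x)`.
2. **Delineation.** Beats are detected and the five fiducials (P onset,
   QRS onset, R peak, QRS offset, T offset) located per beat (details
   below), and the three feature segments sliced out of every beat.
3. **Phase-space reconstruction.** A sliding window of `W1 = 20`
   consecutive segments of one kind (stride 1) is concatenated into a
   series `s(t)` and delay-embedded as the planar point set
   `(s(t), s(t − T))` with delay `T = 20 ms`. The polyline through the
   embedded points is rasterized onto an `N × N` occupancy grid over the
   unit square (default `N = 100`); the number of occupied cells `n_b`
   is the window's *box count*.
4. **Trend statistic.** A second sliding window (length `w = 20`,
   stride 1) runs over the box-count series; within each window the mean
   `μ`, the population standard deviation `σ` (second central moment,
   divide by `w`) and the coefficient of variation `CV = σ/μ` are
   computed. `k` box counts yield `k − 19` CV values.
5. **Two-threshold classification.** From subjects with a known
   healthy→unhealthy transition, per-subject extrema are pooled:
   `Th_final_max = max_i ( max CV over subject i's all-healthy windows )`,
   `Th_final_min = min_i ( min CV over subject i's all-unhealthy windows )`.
   A CV value is *healthy* if `CV ≤ Th_final_max`, *unhealthy* if
   `CV ≥ Th_final_min` (both ties inclusive), and
   *tending-to-unhealthy* in between — the middle band is the early-
   warning zone. Reference thresholds from the original 65-subject
   cohort ship as `PUBLISHED_THRESHOLDS`:
   PR (0.068, 0.1012), QRS (0.069, 0.083), QT (0.079, 0.082).
6. **Evaluation.** Sensitivity, specificity, accuracy, PPV, NPV, FPR,
   FDR, FNR and F1 from the confusion counts; t-based confidence
   intervals; a right-tailed paired t test of unhealthy-vs-healthy mean
   CV; and the equivalent two-condition repeated-measures ANOVA, for
   which `F = t²` exactly.

The physical intuition: a healthy rhythm retraces nearly the same
phase-space loop beat after beat, so the trajectory occupies few cells
and the box count barely moves; arrhythmic rhythm wanders, the
portraits smear, and both the level and the dispersion of the box count
rise. The CV isolates the *relative* dispersion, which is what the
thresholds act on.

## Delineation details

Both delineation stages run on wavelet-derived views of the signal, at
1 kHz: level-3 Haar structure (8-sample scale) for the QRS and level-5
structure (32-sample scale) for the slow P/T waves.

* **R peaks** are modulus maxima of the undecimated level-3 Haar detail
  envelope, above `max(0.3 × rolling RMS over 2 s, 0.25 × rolling max)`
  with a 200 ms refractory period; each envelope peak is refined to the
  signal's local extremum. The rolling-max term rejects T-wave energy,
  whose level-3 envelope stays below ~20 % of the R's.
* **QRS onset/offset**: from the steepest point on each side of R, scan
  outward until the (5 ms-smoothed) derivative stays below 5 % of the
  complex's maximum slope for 5 ms.
* **P onset**: the largest level-5-smoothed positive bump 220→40 ms
  before QRS onset; the onset is placed 3σ before the apex, with σ
  estimated from the bump's half-maximum width and corrected for the
  smoothing-window broadening. Anchoring on the 50 % crossing (steep
  flank) makes this far more stable than any threshold on the shallow
  foot, which inherits the local baseline ripple left by the 1 Hz
  high-pass.
* **T offset**: the largest level-5-smoothed extremum 80→450 ms after
  QRS offset, traced right to where the return slope falls below 5 % of
  the maximum T slope. A slope criterion is immune to a local baseline
  *offset*; we found the classical tangent construction lands about one
  T-width σ short of the generator's ±3σ truth convention, so the slope
  rule is used instead.

All detector thresholds are relative (to rolling RMS, local maximum
slope, or apex height), so beat detection is invariant to positive
rescaling of the input. Beats whose search windows fall off the record
ends are dropped; the pipeline additionally discards beats within 1 s of
either end, where the zero-phase 1 Hz high-pass is still settling.

On noise-free synthetic records the median absolute error of the
recovered PR/QRS/QT durations is ≤ 15 ms (typically 3–11 ms); R peaks
are exact to within a few samples. The residual QRS bias (~10 ms short)
comes from the Q/S deflections' slope tails and is stable, so it cancels
in the CV statistic.

## The synthetic generator

Each beat is a sum of Gaussian bumps (P; Q, R, S; T), so every fiducial
has a closed-form location: a wave starts/ends at ±3σ of its bump. The
generator is the package's ground-truth instrument — feature-recovery
accuracy, window labeling and threshold learning are all scored against
its truth table.

Defaults (healthy): PR 160 ms, QRS 90 ms, QT 380 ms, RR 800 ms at
1 kHz; amplitudes P 0.15, Q −0.08, R 1.0, S −0.18, T 0.35. Healthy
beat-to-beat variability is set low — interval jitter 0.2 % (≈ 1 ms),
amplitude jitter 0.1 %, RR jitter 0.5 % — reflecting how repeatable
resting sinus morphology is; beat-averaging in clinical devices relies
on exactly this stability. Noise and baseline wander default to 0.

Unhealthy regimes are caricatures of disease-class feature
disturbances, not clinically validated simulations:

* `af_like`: P wave suppressed and flickering, RR jitter 15 %.
* `bbb_like`: widened (140 ms), notched QRS whose notch positions
  wander beat to beat (fragmented-QRS variability).
* `long_qt_like`: QT prolonged to 500 ms with a widened T.

All three add, on top of 10–12 % interval jitter: an AR(1) log-scale
amplitude drift (sustained waxing/waning), occasional ectopic-like
beats with grossly enlarged and sometimes inverted deflections,
erratic P amplitude, a handful of random extra deflections per beat
(disorganized fibrillatory-like activity), and small per-beat baseline
displacements. These mechanisms were chosen by
analyzing what actually moves a phase portrait's box count: a thin
trajectory loop's cell count is governed by the *union geometry* of the
window's 20 loops, so sustained amplitude excursions, shape changes and
vertical displacements are what produce the large, persistent
box-count dispersion (CV ≈ 0.05–0.4) that separates the unhealthy band
from the healthy one (CV ≈ 0.00–0.04), mirroring the separation the
method requires. Purely white per-beat jitter self-averages across the
20-beat window and does *not* produce it.

What the generator does **not** emulate: real fibrillatory f-waves,
12-lead geometry, intracardiac electrograms, electrode artifacts,
non-stationary noise, or physiologic QT–RR adaptation. Passing the
synthetic recovery study therefore demonstrates that the pipeline's
machinery (delineation → embedding → box counting → CV thresholds)
recovers planted separations; it does not certify clinical performance.

## Numerical choices

* **Rasterization** is an exact supercover: a cell is occupied iff the
  trajectory polyline intersects the half-open cell
  `[i/N,(i+1)/N) × [j/N,(j+1)/N)` (closed at 1.0). Implemented as a
  per-segment bounding-box walk with Liang–Barsky clipping (numba-
  compiled); verified cell-for-cell against a brute-force every-pixel
  oracle for N ≤ 16.
* **Grid size** `N = 100` and embedding delay 20 ms are configurable;
  the delay in samples is `round(delay_ms · fs / 1000)`, so non-1 kHz
  records work without resampling.
* **Population vs sample SD**: trend windows use the population moment
  (divide by `w`, per the CV definition); all inferential statistics use
  the sample convention (`n − 1`).
* **Degenerate cases**: a constant record cannot be normalized (error);
  a trend window with zero mean count records CV = 0 with a warning; a
  learned threshold pair with `Th_final_max ≥ Th_final_min` (possible
  for overlapping cohorts) is flagged degenerate and classification
  degrades to a two-class midpoint rule with a warning. `Th_final_max`
  may be exactly 0 when every healthy window of a noise-free cohort is
  identical.
* **Ties** go with the band: `≤` on the healthy side, `≥` on the
  unhealthy side.
* **Windowing labels**: a CV window is *all-healthy* iff every beat
  contributing to any of its box counts is healthy (the CV window at
  index m spans beats m … m + w + W1 − 2), giving the landmark
  arithmetic `a = n_healthy − (w + W1 − 1)`, `b = n_healthy` for a
  clean two-block record.

## The cohort study

`run_cohort_study` generates 20 healthy-only records (90 beats) and 20
transition records (45 healthy + 45 unhealthy beats, cycling the three
unhealthy regimes), splits 80/20 stratified, learns per-kind threshold
pairs on the training transition records, and classifies the held-out
records. A record's per-kind summary is the **mean CV of its evaluation
block** (the all-unhealthy window suffix for a transition record, the
whole trace for a healthy record); the record is called positive if any
kind's summary reaches that kind's `Th_final_min`. This block-mean
accounting matches how the cohort statistics (means, CIs, t/F tests)
summarize each subject; the online tool (`classify_trace`) keeps the
stricter any-window rule.

Record sizes (90 beats ≈ 72 s) are the smallest that leave a usable
margin of all-healthy and all-unhealthy CV windows on both sides of the
double windowing (each CV window spans 39 beats).

## Subject-level aggregation

The three-band rule is defined per CV value. For a whole trace the
package reports the most severe window label (any unhealthy window ⇒
subject unhealthy). Per-disease naming (AF/BBB/MI/…) is out of scope:
the decision space is per-feature abnormality, with the union over
features available as a convenience.

## Known limitations

* The delineator is tuned for the generator's smooth morphology; real
  records with pathological baselines or very low SNR will need the
  detector constants revisited.
* Box counting is single-resolution (occupancy at one N), not a
  fractal-dimension estimate across scales.
* Threshold learning needs annotated transition landmarks (a, b); on
  real data these must come from expert annotation.
* WFDB support covers the common format-16 encoding only.
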