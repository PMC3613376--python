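# Methods

## Data model

A **study** is one speckle-tracking acquisition: a temporal grid
(strictly increasing frame times in ms plus a nominal frame rate, which
must agree with the median inter-frame interval to within 20%), a set
of per-point strain traces, optional cardiac-cycle windows, and
metadata. Traces are keyed by (segment, layer, point index): six PLAX
segments (`ant_base, ant_mid, ant_apex, post_apex, post_mid,
post_base`), two layers (`endo`, `epi`), eight points per segment. A
complete layer therefore holds 48 traces. Unknown segment labels are
rejected rather than coerced, keeping all downstream regional logic
total over the fixed vocabulary. Strain is signed percent, shortening
negative; |strain| ≥ 100% is treated as corrupt. Frame indexing is
0-based and cycle windows are half-open `[start, end)`, which makes
per-cycle slicing composable without off-by-one corrections. Point
positions (mm) are optional: every metric works without them; only map
rendering requires them.

## Curves and cycles

Segment curves are frame-wise arithmetic means of the segment's 8
points; the global curve averages all 48 points, which equals the mean
of the six segment curves whenever every segment is complete (equal
weights). Cycle detection anchors windows at local maxima of the
global curve: strain exports carry no ECG channel, but strain is by
construction zero at each cycle's end-diastolic reference frame, so
cycle starts appear as near-zero local maxima. Peaks are found with a
prominence floor of 20% of the curve's range (rejects noise ripple), a
minimum spacing of 40 ms (admits heart rates up to 1500 bpm), and
−∞ padding so end-diastolic frames at the record boundaries count as
maxima; ties break to the earliest frame. A flat curve raises a
detection error. When more cycles are detected than requested, the
first consecutive run is used — a deterministic policy matching the
convention of analysing three consecutive cycles.

Cycles of unequal frame count are compared after linear interpolation
onto a common number of equally spaced times spanning the window.
Linear (not spline) interpolation is chosen because it is monotone and
overshoot-free on noisy physiological curves; it is exact on affine
signals and the identity at matched resolution. Strain is not re-zeroed
per cycle (no baseline subtraction); re-zeroing would alter vector
angles and is not part of any measure here.

## Peaks and regional summaries

Peak strain is the signed minimum of a curve (ties to the earliest
frame); time-to-peak (TTP) is its offset in ms from the window start.
All summary metrics are computed **per cycle and then averaged** across
the selected cycles. This ordering is a contract, not a convenience:
with timing jitter across points, the peak of an averaged curve is
systematically shallower than the average of per-cycle peaks, and the
test suite checks the two are distinguishable.

Regional contrasts pool the basal segments (anterior + posterior base;
16 points) against the apical segments (anterior + posterior apex); mid
segments are deliberately excluded so the contrast is between clean
anatomical extremes. The region curve is defined at the point level
(frame-wise mean of the 16 point traces) — identical to averaging the
two segment curves under equal counts, but the point-level definition
remains correct if counts ever differ.

The Doppler helper uses the simplified Bernoulli relation ΔP = 4·v²
(mmHg from m/s), the standard clinical conversion for continuous-wave
stenosis gradients; a peak velocity of 3.57 m/s corresponds to
~51 mmHg.

## Dyssynchrony measures

1. **Maximum TTP delay** — range of the six segment TTPs (ms).
2. **TTP SD** — sample standard deviation (n−1) of the six TTPs (ms).
3. **Mean vector angle** — each of the layer's 48 cycle-windowed point
   curves is treated as a vector with one dimension per frame; the
   angle θ = arccos(a·b/(|a||b|)) is evaluated for all 1128 unordered
   distinct pairs (self-pairs excluded) and averaged, reported in
   degrees for readability. The cosine ratio is clamped to [−1, 1]
   before arccos to guard against floating-point round-off on
   near-parallel vectors; zero-norm vectors raise an error naming the
   offending point rather than being silently dropped.

Vectors span one cycle each, with per-cycle angles averaged across the
selected cycles, and are computed per layer (endocardial by default) —
pooling layers or spanning multiple cycles would conflate transmural
and beat-to-beat variation with segmental dyssynchrony. Vectors use
raw strain values; mean-centering is available behind an off-by-default
flag because it changes θ.

The angle is invariant under positive scaling, so amplitude-only
heterogeneity (one region contracting less, all curves the same shape
and timing) contributes 0°: the measure isolates timing and morphology.
Conversely, at murine frame rates (~4.3 ms frame time at 230 Hz) TTP
measures can only change in whole-frame steps, while the vector angle
varies continuously with sub-frame timing shifts — the property tests
assert both the lattice structure of the former and the nonzero
seed-to-seed variance of the latter.

## Synthetic studies

The simulator produces the conditions the measures are designed for:
650 bpm, 230 frames/s, three cycles, 48 endo + 48 epi traces. Each
point's curve is a C¹ raised-cosine trough — zero at the cycle-start
reference, descending to −amplitude at 45% of the cycle, returning to
zero — which reproduces the features that matter downstream (a single
systolic trough with a well-defined peak and TTP) without pretending to
be a biomechanical model. Heterogeneity enters through:

* **amplitude**: per-segment peak magnitudes (defaults 15/17.5/20% for
  base/mid/apex — the apical predominance of normal murine longitudinal
  strain); epi amplitudes are endo × 0.8 (transmural gradient);
* **timing**: one Gaussian offset per point (SD = `phase_jitter_sd`,
  default 1.5 ms), shared between that point's endo and epi traces,
  plus optional deterministic per-segment offsets for ground-truth
  phase experiments;
* **morphology**: a seeded random subset of points receives an added
  early-systolic positive-strain bump (raised cosine centered at 12% of
  the cycle), emulating the clusters of positive strain seen under
  pressure overload;
* **noise**: additive white Gaussian per frame (default SD 0.5%).

Presets: `sham` = the defaults; `aac` = basal amplitudes reduced to
9% (mid 14%, apex 19%), jitter SD 6 ms, 50% of basal/mid points given
5% positive excursions; `deaac` = near-sham amplitudes with 2.5 ms
jitter; `mi_like` = anterior mid+apex at 1% amplitude with dominant
positive excursions. Preset numbers are tool defaults chosen to
reproduce each phenotype's qualitative regional/timing pattern, not
measurements of particular animals. Positions are generated on a
schematic PLAX half-ellipse (endo inside epi, mild strain-proportional
radial motion) — synthetic geometry for rendering, not anatomy.

Everything is deterministic given the seed, with draws made in
canonical trace order so adding noise never perturbs the latent phases.

What the simulator does **not** emulate: speckle decorrelation and
tracking drift, respiratory/probe motion, ECG timing, beat-to-beat
physiological variation (every simulated cycle has the same latent
parameters), and realistic spatial correlation of noise along the wall.
Passing tests therefore demonstrate correctness of the measures under
controlled heterogeneity, not robustness to every artefact of real
acquisitions.

## Rendering

Maps use a diverging blue–white–red scale (matplotlib `bwr`) with
symmetric default limits ±30% about a white midpoint at 0; out-of-range
strain clamps to the endpoints, and the red channel is monotone in
strain. Endo and epi chains are both color-coded and distinguished by
marker size (epi larger, drawn behind). Image coordinates follow the
raster convention (y down); axis limits come from the position bounding
box over all frames plus a 1 mm margin, so cine frames share one fixed
view. Rendering is pure — identical studies yield byte-identical
PNGs. Cine output is MP4 when an ffmpeg encoder is importable, else an
animated PNG, else a directory of per-frame PNGs (each fallback with a
warning).

## Numerical choices and problem sizes

Tolerances: round-trip CSV I/O preserves floats to 9 significant
digits; the vectorized pairwise-angle computation agrees with a
brute-force double loop to 1e-9 degrees; exact-zero assertions on
angles allow ~1e-4° of arccos round-off near parallel vectors. The
test suite and the reproduction script run the simulator at its native
scale (96 traces × ~65 frames); stochastic ordering claims use 50
matched-seed replicates and ground-truth recovery uses noise-free,
jitter-free configurations so the imposed parameter is the only signal.

## Known limitations

* Cycle detection assumes the canonical speckle-tracking convention of
  near-zero strain at end-diastole; heavily drifting baselines would
  need external gating (out of scope).
* The mean vector angle is reported per layer and per cycle-average
  only; no confidence interval is attached (group statistics are out of
  scope).
* The CSV dialect is this package's own; vendor-native binary/XML
  exports and DICOM are not parsed.
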