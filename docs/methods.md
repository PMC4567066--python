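# Methods

## The measurement problem

A necklace-worn hybrid sensor (tri-axial accelerometer, 50 Hz, ±4 g;
barometer, 25 Hz) observes an older adult at home. The quantity of
interest is time-on-legs (ToL): every second spent standing, walking or
transferring between sitting and standing. Sitting and quiet standing are
nearly indistinguishable in trunk acceleration alone — both are static,
upright postures — so the chain leans on two complementary cues: the
barometric altitude step the chest-worn sensor makes when the wearer
rises from or lowers onto a seat (≈ 0.45 m, i.e. ≈ 0.053 hPa), and the
temporal context that a quiet period following a stand-up must be
standing. This is the central design idea the package implements.

## Signal conditioning

All filters are zero-phase (forward–backward) 4th-order Butterworth, so
detector output stays aligned to the one-second annotation grid. Cutoffs
are deliberate defaults, surfaced in `SignalConfig`, since no canonical
values exist for this chain:

| parameter | default | role |
|---|---|---|
| `cutoff_detect_hz` | 5 Hz | detection band; keeps step/transfer dynamics, drops sensor noise |
| `cutoff_gravity_hz` | 0.25 Hz | gravity/orientation estimate for tilt and the transient band |
| `cutoff_pressure_hz` | 1 Hz | barometric smoothing before altimetry |
| `intensity_window_s` | 1 s | centred moving-std window of the gravity-removed norm |
| `metres_per_hpa` | 8.43 | barometric altimetry constant near sea level |
| `upright_axis` | z | device axis along the trunk when upright |

Movement intensity is the moving standard deviation of the
gravity-removed acceleration norm — the conventional reading of
accelerometric "signal intensity". The transient band (detection-band
norm minus gravity-band norm) is the input to transfer detection.
Relative altitude is linear in pressure deviation and zero at the first
sample, which makes the whole pipeline invariant to a constant pressure
offset (weather, floor level).

## Detectors and their thresholds

Every threshold is a config default in `DetectorConfig`; none has a
published canonical value, so they were fixed once on pilot synthetic
data (the same way the original chain was trained on separate pilot
recordings) and are not tuned per run:

- active: intensity ≥ 0.03 g, gaps ≤ 2 s merged, bouts ≥ 1 s kept;
- walking: norm peaks ≥ 0.10 g above the 1 g level, inter-peak interval
  0.35–1.4 s (cadence 0.7–2.9 Hz), ≥ 2 peaks per bout — walking is
  defined from two steps upward;
- lying: tilt > 60° sustained ≥ 10 s. The 10 s minimum trades short-bout
  sensitivity for robustness, the same trade the validation literature
  reports (very short lying bouts are the dominant miss);
- transfer candidates: transient-band extrema ≥ 0.12 g, ≥ 1.5 s apart,
  4 s analysis window, gated on ≥ 0.15 m altitude range *and* ≥ 4° tilt
  range within the window. The altitude gate is what excludes level-ground
  walking from the transfer path before any classification happens.

The transfer classifier is a linear SVM (standardized features,
`LinearSVC`) over six features: signed peak normalized cross-correlation
with a canonical 2.5 s biphasic transfer template, peak–valley time,
orientation at mid-window, median intensity 1.5 s before and after, and
the start-to-end altitude change. The altitude sign separates the two
transfer directions; the template correlation and the flanking
intensities reject bends (altitude dips but returns), walking and noise.
Training data are synthetic pilot scenes (stand-ups, sit-downs, walks,
bend-and-pick gestures, quiet postures) over random frail/non-frail
profiles and noise levels up to 0.12 g, with ±0.5 s window jitter; the
fitted model ships as a JSON fixture (`transfer_svm_v1`, seed 20150911,
600 windows, hold-out accuracy 0.985) so detection is deterministic. A
rule-based fallback (`threshold_classify_transfer`: altitude sign gated
by template correlation) is provided for use without the fixture.

A detected transfer is reported over the transient's peak-to-valley span
padded by half that span per side — the biphasic waveform's peak–valley
distance is about half the transfer duration, so this reconstructs the
event extent without knowing the duration a priori.

## Fusion

Per-second assembly uses majority coverage (an interval labels a second
it covers by ≥ 0.5 s; for single-label annotation conversion, ties go to
the earlier event). Conflicts resolve by the fixed priority
transfers > walking > lying, applied pointwise. Context rules then
relabel each maximal active/inactive run from its flanking labels
(standing between a rise/walk and a descent/walk; sitting between a
descent and a rise or lying); they run strictly after priority
resolution, so the two stages cannot conflict, and they never touch
seconds already labeled transfer/walking/lying. Two deliberate choices
where the rule statement is silent:

- a run flanked by walking on both sides becomes standing (the standing
  rule admits walking on either flank; the sitting rule does not);
- at a recording boundary the missing flank matches vacuously, but a run
  matching *both* rules (e.g. one with no flanks at all) keeps its
  active/inactive label. Continuous field recordings have no such
  boundaries; desk recordings truncate context, and the vacuous match
  lets a leading standing run or trailing seated rest be labeled without
  inventing a priority between the two rules.

A run following lying matches neither rule and stays unlabeled
active/inactive; un-labeled *active* seconds still count as ToL (they are
movement on the legs by construction), un-labeled inactive seconds do
not. ToL is the exact set image {sit-to-stand, stand-to-sit, walking,
standing, active}.

## Validation statistics

Sensitivity, specificity and overall agreement are duration ratios over
aligned per-second series; undefined metrics (category absent from the
reference) are reported as not-applicable, never as zero, so group means
are not silently distorted. Grades follow the Fleiss benchmarks with
right-closed boundaries (40/60/80). ICC(2,k) is computed from the two-way
ANOVA mean squares (absolute agreement by default, consistency by flag);
zero between-target variance raises a degenerate-input error rather than
returning a value. The frail/non-frail comparison uses Welch's t-test by
default (pooled-variance by flag) on per-subject values; group-level
metrics pool the concatenated per-second series.

For category-level scoring, predicted transfer seconds collapse to their
destination posture (sit-to-stand → standing, stand-to-sit → sitting),
matching how the generator collapses its script to the four-category
video vocabulary. ToL scoring against synthetic ground truth uses the
fine-grained script labels (which retain transfers) reduced by the same
membership rule the fusion stage uses.

## The synthetic generator

The generator emulates the validation study's two conditions. The
standardized protocol realizes, in order: 5 s standing, sitting down,
timed-up-and-go at slow/3× normal/fast pace, five chair rises (five full
up–down cycles ending seated), a single stand-up, a bend-to-pick gesture,
bed lying with a mid-lying turn onto the side, optional floor lying, and
a final aided 10 m walk for walking-aid users, with 15–20 s seated rests
between exercises (about 5.5 min per subject). The free protocol is a
semi-Markov walk over the four postures with long daily-life dwells
(sitting 40–150 s, standing 10–45 s, walking 8–35 s, lying 20–50 s) and a
transfer inserted at every seated↔upright boundary, truncated to exactly
30 min.

Profiles separate the two groups the way frailty presents in gait:
non-frail cadence 1.5–2.0 Hz vs frail 1.0–1.4 Hz, lower step peaks
(0.20–0.30 g vs 0.28–0.45 g), more sway, slower transfers (2.2–3.0 s vs
1.5–2.2 s), universal walking-aid use among frail profiles with
alternate-step amplitude asymmetry (factor 0.65–0.85), and a frailty
score drawn ≥ 4 (frail) or ≤ 3 (non-frail). These ranges are documented
fixtures chosen as field-plausible values, not published measurements.

The signal model is phenomenological: a gravity vector that follows
posture orientation (85° tilt when lying, 2 s orientation ramps, a
forward-lean bump during transfers and bends), raised-cosine step pulses
locked to cadence, a biphasic ±0.35 g transfer transient, movement
bursts around bed entry/exit, pressure that tracks necklace height
(seat-height steps at transfers, a bend dip that returns to baseline)
plus a slow 0.02 hPa drift, and additive white noise on both channels
(pressure noise scaled at 0.1 hPa per g of accelerometer noise). What it
does **not** model: soft-tissue and necklace-sway artifacts (the pendant
sliding sideways when lying — a known real-world failure mode), stair
and elevator altitude changes, bicycling, non-level walking, and
individual gait irregularity beyond amplitude jitter. Passing the
synthetic end-to-end checks therefore demonstrates internal consistency
of the chain and correctness of its logic under the stated signal
phenomenology — not field accuracy on real recordings.

## Problem sizes and numerical choices

The end-to-end checks use 10 zero-noise standardized recordings (pooled
ToL sensitivity/specificity and category agreement) and 20 recordings per
noise level {0, 0.05, 0.15} g for the degradation check; the acceptance
script simulates 20 subjects (7 frail, 13 non-frail) per protocol at
0.05 g noise, the cohort composition of the study design it emulates.
These sizes were chosen as comfortable for a laptop-class machine while
keeping pooled denominators in the thousands of seconds. Degenerate
inputs are handled explicitly: recordings shorter than 5 s are rejected;
tilt is flagged unreliable below 0.2 g vector magnitude; candidate
windows shorter than the template raise a feature error and are skipped;
interval ties in per-second labeling go to the earlier event.

## Known limitations

- Quiet standing that is not flanked by a detected transfer or walking
  (e.g. after lying) remains unlabeled and is counted off-legs unless the
  active detector fires — the main source of residual ToL misses, and the
  same mechanism that depresses free-living sensitivity relative to the
  scripted protocol.
- Very short lying bouts (< 10 s) are invisible by design.
- At high noise (≳ 0.1 g) the intensity threshold saturates to
  all-active and category agreement collapses; the chain is not tuned
  for such sensors.
- The device-frame axis convention is configurable (`upright_axis`)
  because hardware conventions differ; lying is defined relative to that
  configured axis.
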