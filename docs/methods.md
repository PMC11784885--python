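# Methods

## Pipeline

The detector is a three-stage deterministic pipeline over a per-frame
facial-mesh stream:

1. **Aspect ratios.** From each frame's 468-point mesh, the eye aspect
   ratio (EAR) and mouth aspect ratio (MAR) are computed from fixed
   keypoint indices (eye corners 33/133 and 362/263 with three eyelid
   pairs each; mouth corners 61/291 with three outer-lip pairs). Each
   ratio is a sum of three vertical separations over three times the
   corner width, so it is invariant to uniform scaling, translation and
   horizontal mirroring of the mesh, and needs no camera calibration.
   Only x and y enter the formulas; z is carried but ignored, making
   the computation strictly planar.
2. **Per-frame states and episodes.** A frame is closed-eye when
   `EAR < 0.02` and yawning when `MAR > 0.65`. Maximal runs of a state
   become half-open episodes `[start, end)`, so `duration = end − start`
   equals the number of in-state frames — a 20-frame closure yields
   F_e = 20 with no off-by-one. Optional per-frame detector labels
   tighten the yawn test (`o_mouth` AND the ratio test) and loosen the
   eye test (`c_eyes` OR the ratio test); this asymmetric pairing is
   implemented as specified rather than harmonized.
3. **Cycle verdicts.** The stream is tiled into unit cycles of
   F0 = 150 frames (≈ 6.5 s at ~23 fps). Per cycle, P_eyes and P_mouth
   are the summed episode overlaps divided by F0, and F_e/F_m are the
   longest runs touching the cycle. The cycle is fatigued iff
   `P_eyes ≥ 0.15 ∨ P_mouth ≥ 0.15 ∨ F_e ≥ 20 ∨ F_m ≥ 30`.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `ear_closed` | 0.02 | – | per-frame eye-closure threshold (strict `<`) |
| `mar_yawn` | 0.65 | – | per-frame yawn threshold (strict `>`) |
| `f0` | 150 | frames | unit-cycle length |
| `perclos_threshold` | 0.15 | – | cycle PERCLOS trigger (inclusive `≥`), eyes and mouth |
| `fe_threshold` | 20 | frames | consecutive closed-eye trigger (inclusive) |
| `fm_threshold` | 30 | frames | consecutive yawning trigger (inclusive) |
| `stride` | `f0` | frames | window step; smaller values give sliding evaluation |
| `gap_tolerance` | 0 | frames | episode merge distance (off by default) |

Design choices where the published rule left room:

- **Disjunction of PERCLOS scores.** The cycle rule's eye and mouth
  scores are treated as independent triggers (OR), consistent with the
  conditions being listed disjunctively; requiring both (AND) would make
  the mouth score gate eye-only fatigue, which contradicts the
  single-episode closure criterion.
- **Inclusive cycle comparisons.** The cycle-level comparisons are `≥`
  as printed in the decision rule, although the accompanying prose says
  "exceed"/"surpass"; the per-frame ratio comparisons are strict as
  printed there.
- **Window-straddling episodes.** PERCLOS uses each episode's *clipped*
  overlap with the cycle (keeping the score in [0, 1]); F_e/F_m use the
  *full* duration of any episode touching the cycle, because behavioural
  continuity should not be an artifact of where the tiling falls.
- **Partial trailing windows** are evaluated with F0 as the divisor and
  flagged `partial`; the overall verdict counts complete cycles only.
- **Degenerate frames** (zero eye or mouth corner width) are flagged
  invalid, not fatal, and count as neither closed nor yawning; a missing
  landmark index is a hard, named error because it indicates malformed
  input rather than a transient geometric collapse.
- **Coordinates** must be isotropic (pixels recommended). Per-axis
  normalized coordinates from mesh extractors distort x/y ratios on
  non-square images, so the reader offers a normalized mode that
  rescales by the image dimensions before any ratio is computed.
- "Left"/"right" eye naming follows the keypoint-index convention
  (33/133 vs 362/263); some extractors mirror this anatomically, which
  leaves the averaged EAR — and every verdict — unchanged.

## Synthetic generator

`drowsekit.synthetic` emulates the kinematic structure the detector
assumes: an EAR resting at 0.10 that collapses to 0.005 during
closures, and an MAR resting at 0.25 (within the 0.2–0.3 closed-mouth
band) that plateaus at 1.1 during yawns. A typical yawn lasts ≈ 6.5 s,
i.e. 150 frames at the default 23 fps (`default_yawn`). The open-eye
baseline of 0.10 is a generator choice of convenient magnitude, not an
empirical claim. Geometry uses a 640-unit face width with 90-unit eyes
and a 120-unit mouth, so the Gaussian coordinate noise (`noise_sd`) is
interpretable in pixel-like units.

Transitions are linear attack/plateau/release ramps of `ramp` frames
(default 10) — the simplest shape realizing the stated plateaus. The
ramps interpolate from the baseline *toward the decision threshold
without crossing it* (the plateau alone sits beyond the threshold): a
ramp that crossed the threshold would make detected episodes longer
than the scripted event, breaking the exact correspondence between
script and truth that the round-trip tests rely on. Ground truth marks
a frame closed/yawning iff its noiseless ratio crosses the default
threshold, so a weak event (`intensity < 1`) that never crosses is
correctly absent from the truth.

What the generator does **not** emulate: head rotation and pose-induced
foreshortening, landmark jitter with temporal correlation, occlusion
(glasses, hands), illumination effects, or extractor failure modes.
Noise is isotropic Gaussian, independent across frames and coordinates.
Passing round-trip tests therefore demonstrate the correctness of the
decision layer, not robustness of any upstream landmark extractor.
A measured robustness check shows a 25-frame closure still detected at
`noise_sd = 0.5` units (~0.6 % of the eye width) with the default
thresholds.

## Box geometry and detection metrics

CIoU is computed with its full breakdown (IoU, squared center distance
ρ², squared enclosing diagonal c², aspect term v, weight α). α is
defined as 0 when v = 0, the continuous limit of the 0/0 form at a
perfect match. Although the aspect term names ground truth and
prediction, it squares the arctan difference, so every CIoU term is
invariant under argument swap. On valid boxes `ρ²/c² < 1` and `αv < 1`,
giving the bounds `−2 < CIoU ≤ 1` and `0 ≤ L_CIoU < 3`; CIoU does dip
below −1 for distant boxes with unlike aspect ratios.

AP uses all-point interpolation (the exact area under the running
precision envelope), not 11-point sampling, matching the integral
definition. Matching is greedy in descending confidence (ties keep
input order) against the highest-IoU unmatched ground truth at
IoU ≥ 0.5 (configurable). mAP averages the five face-feature classes;
classes with no ground-truth instances are excluded with a warning.
Zero-denominator precision/recall are defined as 0 with a warning.

## Numerical and testing notes

- All ratio computations are closed-form; the only iterative procedures
  are the bisections in `scripts/acceptance.py`, run to an interval
  width of 1e−9 on the ratio axis and reported to 1e−6.
- Test problem sizes: simulated sequences of 150–300 frames, randomized
  property checks with a few hundred draws, and brute-force oracles
  (run enumeration for verdicts, exhaustive confidence-cutoff
  enumeration with 2×10⁴-point grid integration for AP) on sequences
  ≤ 300 frames and ≤ 5 detections. The full suite runs in a few
  seconds on one CPU.
- Published per-class recognition rates reproduce from their instance
  counts under truncation to three decimals (e.g. 28 690 / 28 870 =
  0.99377 → 0.993), which the arithmetic tests assert explicitly.

## Limitations

The package consumes landmark output; it does not run a face-mesh
network, estimate head pose, or smooth landmarks beyond the validity
flag. The P80 per-blink openness variant of PERCLOS is not computed —
the cycle score here is the fraction of fully-closed frames, with a
mouth analogue for yawning. Frame-rate is never inferred from data;
durations in seconds are converted only through the configured fps.
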