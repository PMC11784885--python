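# drowsekit

Driver-fatigue detection from facial landmark kinematics.

Monitoring systems for drowsy driving track two involuntary facial
behaviours: sustained eyelid closure and yawning. Given a per-frame
stream of 468-point facial meshes (the index convention emitted by
Attention-Mesh-style landmark extractors), `drowsekit` computes the eye
and mouth aspect ratios, segments the resulting boolean time series into
blink/closure and yawn episodes, scores PERCLOS per unit cycle, and
classifies each cycle as *normal* or *fatigued* driving. It is aimed at
researchers and engineers who already have a landmark extractor and a
face-feature detector and need the decision layer — plus the evaluation
mathematics (CIoU box geometry, AP/mAP) to score the detector itself.

## The model

**Aspect ratios.** With `Y_k`, `X_k` the vertical/horizontal coordinates
of mesh point *k*:

```
EAR_right = (|Y384−Y381| + |Y386−Y374| + |Y388−Y390|) / (3·|X362−X263|)
EAR_left  = (|Y161−Y163| + |Y159−Y145| + |Y157−Y154|) / (3·|X33−X133|)
EAR       = (EAR_left + EAR_right) / 2
MAR       = (|Y39−Y181| + |Y0−Y17| + |Y269−Y405|)  / (3·|X61−X291|)
```

EAR collapses toward 0 as the eye closes; MAR rests near 0.2–0.3 for a
closed mouth and plateaus near 1.1 during a yawn.

**Per-frame states.** A frame is closed-eye when `EAR < 0.02` and
yawning when `MAR > 0.65` (strict comparisons). When a feature detector
supplies per-frame class labels, yawning requires `o_mouth ∧ (MAR >
0.65)` and eye closure is `c_eyes ∨ (EAR < 0.02)`.

**Episodes and PERCLOS.** Maximal runs of a state form half-open
episodes `[start, end)` with duration `F_e = F_ej − F_ei` (eyes) or
`F_m` (mouth). Within a unit cycle of `F0 = 150` frames, `P_eyes` is
the summed closed-eye episode overlap divided by `F0`; `P_mouth` is the
yawn analogue. A cycle is **fatigued** iff any criterion holds:

```
P_eyes ≥ 0.15   ∨   P_mouth ≥ 0.15   ∨   F_e ≥ 20   ∨   F_m ≥ 30
```

**Detector evaluation.** `CIoU = IoU − ρ²/c² − αv` with
`v = (4/π²)(arctan(ω_gt/h_gt) − arctan(ω/h))²`, `α = v/(1−IoU+v)`, and
loss `L_CIoU = 1 − IoU + ρ²/c² + αv`; precision/recall, all-point
interpolated AP and mAP over the five face-feature classes (`face`,
`o_eyes`, `c_eyes`, `o_mouth`, `c_mouth`) with greedy confidence-ordered
matching.

A synthetic facial-kinematics generator (`drowsekit.synthetic`)
renders landmark sequences with scripted blink/closure/yawn events and
exact ground truth, so the whole pipeline is verifiable without video
data.

## Worked example

```python
from drowsekit import (EventSpec, SimulationConfig, simulate,
                       classify_sequence)

cfg = SimulationConfig(
    n_frames=300,
    events=(EventSpec("closure", 60, 25), EventSpec("yawn", 180, 40)),
)
frames, truth = simulate(cfg)
cycles, overall = classify_sequence(frames)
for c in cycles:
    print(f"[{c.f_start:3d},{c.f_end:3d})  p_eyes={c.p_eyes:.4f}  "
          f"p_mouth={c.p_mouth:.4f}  fe={c.fe:2d}  fm={c.fm:2d}  "
          f"{c.verdict}  {sorted(c.triggered)}")
print("overall:", overall)
```

prints

```
[  0,150)  p_eyes=0.1667  p_mouth=0.0000  fe=25  fm= 0  fatigued  ['fe', 'perclos_eyes']
[150,300)  p_eyes=0.0000  p_mouth=0.2667  fe= 0  fm=40  fatigued  ['fm', 'perclos_mouth']
overall: fatigued
```

The 25-frame closure in the first cycle fires both the consecutive-frame
criterion (`fe = 25 ≥ 20`) and the eye PERCLOS criterion
(`25/150 ≈ 0.167 ≥ 0.15`); the 40-frame yawn in the second cycle fires
the yawn analogues. Either fatigued cycle makes the overall verdict
fatigued.

The same pipeline runs from the shell:

```sh
drowsekit simulate --out frames.csv --event closure:60:25
drowsekit detect frames.csv --out report.csv      # exit code 3 = fatigued
drowsekit eval detections.csv ground_truth.csv    # per-class AP and mAP
```

`detect` writes a per-cycle report (CSV plus a JSON sidecar carrying a
full provenance block: thresholds, input digest, package version) and
signals a fatigued verdict through exit code 3 so alerting wrappers need
not parse output. All thresholds are overridable by flags
(`--ear-closed`, `--mar-yawn`, `--f0`, `--perclos`, `--fe`, `--fm`).

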