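# condylefit

Anatomically landmarked 3D kinematic leg modeling for walking *Drosophila*.

Legs are modeled as serial kinematic chains whose main (yaw) joint rotation
axes are derived from the positions of the joint condyles, giving oblique,
anatomically informed axes instead of the usual segment-orthogonal ones.
The package covers the full pipeline:

- **`condylefit.camera`** — pinhole cameras with 3 radial + 2 tangential
  distortion coefficients, iterative undistortion, and SVD (DLT)
  triangulation of multi-view 2D keypoints.
- **`condylefit.body`** — the fly-specific right-handed body coordinate
  system built from the scutellum apex (ThAp) and the wing hinges, with the
  skewed anterior axis de-skewed by a reflection construction.
- **`condylefit.model`** — per-leg kinematic chains from condyle landmarks
  (yaw along the condyle pair, roll along the controlled segment,
  pitch = yaw x roll), initial-posture straightening about yaw axes,
  local coordinate systems and Denavit–Hartenberg parameters, forward
  kinematics, per-fly scaling, a freely adjustable tarsus length, and the
  orthogonalized control variant (yaw axes snapped to the nearest body axis,
  segments linearized straight down).
- **`condylefit.ik`** — frame-by-frame inverse kinematics by bounded,
  weighted trust-region-reflective least squares with per-joint
  initialization and warm starts; default joint-angle constraints for both
  model variants ship as data files.
- **`condylefit.gait`** — treadmill-ball center estimation (100x penalty for
  tips inside the sphere), swing/stance thresholding, lift-off/touchdown
  events, and phase normalization onto a 100-sample time base.
- **`condylefit.analysis`** — model error (µm), composite-Simpson AUC,
  angle post-processing and left/right mirroring, range of motion,
  femur–tibia plane rotation, and the selective-DOF-update (ablation)
  experiment.
- **`condylefit.synthetic`** — ground-truth generators: six-legged
  bilaterally symmetric landmark sets with configurable axis obliquity,
  periodic walking simulation with exact ball contact during stance,
  camera rigs, and noisy 2D renderings.

## CLI

```bash
condylefit simulate --seed 7 --out scenario/          # synthetic fly + walking data
condylefit fit --landmarks scenario/landmarks.json \
               --keypoints scenario/keypoints.csv \
               --legs R2 --out fit.csv                # inverse kinematics
condylefit phases --keypoints scenario/keypoints.csv --out events.csv
condylefit analyze --fit fit.csv --phases events_labels.csv --out report/
```

## Conventions

- Global/body 3D coordinates in mm; model error reported in µm; angles in
  degrees at every public interface (radians internally).
- Yaw axis sign follows `condyle_b - condyle_a` as stored in the landmark
  file; left legs mirror right-leg geometry across the body sagittal plane,
  and left yaw/roll angle bounds and signs are inverted.
- All-zero angles denote the straightened (extended) reference posture.
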