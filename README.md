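# endonav

Simulation-testable toolkit for marker-based augmented-reality navigation in
endoscopic skull-base surgery. It implements two complete tracking/overlay
pipelines and the evaluation protocol to compare them on a synthetic phantom
with known ground truth:

* **On-board system** — a tracking camera rigidly mounted on the endoscope
  observes a planar fiducial board fixed to the patient holder.
  Registration is automatic: the face is reconstructed from the depth
  stream, aligned to the segmented CT surface with a prior-initialized
  robust point-to-plane ICP (Tukey biweight, distance-gated
  correspondences), and the registration is persisted on the board so a
  single per-frame board pose drives the AR overlay.
* **IR-tracked comparator** — an external infrared tracker observes
  reflective bodies on the endoscope and the holder; registration is
  point-based (closed-form Procrustes) from pointer-sampled fiducials.

Accuracy is measured as **projected target registration error (TRE)**: the
distance between the true targets and their overlay, converted to
millimetres at each target's true depth.

## Layout

| module | contents |
| --- | --- |
| `endonav.geometry3d` | SE(3) transforms, pose error, seeded random poses, 4×4 JSON I/O |
| `endonav.camera` | pinhole + Brown–Conrady model, projection/back-projection, planar intrinsic calibration, planar pose estimation, depth-map I/O |
| `endonav.fiducial_board` | board geometry, detections, occlusion-tolerant board pose |
| `endonav.calibration` | two-camera extrinsic calibration from paired board poses (chordal averaging) |
| `endonav.registration` | point clouds/meshes, normal estimation, robust point-to-plane ICP, Procrustes, registration-to-board composition |
| `endonav.ir_baseline` | tracker frames, pointer sampling, fiducial registration, IR overlay chain |
| `endonav.overlay_eval` | overlay chains, projected TRE, the seeded two-system comparison experiment |
| `endonav.phantom_sim` | parametric phantom (face surface, 1 cm target grid, seven base fiducials), depth rendering, board/tracker observation models, seeded noise |
| `endonav.meshio` | PLY/STL readers and writers |

## CLI

```sh
endonav simulate --out fixtures --seed 1          # phantom fixture set
endonav calibrate --pairs pairs.json --out extrinsic.json
endonav register --mesh ct.ply --depth depth.png --prior prior.json --out reg.json
endonav track --board board.yaml --detections dets.csv \
              --intrinsics intr.json --out poses.json
endonav evaluate --targets targets.csv --truth-chain truth.json \
                 --estimated-chain est.json --intrinsics intr.json --out tre.json
endonav compare --reps 100 --seed 1 --out results/ [--plot]
```

`compare` runs both systems end-to-end per seeded repetition (calibration →
registration → tracking → overlay) on the same phantom instance and writes a
per-repetition CSV, a JSON summary, and the config used. All noise
magnitudes, geometry, and board layouts live in the experiment YAML
(`ExperimentConfig`); every command takes a seed and every random draw is
derived from it.

## Python API sketch

```python
from endonav import (ExperimentConfig, run_comparison_experiment)

result = run_comparison_experiment(ExperimentConfig(), n_repetitions=100, seed=1)
print(result.summary())   # {'ours': {...}, 'ir': {...}, 'ours_better': True, ...}
```
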