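# lapreg

Rigid registration and accuracy evaluation for laparoscopic image-guided
liver surgery, with a synthetic-scene simulator so the whole chain is
testable without clinical data.

The package covers the computational core of a surface-based guidance
pipeline:

- **Stereo surface reconstruction** — pinhole stereo model, two-view
  triangulation of pixel correspondences into labelled 3D point clouds
  (`lapreg.stereo`).
- **Segmentation gate** — filtering reconstructed points down to
  liver-labelled ones before registration, with a configurable oracle error
  rate standing in for a learned classifier (`lapreg.gate`).
- **Registration** — point-to-point ICP against the preoperative liver
  model (exact closest-point-on-mesh correspondences, Kabsch/SVD core,
  Besl–McKay extrapolation, monotone residual history), plus a manual
  passthrough mode and an explicit registration-failure contract
  (`lapreg.icp`).
- **Accuracy** — landmark target registration error (TRE): per-frame
  landmark distances summarised as mm RMS (`lapreg.tre`).
- **Cohort statistics** — mean ± sample SD, Shapiro–Wilk (own Royston
  implementation), pooled and paired t-tests with 95% CIs; a packaged
  per-patient TRE table (`table3`) ships for regression (`lapreg.cohort`).
- **Synthetic scenes** — seeded lobulated-ellipsoid livers, a diaphragm-like
  distractor sheet at controlled clearance, curvature-extremum landmarks,
  visibility-correct stereo observations (`lapreg.scene`, `lapreg.mesh`).
- **Pipeline & I/O** — ASCII PLY/OBJ meshes, labelled-cloud PLY/CSV,
  landmark/correspondence/cohort CSVs, JSON transforms and reports, and a
  replayable batch pipeline with a hash manifest (`lapreg.io`,
  `lapreg.pipeline`).

Units are millimetres and coordinates right-handed throughout. All
randomness flows from explicit integer seeds; identical seeds give
bit-identical outputs.

## CLI

A single `lapreg` entry point with subcommands:

```sh
lapreg simulate  --seed 1 --out scene/                # scene + stereo observation
lapreg reconstruct --rig scene/rig.json --camera-pose scene/camera_pose.json \
                 --correspondences scene/correspondences.csv --out cloud.ply
lapreg gate      --cloud cloud.ply --out gated.ply    # keep liver-labelled points
lapreg register  --mode semiauto --mesh scene/liver_model.ply \
                 --cloud gated.ply --init init.json --out reg.json
lapreg evaluate  --registration reg.json --model-landmarks scene/model_landmarks.csv \
                 --frames frames.csv --out tre.json
lapreg stats     --fixture table3                     # packaged cohort regression
lapreg run       --config config.json --out run/      # full batch pipeline
lapreg benchmark --n-seeds 20                         # gating-vs-passthrough A/B
```

Exit codes: `0` success, `3` registration failure, `4` I/O or format error,
`5` schema/config error.

`register --mode manual` implements the manual-registration contract: the
supplied pose *is* the final transform. `--mode semiauto` refines it by ICP
and raises the failure signal (exit 3, partial result in the output JSON)
when the fit does not converge or lands above the failure RMS threshold.

## Notes on statistical conventions

Group summaries use the sample SD (n−1). The between-phase comparison is a
pooled-variance independent t-test (df = n1+n2−2); the within-phase-2
manual-vs-semiautomatic contrast is reported both paired-by-patient and
pooled-independent. See `lapreg/cohort.py` for why these variants are
pinned.
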