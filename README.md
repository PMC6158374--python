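# capsdecode

Reconstruct 28×28 visual stimuli (digit-like glyphs, classes '6' and '9')
from fMRI-like voxel responses. The pipeline has two training stages and an
inference chain:

1. **Capsule network** (`capsdecode.capsnet`) — two convolutions build 1152
   8-D primary capsules that are dynamically routed (3 iterations of routing
   by agreement) into one 16-D capsule per class. Trained end to end with a
   margin loss on capsule norms plus a weighted reconstruction MSE through a
   three-layer sigmoid decoder (μ = 4.0, batch 10, Adam). The capsule norm
   predicts class; the capsule components carry pose/scale/stroke
   information, so the decoder can reproduce the input image.
2. **Voxel selection** (`capsdecode.encoding`) — each voxel is regressed
   (OLS with intercept) on the 16 components of the longer class capsule;
   voxels are ranked by in-sample R² and the top 100 of 3092 retained.
3. **Voxel-to-capsule mapper** (`capsdecode.mapper`) — a 100→256→128→32
   fully connected network (ReLU, ReLU, linear; output split into two 16-D
   halves, each squashed), trained with Adam (lr 1e-4, batch 10, ~10k
   iterations) against the frozen capsule network's capsules, with L2
   penalties on the first two layers.

Inference (`capsdecode.pipeline.reconstruct_from_fmri`): voxel vector →
selection mask → mapper → take the longer predicted capsule → decode.
Evaluation runs stratified 10-fold cross-validation (selection and mapper
refit per fold) and reports MSE, Pearson correlation and SSIM per item,
plus "theoretical" reconstructions decoded from the true capsules.

Everything runs on synthetic data: `capsdecode.synthetic` renders
parametric glyphs and simulates voxel responses that are a noisy linear
function of capsule features on a known informative subset, so selection,
mapping and reconstruction can all be validated by parameter recovery. An
IDX-format reader is included for real digit archives.

The networks run on a small NumPy reverse-mode autodiff engine
(`capsdecode.autodiff`) — no GPU or deep-learning framework required; all
gradients are exact and finite-difference checked.

## CLI

```sh
capsdecode print-config > config.json           # all defaults, editable
capsdecode simulate      --run-dir run --config config.json
capsdecode train-capsnet --run-dir run --config config.json
capsdecode select-voxels --run-dir run --config config.json
capsdecode train-mapper  --run-dir run --config config.json
capsdecode evaluate      --run-dir run --config config.json   # metrics.csv
capsdecode reconstruct   --run-dir run --item 3
capsdecode interpret     --run-dir run --dimension 1
```

Stages write HDF5/CSV/PNG artifacts into `--run-dir` and append a
provenance line (stage, config hash) to `run.log`; a stage run before its
dependencies fails with the name of the missing stage.

`interpret` exports a perturbation sweep (decode the capsule with one
dimension offset from −0.5 to +0.5) and a voxel×32 gradient-attribution
heat map of the mapper.

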