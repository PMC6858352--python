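# fluoromap

Whole-image tumor detection for two-channel fluorescence microscopy of lymph
nodes, built as a tested, reusable pipeline:

1. **synthetic data** — pseudo-fluorescence frames with ground-truth tumor
   masks: dense blue lymphocyte nuclei, metastatic lesions (large cells,
   green cytoplasm, bright nucleoli; glandular / cribriform / solid
   patterns), and histiocyte-nodule confounders that are never in the mask.
2. **patch pipeline** — non-overlapping 278 × 278 tiling, scalar-max
   normalization, asymmetric labeling (tumor-containing patches from
   positive nodes are positive; tumor-free patches from positive nodes are
   *excluded*, never negative), and node-grouped train/validation/test
   splits with no leakage.
3. **classifier** — a pluggable patch-classifier contract with two
   implementations: a from-scratch numpy CNN (4 conv blocks → global
   average pooling → dropout 0.5 → 2-node softmax) trained with two-phase
   SGD (head first, then all weights) and min-validation-loss
   checkpointing, and a position-keyed noisy oracle with exact
   false-positive / false-negative rates for testing the mapping machinery.
4. **mapper** — mirror padding by half a window (139 px), strided 278 × 278
   window classification, probability rounding, and center-pixel assignment
   into a binary prediction map. The canonical 2,592 × 2,048 frame pads to
   2,870 × 2,326 and yields a 260 × 205 map (53,300 predictions) at step 10.
5. **majority filter** — a strict-threshold windowed vote (27 / 8 / 4 map
   pixels for steps 10 / 35 / 70) that removes sparse misclassifications
   and crops the mirrored border, plus the any-positive-pixel image call
   and a threshold-sweep evaluation table.
6. **pipeline / CLI** — end-to-end orchestration, overlay rendering, and
   the error-budget arithmetic (53,300 windows × (1 − 0.988) ≈ 640).

Everything runs on one CPU with no downloads; the synthetic generator makes
all stages testable end to end.

## CLI

One entry point with per-stage subcommands:

```bash
fluoromap synth --out data/ --n-pos 4 --n-neg 4 --nodes-per-class 2 --seed 1
fluoromap patchify --manifest data/manifest.csv --out patches.csv
fluoromap train --manifest data/manifest.csv --out model.npz --seed 1
fluoromap map --image data/image_0000.png --mask data/mask_0000.png \
    --step 70 --out map.png          # omit --model to use the exact oracle
fluoromap vote --map map.png --threshold 0.7 --out decided.png --report r.json
fluoromap sweep --maps-dir maps/ --manifest data/manifest.csv --out table.csv
fluoromap run-all --config run.yaml --out run/ --seed 1
```

`fluoromap map` writes the grid as a 0/255 PNG plus a JSON sidecar with the
geometry metadata (step, pad, source dims, fencepost convention). A
`--grid-convention truncate` compatibility flag reproduces the alternative
off-by-one axis count for comparison; the fencepost convention
(`floor((L − 278)/step) + 1`) is canonical because it reproduces the
53,300-prediction identity.

## Library use

```python
from fluoromap import (SceneSpec, generate_image, MapperConfig, build_map,
                       MajorityConfig, majority_vote, decide_image,
                       noisy_oracle, NoisyOracleConfig)

image = generate_image(SceneSpec(width=560, height=560, n_lesions=1, seed=0))
pmap = build_map(image, noisy_oracle(image, NoisyOracleConfig(0.012, 0, 1)),
                 MapperConfig(step=70))
filtered = majority_vote(pmap, MajorityConfig.for_step(70, threshold=0.7))
print(decide_image(filtered).image_call)
```
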