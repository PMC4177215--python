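# visenc

Voxelwise encoding models and identification analysis for visual fMRI.

`visenc` implements the classic encoding/identification workflow for
stimulus-driven cortical responses: grayscale images are decomposed by a
Gabor wavelet pyramid, each voxel of a target region (e.g. early retinotopic
cortex, V1/V2/V3) is modelled as a linear function of the feature channels,
and trained models are scored by *identification* — matching each observed
test-set activity pattern to the predicted pattern it correlates with best.
The same linear machinery also fits *region-to-region* models, where the
input channels are another region's voxel patterns (e.g. the lateral
occipital complex) instead of stimulus features, and the two kinds of
prediction can be fused by averaging.

## The model

For a voxel with responses `y` (one amplitude per stimulus) and input
channels `X` (stimuli × channels),

    y = X h + c + noise

with kernel `h` and intercept `c`.  `X` is either the log-magnitude Gabor
feature matrix of the stimuli (stimulus encoding model) or a source region's
response matrix (region-to-region model).  Kernels are estimated by
full-batch gradient descent from zero with **early stopping**: 20% of the
training stimuli form a held-out stopping set, and the kernel snapshot with
the lowest stopping-set error is kept, shrinking coefficients before
over-fitting sets in.  A bootstrap loop (10 rounds) resamples the remaining
rows and averages the resulting kernels.

Identification builds the P×P Pearson correlation matrix between P predicted
and P observed test patterns (correlated across voxels); test image *m* is
identified correctly when the diagonal entry of column *m* is the strict
column maximum.  Chance accuracy is 1/P.

The default Gabor pyramid covers a 128×128 image with six frequencies
(1–32 cycles/field-of-view) × eight orientations on frequency-matched grids
plus a luminance channel: (1 + 2² + 4² + 8² + 16² + 32²) × 8 + 1 = 10,921
wavelets.

Because the original fMRI recordings are an external download, the package
ships a synthetic-data generator (`visenc.simulate`) that reproduces the
statistical structure the analysis assumes — sparse localized kernels,
per-voxel signal-to-noise ratios, repeat-averaged test responses, and a
source region that linearly mixes the target region's noise-free signal —
so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from visenc import (PyramidConfig, TrainConfig, NoiseSpec, DesignMatrix,
                    build_pyramid, featurize, generate_images, generate_erc,
                    fit_region, predict, correlation_matrix, identify)

cfg = PyramidConfig(frequencies=(1, 2, 4, 8))        # 681 channels
pyramid = build_pyramid(cfg)
images = generate_images(860, 128, "pink_noise", seed=0)
ids = [f"train_{i}" for i in range(800)] + [f"test_{i}" for i in range(60)]
features = featurize(images, pyramid, cfg, stimulus_ids=ids)

train, test, truth = generate_erc(features, n_train=800, n_voxels=60,
                                  noise=NoiseSpec(snr=2.0), seed=0)
X_train = DesignMatrix(features.values[:800], features.channel_ids, ids[:800])
X_test = DesignMatrix(features.values[800:], features.channel_ids, ids[800:])

model = fit_region(X_train, train, TrainConfig(seed=0))
result = identify(correlation_matrix(predict(model, X_test), test))
print(f"{result.n_correct}/{result.n_images} correct "
      f"({result.accuracy_percent()}), chance {100/result.n_images:.1f}%")
```

Output:

```
60/60 correct (100.0%), chance 1.7%
```

i.e. every one of the 60 held-out test images is identified from the
predicted 60-voxel activity pattern, against a 1.7% chance level.

The same analysis is available from the shell:

```bash
visenc pipeline --config examples/pipeline.yaml --seed 0 --out-dir run/
visenc simulate --out-dir data/ --seed 0
visenc fit --design data/features.h5 --responses data/erc_train.h5 --out model.h5
visenc identify --pred pred.h5 --obs data/erc_test.h5 --out result.json
```

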