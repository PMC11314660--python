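# echotherm

Non-invasive temperature monitoring for microwave hyperthermia from B-mode
ultrasound image sequences.

Thermal therapy needs real-time knowledge of tissue temperature: mild
hyperthermia targets 41–45 °C, thermo-ablation 46–60+ °C, and both must spare
surrounding tissue. Thermocouples are accurate but invasive; MRI thermometry
is slow and expensive. Ultrasound B-mode images, however, change with
temperature — echo intensity and texture drift as the speed of sound and
scattering change — and most clinical scanners already produce them.
`echotherm` turns an 8-minute B-mode recording plus a 1 Hz reference
temperature trace into a trained regressor that reads temperature (25–65 °C)
directly off image texture. It is written for researchers building
image-based thermometry pipelines: phantom and ex-vivo studies, method
comparisons, and synthetic validation.

## Method

1. **Texture features.** Frames are fused to 1 Hz (block averaging), mean
   filtered, and reduced to a 64×64 region of interest around the probe.
   From each patch the gray-level gradient co-occurrence matrix (GLGCM) is
   built: H(x, y) is the joint relative frequency of quantised gray level x
   and quantised Sobel gradient magnitude y at the same pixel. Per second the
   package computes average gray level Σₓ x Σ_y H(x, y), gray-level entropy
   −Σₓ HₓlnHₓ, mixture entropy −ΣΣ H ln H, inertia ΣΣ (x−y)²H, inverse
   difference moment ΣΣ H/(1+(x−y)²), and the gray-temperature gradient
   (T_{t+5}−T_t)/(AVGL_{t+5}−AVGL_t).

2. **Period decomposition.** The multichannel feature series X₁D is
   spectrally decomposed: A = Avg_channels(normalised |FFT(X₁D)|),
   f₁…f_k = argTopK(A), p_i = ⌈T/f_i⌉. Each selected period folds the series
   into a 2D tensor X₂D = Reshape_{p_i×f_i}(Padding(X₁D)) whose columns are
   successive heating cycles — motivated by the hypothesis that tissue
   constituents with different dielectric constants superimpose shorter
   heating periods on the main trend.

3. **Temporal regression.** A lightweight network (≈ 2k parameters,
   ≈ 0.008 MB) embeds 96-s windows, and per period applies a dual-branch
   attention block: a depthwise-convolutional branch with learned
   per-position gates for high-frequency local structure, and a softmax
   attention branch over pooled cycle summaries for low-frequency global
   structure. Branch outputs are fused, the k periods aggregated by
   softmax-amplitude weights, and a per-step head (plus a pointwise linear
   bypass) emits temperature in °C.

Because real recordings of this kind are rarely shareable, the package ships
a first-class synthetic generator (`echotherm.synthetic`): saturating
exponential heating curves, gray level linearly coupled to temperature,
injected sub-period modulations, multiplicative Rayleigh speckle — so the
entire chain is testable against known ground truth.

## Worked example

Simulate a small study, fit the model, and evaluate on held-out experiments:

```python
from echotherm.datasets import simulate_feature_dataset
from echotherm.model import TrainConfig
from echotherm.network import ModelConfig
from echotherm.train import split_experiments, train, evaluate

dataset = simulate_feature_dataset(16, seed=0)       # 16 heating experiments
train_set, test_set = split_experiments(dataset.features, 0.7, seed=0)

results = train(
    ModelConfig(),                                    # k=5 periods, 96-s windows
    TrainConfig(epochs=60, early_stopping=True, patience=8,
                train_stride=24, seed=0),
    train_set,
)
print(results.summary())
report = evaluate(results, test_set)
print(f"held-out RMSE {report.rmse:.3f} °C, MAE {report.mae:.3f} °C")
```

Output:

```
Temperature Regression Results
==========================================================
Backbone:                   temporal
Input channels:             5
Window length:              96
k periods:                  5
Embedding dim:              16
Blocks:                     2
Trainable parameters:       2055
Storage (float32, MB):      0.0078
Training experiments:       11
Epochs run:                 60
Final train MSE (std.):     0.00773
Best val MSE (std.):        0.00681  (epoch 56)
==========================================================
channels: average_gray_level, gray_level_entropy, mixture_entropy, inertia, inverse_difference_moment
held-out RMSE 0.854 °C, MAE 0.682 °C
```

The model recovers the simulated tissue temperature to sub-degree accuracy
on experiments it never saw, using ~2k parameters. `results.predict(fs)`
returns the per-second temperature estimates for one experiment;
`echotherm.render` draws predicted-vs-measured curves and 2D pseudocolor
temperature maps (sliding the ROI across the frame on a stride grid).

The same pipeline is scriptable from the shell:

```bash
echotherm run --config study.yaml --seed 0 --out runs/
echotherm simulate --out data/ --seed 1 --n 4
echotherm predict --model runs/run/train/model --features features.csv
```

`echotherm run` executes simulate → preprocess → features → train →
evaluate → render and writes a manifest with per-file checksums; reruns with
the same config and seed are byte-identical.

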