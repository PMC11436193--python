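# veinfeat

Unsupervised multi-scale Log-Gabor convolutional features for finger-vein
biometrics.

Finger veins are imaged with near-infrared light: hemoglobin absorbs NIR, so
vessels appear as dark curvilinear strokes on a brighter, noisy background.
`veinfeat` turns a vein ROI into a discriminative feature vector without any
labels or backpropagation, and evaluates identification and verification
performance under an open-set protocol. It is aimed at biometrics
researchers who want a light, fully deterministic baseline that trains on a
handful of images.

## The model

The feature extractor is a two-layer convolutional cascade whose kernels are
2D Log-Gabor filters, built in the polar frequency domain as the product of
a radial and an angular Gaussian:

```
logG(r, θ) = exp(−(ln(r/f₀))² / (2 (ln σᵣ)²)) · exp(−(θ−θ₀)² / (2 σθ²))
```

with center frequency `f₀ = 1/λ`, wavelengths `λ_S = W_min · M^(S−1)` for
scales `S = 1..N_scale`, candidate orientations `θ₀ = i·π/N_ori`, and
angular bandwidth `σθ = T·π/N_ori`. Defaults: `W_min = 2` px, `M = 2.2`,
`σᵣ = 0.55` (≈2 octaves per band), `T = 1.3`, 4 scales × 10 candidate
orientations, on 32×32 ROIs.

Training is purely statistical: for each scale, every training ROI is
filtered by all candidate orientations, each pixel votes for the
orientation with its strongest |Re| response, and the `n_S` most-voted
orientations are retained. With the default allocation `[2, 7, 7, 2]` the
retained set is *diamond*-shaped — many orientations at the mid scales that
carry the vein texture, few at the extremes — giving K₁ = K₂ = 18 kernels
per layer. The K₂ signed maps under each layer-1 parent are binarized at
zero and packed into one integer code map (weights 2^(k−1)); each code map
is split into 8×8 blocks whose value histograms are concatenated into a
sparse nonnegative vector of conceptual length 2^K₂·K₁·B. Matching is
Euclidean distance; identification is 1-NN; verification sweeps an accept
threshold to report FAR, FRR, the equal error rate (EER) and the ROC.

## Worked example

```python
from veinfeat import LogGaborNet, SyntheticSpec, make_arrays, evaluate

X, y = make_arrays(SyntheticSpec())        # 20 classes x 6 samples, 32x32
net = LogGaborNet()                        # diamond counts (2, 7, 7, 2)
report = evaluate(X, y, net, train_fraction=0.5, n_iterations=1, seed=1)
print(f"EER={report.eer:.3f}%  ACC={report.acc:.3f}%")
```

prints

```
EER=0.667%  ACC=100.000%
```

i.e. on the built-in synthetic benchmark every test probe is identified
correctly by its nearest neighbour (rank-1 accuracy 100%), and the
verification score distributions overlap so little that false acceptances
and false rejections balance at 0.667%. Training and testing use disjoint
finger identities (10 training classes select the orientations, the other
10 are scored).

The same workflow is available from the shell:

```
veinfeat synth data/                       # generate a labeled dataset
veinfeat train data/ model.zip --bypass-roi
veinfeat extract model.zip data/ features/ --bypass-roi
veinfeat evaluate data/ results/ --bypass-roi --iterations 1 --seed 1
veinfeat sweep data/ sweep.csv --parameter per_scale_counts \
    --grid '10,0,0,0;0,10,0,0;0,0,10,0;0,0,0,10;2,7,7,2' --bypass-roi
veinfeat bank render bank.png              # inspect the candidate filters
```

All filter parameters can also come from a flat `key = value` config file
(`--config run.cfg`); explicit flags override file values.

Raw (uncropped) finger images are supported through the `roi` subcommand /
`extract_roi`, which localizes the finger band with a Kirsch compass edge
detector binarized at mean-plus-kσ dynamic thresholds before resizing.

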