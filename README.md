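# ebdl — band-dependent learning for radar time–frequency data

`ebdl` is a Python library (plus a small CLI) for classifying time–frequency
representations (TFRs) of radar-sensed motion — micro-Doppler gait
signatures, contact-free vital-sign recordings — whose class-relevant
features are *band-dependent*: they live in specific frequency sub-bands
and at power scales that differ by orders of magnitude (torso vs feet,
breathing vs heartbeat).  Plain convolutional classifiers are biased toward
high-power regions and are translation invariant, so they under-use exactly
this structure.

The model is trained end to end from three parts:

1. **Trainable sub-band filters.**  M generalized-Gaussian profiles
   `g(f; μ, σ, β) = exp(−(|f−μ|/σ)^β)` scale the TFR per frequency bin on
   the axis normalized to [−1, 1].  Location μ and bandwidth σ are learned;
   the even shape exponent β (default 8) gives a flat passband with steep
   edges.  Each filter produces a "sub-view" of the input.
2. **A shared encoder.**  Every sub-view goes through the same CNN backbone
   and projection head and is L2-normalized onto the unit hypersphere.
3. **A proxy-based sub-view contrastive loss.**  Each (view, class) pair
   owns a trainable unit-norm proxy; the loss pulls an embedding toward its
   same-view same-class proxy, pushes it from same-view other-class
   proxies, and caps its similarity to other views' same-class proxies at
   zero so different sub-views capture different features.  Test-time
   classification returns the class of the most similar same-view proxy
   across all views.

The package includes the full preprocessing pipelines (segmentation,
Butterworth band-pass, two-sided STFT, log scaling, standardization,
magnitude/phase composition, class-balancing mix augmentation), metrics and
validation strategies (random split, filter-count sweep,
leave-one-subject-out), and synthetic generators that plant band-dependent
structure so everything is testable on one CPU with no downloads.  All
trainable parts run on a small self-contained numpy autodiff engine
(`ebdl.autodiff`) — there is no deep-learning framework dependency.

## Worked example

Train on a synthetic 4-class gait-like task — a strong shared torso ridge
at low frequency plus weak class-specific limb ridges at high frequency —
and evaluate on the held-out split:

```python
import numpy as np
from ebdl import (SyntheticConfig, TrainConfig, evaluate, gen_gait_like,
                  split_dataset, train)

cfg = SyntheticConfig(n_classes=4, samples_per_class=200, tfr_shape=(16, 64),
                      power_ratio_db=6.0, noise_sd=0.05, seed=1024)
samples = gen_gait_like(cfg)                    # 800 labeled 16x64 TFRs
split = split_dataset(samples, seed=1024)       # 7 : 1.5 : 1.5
tc = TrainConfig(filter_count=3, epochs=15, lr_encoder=1e-3,
                 lr_proxies=0.01, seed=1024)
ckpt = train(split, tc)                         # ~45 s on one CPU core
report = evaluate(ckpt, split.test)
print(f"test accuracy      {report.accuracy:.3f}")
print(f"balanced accuracy  {report.balanced_accuracy:.3f}")
print("filter centers mu  ", np.round(ckpt.model.bank.mu.data, 2))
print("filter widths sigma", np.round(ckpt.model.bank.sigma.data, 2))
```

```
test accuracy      1.000
balanced accuracy  1.000
filter centers mu   [-0.61  0.08  0.35]
filter widths sigma [1.29 1.13 1.25]
```

The model separates the four classes perfectly even though the
discriminative limb ridges carry 4x less power than the shared torso
ridge, and the third filter has drifted toward the high-frequency limb
band — inspect the learned bank with `ckpt.model.bank.plot()` or
`ckpt.model.bank.to_json()`.

The same workflow is available from the shell:

```sh
ebdl synth --task gait --config gait.yaml --out data/
ebdl train --data data/ --config train.yaml --out model.npz
ebdl eval  --checkpoint model.npz --data data/
ebdl sweep-filters --data data/ --m 1 6
ebdl inspect-proxies --checkpoint model.npz
```

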