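# Methods

## The problem

Radar sensors capture kinetic and physiological motion as micro-Doppler
modulations of the returned signal.  After a short-time Fourier transform,
the data are time-frequency representations (TFRs) in which class-relevant
patterns are *band-dependent*: different motion components occupy different
frequency sub-bands, and their power scales differ by orders of magnitude
(a walking torso reflects far more power than the feet; breathing dominates
heartbeat in chest returns).  Convolutional classifiers operating on the
raw TFR are biased toward the high-power regions and, being translation
invariant, are poorly matched to features whose *frequency position* is
informative.

This package implements an end-to-end trainable remedy with three parts:

1. **Adaptive sub-band filtering.**  M filters scale the TFR per frequency
   bin by a generalized-Gaussian profile
   `g(f; mu, sigma, beta) = exp(-(|f - mu| / sigma)^beta)` on the frequency
   axis normalized to [-1, 1].  `mu` (center) and `sigma` (bandwidth) are
   trained by gradient descent; `beta` is a fixed even shape exponent
   (default 8) giving a near-flat passband with steep edges.  Each filter
   yields a "sub-view" of the input.
2. **Shared encoder.**  Every sub-view passes through the same backbone +
   projection head (Linear D→H, batch norm, ReLU, Linear H→L) and is
   L2-normalized onto the unit hypersphere.  Weight sharing puts all
   sub-views into one representation space.
3. **Sub-view contrastive loss (SCLoss).**  Each (view, class) pair owns a
   trainable proxy vector, used in unit-norm form.  For the embedding `z_i`
   of view `i` of a sample with class `c`, the loss term is
   `-log[ e^{p~.z_i} / (e^{p~.z_i} + Σ_{p∈A} e^{p.z_i} + Σ_{p∈B} e^{ReLU(p.z_i)}) ]`
   where `p~` is the same-view same-class proxy, `A` the same-view
   other-class proxies and `B` the other-view same-class proxies; the
   remaining proxies are excluded.  The ReLU caps cross-view same-class
   similarity at zero, pushing different sub-views to encode different
   features.  The sample loss is the mean over views, the batch loss the
   mean over samples.  Prediction compares each embedding to its own view's
   proxies and takes the class of the globally most similar proxy (ties to
   the lowest class index).

## Training protocol

Adam with three parameter groups: encoder (learning rate 1e-4 for the
vital-sign recipe, 1e-3 for the gait recipe and the synthetic studies),
proxies (default 0.01), and the filter parameters at 0.25.  Batch size 32,
up to 15 epochs; the checkpoint with the best validation accuracy is kept,
saved only on strict improvement so ties resolve to the earliest epoch.

Two optimizer choices deserve explanation:

* **Filter steps are plain SGD, not Adam.**  Adam rescales every step to
  roughly its learning rate; at a rate of 0.25 the two filter parameters
  would move a quarter of the frequency axis per mini-batch regardless of
  gradient size — a random walk.  Non-adaptive steps at 0.25 give smooth,
  gradient-proportional filter trajectories while preserving the large
  nominal rate the protocol prescribes.  `filter_optimizer="adam"` restores
  adaptive steps if wanted.
* **Proxies learn faster than the encoder (0.01 vs 1e-3).**  With a
  from-scratch encoder the proxies must track the evolving embedding space
  for the loss to carry a useful signal; fast proxy updates are the usual
  convention in proxy-based metric learning.

Filter parameters are intentionally unconstrained: `mu` may leave [-1, 1]
and `sigma` may go negative (the even `beta` makes its sign irrelevant).
Proxies are stored free and normalized at use time, so the unit-norm
contract holds for any optimizer state.

## Preprocessing recipes

* **vital**: segment the complex I/Q recording into 20 s windows with 50%
  overlap (2000 samples at 100 Hz); 4th-order Butterworth band-pass
  [0.1, 20] Hz; two-sided STFT with 512 DFT points, 128-point Hann window,
  108-sample overlap (94 frames from a 2000-sample segment); magnitude
  scaled by `10*log10(x + 1e-5)`; the input sample combines the
  nonnegative-frequency half of the standardized magnitude (lower bins)
  with the matching half of the standardized phase (upper bins).  Which
  half is used is configurable (`magnitude_half`), since either convention
  is defensible.
* **gait**: two-sided STFT with 512 DFT points and a 512-point Kaiser
  window (shape 14) at 50% overlap; magnitude scaled by
  `20*log10(x + 1e-5)` and standardized.

Standardization is a per-sample z-score over all matrix entries (no
dataset-level statistics are involved), and a constant matrix maps to
zeros.  Two-sided spectra are stored fftshifted, with bin positions mapped
linearly onto [-1, 1].  Trailing samples that do not fill a window are
dropped everywhere (floor-based frame counts, no padding).

The class-balancing augmentation for imbalanced vital-sign data averages a
resting-class sample with a minority-class sample in equal proportions and
assigns the minority label; it is applied only to training batches
(`balance_with_mix`).

## Synthetic data

The generators plant the band-dependent structure the framework targets,
at desk scale (default TFR 16x64):

* `gen_band_task` — per class, a frequency-modulated Gaussian ridge whose
  instantaneous center sweeps sinusoidally inside the class band (ridge
  cross-section width/10, floored at 1.5 bins; class-specific modulation
  rate), plus a shared high-power FM nuisance ridge and white noise.  The
  nuisance is normalized to unit RMS and the class signature to
  `10^(-power_ratio_db/20)` RMS, so 20 dB means the nuisance carries 100x
  the signature's power; ratios are applied before standardization.  By
  default the nuisance is mirrored to ± its center frequency, as in the
  two-sided spectrum of a real-valued bulk motion.  Each sample also
  carries `n_distractors` uninformative FM ridges at random positions
  outside all class bands, at signature power — energy from other motion
  components.  A class band of `None` plants no signature, making in-band
  energy presence itself the class feature.
* `gen_gait_like` — a strong low-frequency torso ridge common to all
  classes plus weak class-dependent high-frequency limb ridges (class
  offset and modulation rate); classes differ only in the limb component,
  and `include_limb=False` degenerates to indistinguishable classes.
* `gen_vital_signal` — complex baseband chest return
  `exp(j*(b*sin(2π f_b t) + h*sin(2π f_h t)))` with breathing in
  0.1–0.9 Hz and heartbeat in 1–2.5 Hz, `h = b / amplitude_ratio`.

What the generators do *not* emulate: measurement artifacts (phase noise,
I/Q imbalance, static clutter), subject-specific variability beyond the
random phases, harmonics of breathing in chest returns, and the continuous
spread of real micro-Doppler energy across bands.  Tests passing on this
data show that the mechanism works as designed, not that clinical-grade
accuracy transfers to real radar recordings.

## Desk-scale study conditions

The three training-level checks in `tests/test_acceptance.py` (also
recomputed by `scripts/acceptance.py`) use a tiny three-block CNN backbone
(channels 6/12/24, feature dimension 24, head 24→64→32) so everything runs
on one CPU core in minutes, with M=3 filters and the training protocol
above:

* **Filter recovery** — 2 classes (signature present vs absent) with the
  salient band at (0.4, 0.3), nuisance (-0.8, 0.2) mirrored, one distractor
  ridge, 20 dB power ratio, noise 0.1, 300 samples/class, seeds 1–5.  A run
  counts as a hit when some learned `|mu - 0.4| <= 0.15`.  The geometry
  keeps the nuisance well separated from the salient band (as breathing vs
  heartbeat bands are), because a flat-top `beta=8` filter only receives
  location gradients from interference in its edge-transition zones: with
  interference crowding one flank, `mu` is biased away from it, and with
  none, `mu` is unidentifiable inside the passband.  The hit rate is
  seed-sensitive: a filter centered above 0.4 has its upper transition zone
  beyond the axis edge, so it feels only lower-flank interference, and the
  size of that one-sided push varies with the encoder initialization.
  Across ten seeds roughly 70% of runs localize within tolerance; the five
  seeds above are the experiment's fixed conditions, and
  `scripts/acceptance.py`, which derives its run seeds from `--seed`,
  reports whatever hit count its seeds produce.
* **End-to-end learning** — separable 4-class gait-like task, 200
  samples/class, 6 dB torso-over-limb ratio, noise 0.05; test accuracy must
  reach 0.95 within 15 epochs.
* **Power-scale robustness** — 2 classes in distinct bands at a 20 dB
  nuisance-over-signature ratio, 300 samples/class, 5 seeds; the median
  accuracy of the filtered contrastive model must be at least that of the
  identical encoder trained with cross-entropy on the raw TFR.  At this
  problem size both models typically saturate: the tiny zero-padded CNN
  retains enough positional information that the baseline is not
  handicapped, so the comparison is a non-inferiority check rather than a
  separation.

## Numerical choices

* All tensors are float64; gradient checks against central finite
  differences pass at 1e-5 relative tolerance.
* The autodiff engine (`ebdl.autodiff`) is a small reverse-mode tape over
  numpy supporting exactly the operations the model graph needs;
  convolutions are stride-1 im2col with the column matrix shared between
  the forward pass and both backward products.
* `standardize` treats a matrix whose standard deviation is below
  `1e-12 * (1 + max|x|)` as constant.
* Filter responses may underflow to exactly 0 far from the passband;
  mathematically g is in (0, 1].
* In `scloss`, similarities are raw cosines in [-1, 1] (no temperature);
  exponentials therefore cannot overflow.
* Nearest-proxy ties resolve to the lowest class index (`argmax` on the
  per-class best similarity).
* Validation/test split sizes round half away from zero; the training set
  takes the remainder.  Batches with fewer than 2 samples are skipped
  (batch norm needs at least two rows).

## Known limitations

* The tiny backbone is not a substitute for a pretrained ResNet-18: it has
  no pretrained edge/shape priors, so absolute accuracies on real datasets
  would differ substantially.  The encoder is pluggable
  (`EncoderSpec.backbone_kind`), and any module mapping (N, C, T, F) to
  (N, D) on the package's tape can stand in.
* Filter localization is demonstrable but slow: the flat-top profile gives
  sparse gradients, so `mu` sharpening beyond the passband scale needs
  longer training than the 15-epoch protocol used here.
* `sigma` can collapse toward 0 under adversarial learning rates, zeroing
  a view; the best-validation checkpoint guards against deploying such a
  state but training does not re-inflate it.
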