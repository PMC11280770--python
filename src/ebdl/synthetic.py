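"""Synthetic band-dependent classification tasks and vital-sign signals.

These generators plant the two difficulties the framework exists to handle:

* class-discriminative signatures confined to class-specific frequency
  sub-bands, superposed on a **shared high-power nuisance component** in a
  different band (the torso-vs-feet power contrast of micro-Doppler gait
  data), with a configurable nuisance-to-signal power ratio in dB;
* class signatures that are frequency-modulated ridges — their
  time-frequency pattern drifts inside the band — so a plain convolutional
  classifier cannot rely on translation invariance alone.

``gen_vital_signal`` produces the standard radar chest-return model: a
complex exponential whose phase is the sum of a breathing sinusoid
(0.1-0.9 Hz) and a faster, weaker heartbeat sinusoid (1-2.5 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tfr_pipeline import RadarSegment, TFRSample, normalized_freq_axis, standardize

__all__ = ["SyntheticConfig", "VitalSimConfig",
           "gen_band_task", "gen_vital_signal", "gen_gait_like"]


@dataclass
class SyntheticConfig:
    """A generatable band-dependent classification task.

    ``class_bands`` gives one (center, width) interval on the normalized
    frequency axis per class; a ``None`` entry plants no signature for that
    class (its samples carry only the nuisance and noise, so the presence of
    in-band energy is itself the discriminative feature).  Classes whose
    bands coincide are still distinguishable through class-specific
    modulation rates of the planted ridge.  ``power_ratio_db`` is the
    nuisance-to-signal power ratio (20 dB means the shared nuisance carries
    100x the class component's power).  With ``mirror_nuisance`` the
    nuisance appears at both +/- its center frequency, as in the two-sided
    spectrum of a real-valued bulk motion.
    """

    n_classes: int = 4
    samples_per_class: int = 200
    tfr_shape: tuple[int, int] = (16, 64)
    class_bands: list[tuple[float, float] | None] | None = None
    nuisance_band: tuple[float, float] = (-0.7, 0.3)
    mirror_nuisance: bool = True
    power_ratio_db: float = 20.0
    noise_sd: float = 0.1
    n_distractors: int = 2
    distractor_width: float = 0.2
    seed: int = 1024
    n_subjects: int = 10

    def __post_init__(self):
        if self.class_bands is None:
            # default: equal-width bands spread over the positive frequencies
            centers = (np.linspace(0.25, 0.85, self.n_classes)
                       if self.n_classes > 1 else np.array([0.4]))
            self.class_bands = [(float(c), 0.3) for c in centers]
        if len(self.class_bands) != self.n_classes:
            raise ValueError("need one (center, width) band per class")
        for band in [*self.class_bands, self.nuisance_band]:
            if band is None:
                continue
            center, width = band
            if width <= 0:
                raise ValueError("band widths must be positive")
            if not (-1 <= center - width / 2 and center + width / 2 <= 1):
                raise ValueError(f"band ({center}, {width}) leaves [-1, 1]")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")


def _fm_ridge(t_frames: int, freq_axis: np.ndarray, center: float, width: float,
              rate: float, phase: float) -> np.ndarray:
    """A frequency-modulated Gaussian ridge confined to one band.

    The instantaneous center sweeps sinusoidally inside the band; the
    cross-section is a Gaussian with sd = width/10 (floored at 1.5 frequency
    bins so the ridge is resolvable), and the sweep amplitude leaves a 3-sd
    margin so essentially all energy stays inside the band.
    """
    bin_spacing = float(freq_axis[1] - freq_axis[0])
    sd = max(width / 10.0, 1.5 * bin_spacing)
    swing = max(width / 2.0 - 3.0 * sd, 0.0)
    t = np.arange(t_frames)
    inst = center + swing * np.sin(2 * np.pi * rate * t / t_frames + phase)
    return np.exp(-((freq_axis[None, :] - inst[:, None]) ** 2) / (2 * sd ** 2))


def _assemble(class_comp: np.ndarray, nuisance: np.ndarray,
              power_ratio_db: float, noise_sd: float,
              rng: np.random.Generator) -> np.ndarray:
    """Fix relative powers, add white noise, and standardize.

    The nuisance is normalized to unit RMS and the class component to RMS
    10^(-dB/20), so the nuisance carries ``power_ratio_db`` more power than
    the class signature and the absolute noise level is identical for every
    class (including signature-free ones).  Power ratios are applied before
    standardization, which would otherwise erase global scale.
    """
    e_nui = np.sqrt(np.mean(nuisance ** 2))
    if e_nui > 0:
        nuisance = nuisance / e_nui
    e_sig = np.sqrt(np.mean(class_comp ** 2))
    if e_sig > 0:
        class_comp = class_comp * (10 ** (-power_ratio_db / 20) / e_sig)
    total = class_comp + nuisance
    if noise_sd > 0:
        total = total + rng.normal(0.0, noise_sd, size=total.shape)
    return standardize(total)


def _distractor_center(cfg: SyntheticConfig, rng: np.random.Generator) -> float:
    """A random band center avoiding every class band (the distractors model
    energy from other, uninformative motion components in other bands)."""
    half = cfg.distractor_width / 2
    for _ in range(200):
        center = rng.uniform(-1 + half, 1 - half)
        clear = all(b is None or abs(center - b[0]) > (b[1] + cfg.distractor_width) / 2
                    for b in cfg.class_bands)
        if clear:
            return center
    return center  # pathologically full axis: give up on exclusion


def gen_band_task(cfg: SyntheticConfig) -> list[TFRSample]:
    """Labeled TFRs with class-specific in-band FM ridges plus a shared
    high-power nuisance ridge; balanced classes, reproducible under seed.

    Each sample additionally carries ``n_distractors`` uninformative FM
    ridges at random out-of-class-band positions and the class signature's
    power, emulating energy from other motion components; reliable class
    evidence exists only inside the class bands.
    """
    rng = np.random.default_rng(cfg.seed)
    t_frames, f_bins = cfg.tfr_shape
    freq_axis = normalized_freq_axis(f_bins)
    nc, nw = cfg.nuisance_band
    sig_rms = 10 ** (-cfg.power_ratio_db / 20)
    samples = []
    for c in range(cfg.n_classes):
        band = cfg.class_bands[c]
        rate = 1.0 + c  # class-specific modulation rate: the discriminative pattern
        for k in range(cfg.samples_per_class):
            if band is None:
                sig = np.zeros((t_frames, f_bins))
            else:
                sig = _fm_ridge(t_frames, freq_axis, band[0], band[1], rate,
                                phase=rng.uniform(0, 2 * np.pi))
            nui = _fm_ridge(t_frames, freq_axis, nc, nw, rate=0.5,
                            phase=rng.uniform(0, 2 * np.pi))
            if cfg.mirror_nuisance:
                nui = nui + _fm_ridge(t_frames, freq_axis, -nc, nw, rate=0.5,
                                      phase=rng.uniform(0, 2 * np.pi))
            values = _assemble(sig, nui, cfg.power_ratio_db, cfg.noise_sd, rng)
            for _ in range(cfg.n_distractors):
                d = _fm_ridge(t_frames, freq_axis, _distractor_center(cfg, rng),
                              cfg.distractor_width, rate=rng.uniform(0.5, 3.0),
                              phase=rng.uniform(0, 2 * np.pi))
                d_rms = np.sqrt(np.mean(d ** 2))
                if d_rms > 0:
                    values = values + d * (sig_rms / d_rms)
            samples.append(TFRSample(
                values=standardize(values), freq_axis=freq_axis, label=c,
                subject_id=f"subj{(c * cfg.samples_per_class + k) % cfg.n_subjects:02d}"))
    return samples


def gen_gait_like(cfg: SyntheticConfig,
                  torso_band: tuple[float, float] = (0.0, 0.4),
                  limb_band: tuple[float, float] = (0.6, 0.35),
                  include_limb: bool = True) -> list[TFRSample]:
    """Gait-style TFRs: one strong low-frequency torso ridge common to all
    classes plus weak class-dependent high-frequency limb ridges.

    The classes differ *only* in the limb component (its center offset and
    modulation rate within ``limb_band``); with ``include_limb=False`` the
    generator degenerates to class-indistinguishable samples.
    """
    rng = np.random.default_rng(cfg.seed)
    t_frames, f_bins = cfg.tfr_shape
    freq_axis = normalized_freq_axis(f_bins)
    tc, tw = torso_band
    lc, lw = limb_band
    # class-specific limb centers spread inside the limb band
    offsets = (np.arange(cfg.n_classes) - (cfg.n_classes - 1) / 2)
    spread = 0.5 * lw / max(cfg.n_classes - 1, 1)
    samples = []
    for c in range(cfg.n_classes):
        for k in range(cfg.samples_per_class):
            torso = _fm_ridge(t_frames, freq_axis, tc, tw, rate=1.0,
                              phase=rng.uniform(0, 2 * np.pi))
            if include_limb:
                limb = _fm_ridge(t_frames, freq_axis,
                                 lc + offsets[c] * spread, lw / 2,
                                 rate=1.5 + 0.75 * c,
                                 phase=rng.uniform(0, 2 * np.pi))
            else:
                limb = np.zeros_like(torso)
            # torso is the "nuisance": high power, shared across classes
            values = _assemble(limb, torso, cfg.power_ratio_db, cfg.noise_sd, rng)
            samples.append(TFRSample(
                values=values, freq_axis=freq_axis, label=c,
                subject_id=f"subj{(c * cfg.samples_per_class + k) % cfg.n_subjects:02d}"))
    return samples


@dataclass
class VitalSimConfig:
    """Phase-modulated chest-return model for one monitoring scenario.

    The complex baseband signal is exp(j*(b*sin(2*pi*f_b*t) +
    h*sin(2*pi*f_h*t))): breathing depth ``b`` (radians) and heartbeat depth
    ``h = b / amplitude_ratio``.  Breathing must lie in 0.1-0.9 Hz and
    heartbeat in 1-2.5 Hz, the physiological bands.
    """

    fs: float = 100.0
    duration: float = 20.0
    breathing_hz: float = 0.25
    heartbeat_hz: float = 1.2
    amplitude_ratio: float = 5.0
    breathing_depth_rad: float = 2.0
    scenario: str = "resting"

    def __post_init__(self):
        if not 0.1 <= self.breathing_hz <= 0.9:
            raise ValueError("breathing_hz must lie in [0.1, 0.9] Hz")
        if not 1.0 <= self.heartbeat_hz <= 2.5:
            raise ValueError("heartbeat_hz must lie in [1, 2.5] Hz")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")

    @property
    def heartbeat_depth_rad(self) -> float:
        return self.breathing_depth_rad / self.amplitude_ratio


def gen_vital_signal(cfg: VitalSimConfig, label: int = -1,
                     subject_id: str = "sim") -> RadarSegment:
    """Complex I/Q chest return of length ``fs * duration`` samples."""
    n = int(round(cfg.fs * cfg.duration))
    t = np.arange(n) / cfg.fs
    phase = (cfg.breathing_depth_rad * np.sin(2 * np.pi * cfg.breathing_hz * t)
             + cfg.heartbeat_depth_rad * np.sin(2 * np.pi * cfg.heartbeat_hz * t))
    return RadarSegment(samples=np.exp(1j * phase), sampling_rate=cfg.fs,
                        subject_id=subject_id, label=label)
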