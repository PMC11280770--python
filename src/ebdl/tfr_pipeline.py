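"""Raw radar I/Q signals to standardized time-frequency samples.

Two preprocessing recipes are supported, matching the two sensing problems
the framework targets:

* **vital** — continuous-wave radar chest returns: segment into 20 s windows
  with 50% overlap, 4th-order Butterworth band-pass [0.1, 20] Hz, two-sided
  STFT (512-point DFT, 128-point Hann window, 108-sample overlap), then a
  composite sample built from half the log-scaled magnitude spectrogram and
  half the phase spectrogram along the frequency axis.
* **gait** — micro-Doppler gait signatures: two-sided STFT with a 512-point
  DFT and a 512-point Kaiser window at 50% overlap, magnitude scaled by
  ``20*log10(x + 1e-5)`` and standardized.

Spectrograms are stored fftshifted so the frequency axis runs from -fs/2
toward +fs/2 and is linearly normalized to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

__all__ = [
    "RadarSegment", "STFTConfig", "TFRSample", "DatasetSplit",
    "GAIT_STFT", "VITAL_STFT",
    "segment_signal", "bandpass_filter", "stft_spectrogram", "log_scale",
    "standardize", "compose_vital_sample", "mix_augment", "split_dataset",
    "normalized_freq_axis", "gait_sample_from_spectrogram",
]

LOG_EPS = 1e-5


@dataclass
class RadarSegment:
    """A contiguous stretch of complex (I/Q) radar samples."""

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    label: int = -1

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class STFTConfig:
    """Framing and window recipe for the short-time Fourier transform."""

    n_dft: int
    window_kind: Literal["hanning", "kaiser"]
    window_length: int
    overlap: int
    two_sided: bool = True
    kaiser_beta: float = 14.0  # sidelobe-suppression shape; unconstrained choice

    def __post_init__(self):
        if not (0 <= self.overlap < self.window_length <= self.n_dft):
            raise ValueError(
                "require 0 <= overlap < window_length <= n_dft, got "
                f"overlap={self.overlap}, window_length={self.window_length}, "
                f"n_dft={self.n_dft}")

    @property
    def hop(self) -> int:
        return self.window_length - self.overlap

    def window(self) -> np.ndarray:
        if self.window_kind == "hanning":
            return sps.get_window("hann", self.window_length, fftbins=True)
        if self.window_kind == "kaiser":
            return sps.get_window(("kaiser", self.kaiser_beta),
                                  self.window_length, fftbins=True)
        raise ValueError(f"unknown window kind {self.window_kind!r}")

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.window_length:
            raise ValueError(
                f"segment of {n_samples} samples is shorter than the "
                f"{self.window_length}-sample analysis window")
        return (n_samples - self.window_length) // self.hop + 1


# the two standard recipes
VITAL_STFT = STFTConfig(n_dft=512, window_kind="hanning", window_length=128, overlap=108)
GAIT_STFT = STFTConfig(n_dft=512, window_kind="kaiser", window_length=512, overlap=256)


@dataclass
class TFRSample:
    """A standardized T x F time-frequency matrix with its class label."""

    values: np.ndarray
    freq_axis: np.ndarray
    label: int
    channel_semantics: Literal["power", "magnitude_phase_composite"] = "power"
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.freq_axis = np.asarray(self.freq_axis, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x F matrix")
        if self.freq_axis.shape != (self.values.shape[1],):
            raise ValueError("freq_axis length must equal the number of frequency bins")
        if np.any(np.diff(self.freq_axis) <= 0):
            raise ValueError("freq_axis must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TFR values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class DatasetSplit:
    train: list[TFRSample]
    validation: list[TFRSample]
    test: list[TFRSample]
    ratios: tuple[float, float, float] = (0.7, 0.15, 0.15)


def normalized_freq_axis(n_bins: int) -> np.ndarray:
    """Bin centers of an fftshifted n-bin axis mapped linearly onto [-1, 1)."""
    return (2.0 * np.arange(n_bins) - n_bins) / n_bins


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def segment_signal(sig: RadarSegment, window_seconds: float,
                   overlap_fraction: float) -> list[RadarSegment]:
    """Cut a recording into fixed-length windows with fractional overlap.

    Trailing samples that do not fill a whole window are dropped; a signal
    shorter than one window yields an empty list.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    win_f = window_seconds * sig.sampling_rate
    win = int(round(win_f))
    if abs(win_f - win) > 1e-9:
        raise ValueError(
            f"window of {window_seconds} s is not a whole number of samples "
            f"at {sig.sampling_rate} Hz")
    hop = int(round(win * (1.0 - overlap_fraction)))
    if hop < 1:
        raise ValueError("overlap too large: hop collapses to zero samples")
    out = []
    for start in range(0, len(sig) - win + 1, hop):
        out.append(replace(sig, samples=sig.samples[start:start + win].copy()))
    return out


def bandpass_filter(seg: RadarSegment, low_hz: float, high_hz: float,
                    order: int = 4) -> RadarSegment:
    """Butterworth band-pass applied to the complex I/Q stream."""
    nyq = seg.sampling_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"cutoffs must satisfy 0 < low < high < fs/2, got "
            f"({low_hz}, {high_hz}) at fs={seg.sampling_rate}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=seg.sampling_rate, output="sos")
    filtered = sps.sosfilt(sos, seg.samples.real) + 1j * sps.sosfilt(sos, seg.samples.imag)
    return replace(seg, samples=filtered)


def stft_spectrogram(seg: RadarSegment, cfg: STFTConfig) -> np.ndarray:
    """Two-sided complex spectrogram, frames x n_dft, frequency-shifted.

    Frame count follows T = floor((N - window_length)/hop) + 1 with no
    padding or boundary extension; each windowed frame is zero-padded to
    n_dft before the DFT.  With ``two_sided`` the bins are fftshifted so the
    axis runs from -fs/2 toward +fs/2.
    """
    n = len(seg)
    t = cfg.n_frames(n)  # raises with the required minimum length
    hop = cfg.hop
    frames = sliding_window_view(seg.samples, cfg.window_length)[::hop][:t]
    spec = np.fft.fft(frames * cfg.window(), n=cfg.n_dft, axis=1)
    if cfg.two_sided:
        spec = np.fft.fftshift(spec, axes=1)
    return spec


def log_scale(values: np.ndarray, mode: Literal["gait", "vital"]) -> np.ndarray:
    """Decibel-style compression of nonnegative spectrogram magnitudes.

    gait: ``20*log10(x + 1e-5)``;  vital: ``10*log10(x + 1e-5)``.
    """
    values = np.asarray(values, dtype=np.float64)
    if np.any(values < 0):
        raise ValueError("log scaling requires nonnegative input")
    factor = {"gait": 20.0, "vital": 10.0}[mode]
    return factor * np.log10(values + LOG_EPS)


def standardize(values: np.ndarray) -> np.ndarray:
    """Per-sample z-score over all matrix entries; constant input maps to 0."""
    values = np.asarray(values, dtype=np.float64)
    sd = values.std()
    if sd <= 1e-12 * (1.0 + np.abs(values).max()):  # constant up to rounding
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def compose_vital_sample(spec: np.ndarray, label: int = -1, subject_id: str = "",
                         magnitude_half: Literal["positive", "negative"] = "positive",
                         ) -> TFRSample:
    """Build the magnitude/phase composite sample from a two-sided spectrogram.

    One half of the frequency axis carries the log-scaled standardized
    magnitude, the other half the standardized phase.  By default the
    nonnegative-frequency half of each part is used, magnitude in the lower
    output bins; ``magnitude_half='negative'`` flips which spectrum half is
    taken (either convention is defensible).
    """
    spec = np.asarray(spec)
    t, f = spec.shape
    if f % 2:
        raise ValueError("composite sample requires an even number of frequency bins")
    half = f // 2
    # fftshifted layout: bins [0, half) are negative frequencies, [half, f) nonnegative
    sel = slice(half, f) if magnitude_half == "positive" else slice(0, half)
    mag = standardize(log_scale(np.abs(spec[:, sel]), mode="vital"))
    phase = standardize(np.angle(spec[:, sel]))
    values = np.concatenate([mag, phase], axis=1)
    return TFRSample(values=values, freq_axis=normalized_freq_axis(f), label=label,
                     channel_semantics="magnitude_phase_composite",
                     subject_id=subject_id)


def gait_sample_from_spectrogram(spec: np.ndarray, label: int = -1,
                                 subject_id: str = "") -> TFRSample:
    """Log-scale and standardize a two-sided magnitude spectrogram (gait recipe)."""
    values = standardize(log_scale(np.abs(np.asarray(spec)), mode="gait"))
    return TFRSample(values=values, freq_axis=normalized_freq_axis(values.shape[1]),
                     label=label, subject_id=subject_id)


def mix_augment(resting: TFRSample, minority: TFRSample) -> TFRSample:
    """Equal-proportion mix of a resting sample with a minority-class sample.

    The augmented sample inherits the minority label; this class-balancing
    augmentation is meant for training batches only.
    """
    if resting.values.shape != minority.values.shape:
        raise ValueError(
            f"shape mismatch: {resting.values.shape} vs {minority.values.shape}")
    return TFRSample(values=0.5 * resting.values + 0.5 * minority.values,
                     freq_axis=minority.freq_axis.copy(),
                     label=minority.label,
                     channel_semantics=minority.channel_semantics,
                     subject_id=minority.subject_id)


def split_dataset(samples: Sequence[TFRSample],
                  ratios: tuple[float, float, float] = (0.7, 0.15, 0.15),
                  seed: int = 1024) -> DatasetSplit:
    """Seeded shuffle then train/validation/test partition.

    Validation and test sizes are rounded to the nearest integer (half away
    from zero) and the training set takes the remainder.
    """
    r = np.asarray(ratios, dtype=float)
    if np.any(r < 0):
        raise ValueError("ratios must be nonnegative")
    r = r / r.sum()
    n = len(samples)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(np.floor(n * r[2] + 0.5))
    n_val = int(np.floor(n * r[1] + 0.5))
    if n_test + n_val > n:
        n_val = n - n_test
    idx_test = order[:n_test]
    idx_val = order[n_test:n_test + n_val]
    idx_train = order[n_test + n_val:]
    pick = lambda idx: [samples[i] for i in idx]
    return DatasetSplit(train=pick(idx_train), validation=pick(idx_val),
                        test=pick(idx_test), ratios=tuple(r))
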