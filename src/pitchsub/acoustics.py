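"""Acoustic feature computations on 32-kHz mono song recordings.

Harmonic Product Spectrum pitch in a 16-ms window, the log-power
spectrogram (Hamming 512, hop 128, natural log after a 0.1 offset, lowest
10 bins removed => 625 Hz cutoff), per-frame Wiener entropy features, and
the day-to-day spectrogram bias-variance decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.io import wavfile


@dataclass(frozen=True)
class SpectrogramConfig:
    sample_rate: int = 32000
    window: int = 512  # 16 ms at 32 kHz
    hop: int = 128  # 4 ms
    log_offset: float = 0.1
    low_cut_bins: int = 10  # 625 Hz cutoff at 62.5 Hz/bin
    normalize: bool = False  # scale linear power to unit 75th percentile
    hps_harmonics: int = 5
    hps_nfft: int = 8192
    hps_fmin: float = 300.0
    hps_fmax: float = 3000.0

    def __post_init__(self) -> None:
        if self.hop > self.window:
            raise ValueError("hop must not exceed the window length")
        for name in ("sample_rate", "window", "hop", "log_offset", "low_cut_bins"):
            if getattr(self, name) <= 0 and name != "low_cut_bins":
                raise ValueError(f"{name} must be positive")


DEFAULT_CONFIG = SpectrogramConfig()


def read_wav(path, expected_rate: int = 32000) -> np.ndarray:
    """Read a mono WAV file as float64, checking the sampling rate."""
    rate, data = wavfile.read(path)
    if rate != expected_rate:
        raise ValueError(f"expected {expected_rate} Hz, file has {rate} Hz")
    if data.ndim != 1:
        raise ValueError("expected a mono recording")
    return data.astype(float)


def hps_pitch(window_samples: np.ndarray, config: SpectrogramConfig = DEFAULT_CONFIG) -> float:
    """Fundamental frequency of one 16-ms analysis window, in Hz.

    Harmonic Product Spectrum: the magnitude spectrum is downsampled by each
    harmonic index h = 1..H and the products' maximum marks the fundamental.
    The defining property is robustness to a missing fundamental.  Amplitude
    scaling leaves the argmax unchanged.
    """
    x = np.asarray(window_samples, dtype=float)
    if x.size != config.window:
        raise ValueError(f"expected a {config.window}-sample window, got {x.size}")
    if not np.any(x):
        raise ValueError("silent window: pitch undefined")
    spec = np.abs(np.fft.rfft(x * np.hamming(x.size), n=config.hps_nfft))
    log_spec = np.log(spec + 1e-12)
    freq_step = config.sample_rate / config.hps_nfft
    k_lo = max(1, int(np.ceil(config.hps_fmin / freq_step)))
    k_hi = int(np.floor(config.hps_fmax / freq_step))
    ks = np.arange(k_lo, k_hi + 1)
    score = np.zeros(ks.size)
    for h in range(1, config.hps_harmonics + 1):
        score += log_spec[ks * h]
    return float(ks[int(np.argmax(score))] * freq_step)


def linear_power_spectrogram(
    waveform: np.ndarray, config: SpectrogramConfig = DEFAULT_CONFIG
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear-power spectrogram (freqs, frame times, power matrix F x T)."""
    x = np.asarray(waveform, dtype=float)
    if x.size < config.window:
        raise ValueError("waveform shorter than one analysis window")
    freqs, times, stft = signal.stft(
        x,
        fs=config.sample_rate,
        window=np.hamming(config.window),
        nperseg=config.window,
        noverlap=config.window - config.hop,
        boundary=None,
        padded=False,
        detrend=False,
    )
    power = np.abs(stft) ** 2
    return freqs, times, power


def log_power_spectrogram(
    waveform: np.ndarray, config: SpectrogramConfig = DEFAULT_CONFIG
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Natural-log power spectrogram with the additive offset, lowest bins
    removed for robustness to low-frequency noise."""
    freqs, times, power = linear_power_spectrogram(waveform, config)
    if config.normalize:
        q75 = np.percentile(power, 75)
        if q75 > 0:
            power = power / q75 * config.log_offset
    cut = config.low_cut_bins
    return freqs[cut:], times, np.log(power[cut:] + config.log_offset)


def entropy_features(
    syllable_spectrogram: np.ndarray,
) -> tuple[float, float]:
    """Mean and variance over frames of the per-frame Wiener entropy.

    Wiener entropy is the log ratio of the geometric to the arithmetic mean
    of the linear power in a frame: 0 for a flat (noise-like) spectrum,
    strongly negative for a peaked (tonal) one.  Mean entropy indexes
    syllable noisiness, variance entropy syllable complexity.  Expects the
    *linear*-power spectrogram (frequencies x frames), already low-cut.
    """
    power = np.asarray(syllable_spectrogram, dtype=float)
    if power.ndim != 2 or power.shape[1] < 2:
        raise ValueError("need a 2-D spectrogram with at least two frames")
    p = np.maximum(power, 1e-300)
    wiener = np.mean(np.log(p), axis=0) - np.log(np.mean(p, axis=0))
    return float(wiener.mean()), float(wiener.var(ddof=1))


def spectrogram_bias_variance(
    renditions_day_a: "list[np.ndarray]",
    renditions_day_b: "list[np.ndarray]",
) -> tuple[float, float, float]:
    """Day-to-day spectral change decomposed into bias and variances.

    All rendition spectrograms are cropped to the shortest rendition's frame
    count.  Bias is the Euclidean (Frobenius) distance between the two
    day-mean spectrograms; each day's variance is the mean over pixels of
    the across-rendition variance.
    """
    if len(renditions_day_a) < 2 or len(renditions_day_b) < 2:
        raise ValueError("each day needs >= 2 renditions for a variance")
    all_specs = list(renditions_day_a) + list(renditions_day_b)
    n_freq = {s.shape[0] for s in all_specs}
    if len(n_freq) != 1:
        raise ValueError("renditions disagree on the frequency axis")
    t_min = min(s.shape[1] for s in all_specs)
    a = np.stack([np.asarray(s, dtype=float)[:, :t_min] for s in renditions_day_a])
    b = np.stack([np.asarray(s, dtype=float)[:, :t_min] for s in renditions_day_b])
    bias = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    var_a = float(a.var(axis=0, ddof=1).mean())
    var_b = float(b.var(axis=0, ddof=1).mean())
    return bias, var_a, var_b


def harmonic_stack(
    fundamental: float,
    duration: float = 0.1,
    sample_rate: int = 32000,
    n_harmonics: int = 5,
    amplitudes: np.ndarray | None = None,
    missing_fundamental: bool = False,
) -> np.ndarray:
    """Synthetic harmonic tone for fixtures and pitch-estimator checks."""
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    if amplitudes is None:
        amplitudes = 1.0 / np.arange(1, n_harmonics + 1)
    x = np.zeros_like(t)
    for h, amp in zip(range(1, n_harmonics + 1), amplitudes):
        if missing_fundamental and h == 1:
            continue
        x += amp * np.sin(2 * np.pi * h * fundamental * t)
    return x


def segment_by_rms(
    waveform: np.ndarray,
    threshold: float,
    window: int = 512,
    hop: int = 128,
) -> "list[tuple[int, int]]":
    """Trivial RMS-threshold segmentation helper for synthetic fixtures:
    returns (start, end) sample indices of supra-threshold stretches."""
    x = np.asarray(waveform, dtype=float)
    n_frames = 1 + max(0, (x.size - window)) // hop
    rms = np.array(
        [np.sqrt(np.mean(x[i * hop : i * hop + window] ** 2)) for i in range(n_frames)]
    )
    above = rms > threshold
    segments = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            segments.append((start * hop, i * hop + window))
            start = None
    if start is not None:
        segments.append((start * hop, (len(above) - 1) * hop + window))
    return segments
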