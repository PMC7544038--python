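"""WAV input/output and step-1 preprocessing.

The recording device pairs a chest-contact lung-sound microphone with an
environment microphone that captures ambient room sound; both channels are
carried in one stereo WAV file. Preprocessing band-limits the signal and
resamples it to the analysis standard of 11.025 kHz / 16-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "Recording",
    "PreprocessConfig",
    "read_recording",
    "write_recording",
    "preprocess",
]

#: Nominal minimum recording length used in the study protocol (advisory).
RECOMMENDED_MIN_DURATION_S = 30.0


@dataclass(frozen=True)
class Recording:
    """A two-channel lung-sound recording.

    Samples are dimensionless full-scale floats in [-1, 1]; ``lung`` is the
    chest-contact microphone, ``environment`` the ambient reference.
    """

    lung: np.ndarray
    environment: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        lung = np.asarray(self.lung, dtype=np.float64)
        env = np.asarray(self.environment, dtype=np.float64)
        object.__setattr__(self, "lung", lung)
        object.__setattr__(self, "environment", env)
        if lung.ndim != 1 or env.ndim != 1:
            raise ValueError("channels must be one-dimensional sample arrays")
        if lung.shape != env.shape:
            raise ValueError(
                f"channel lengths differ: lung {lung.size}, environment {env.size}"
            )
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not (np.all(np.isfinite(lung)) and np.all(np.isfinite(env))):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.lung.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class PreprocessConfig:
    """Step-1 settings: resampling target and band-limiting filters.

    The 50–5500 Hz passband sits just outside the 90–5000 Hz thresholding
    band so the filter skirts do not shape the band edges used later.
    Filters are zero-phase (forward-backward) Butterworth so that event
    onsets, which feed the 100 ms duration rule, are not shifted.
    """

    target_rate: int = 11025
    quantization_bits: int = 16
    highpass_hz: float = 50.0
    lowpass_hz: float = 5500.0
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.highpass_hz < self.lowpass_hz < self.target_rate / 2):
            raise ValueError(
                "require 0 < highpass_hz < lowpass_hz < target_rate/2, got "
                f"{self.highpass_hz}, {self.lowpass_hz}, {self.target_rate}"
            )
        if self.quantization_bits < 2:
            raise ValueError("quantization_bits must be >= 2")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


def _pcm_to_float(data: np.ndarray) -> np.ndarray:
    """Convert integer PCM (or float) WAV data to full-scale float64."""
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32768.0
    if data.dtype == np.int32:
        return data.astype(np.float64) / 2147483648.0
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned
        return (data.astype(np.float64) - 128.0) / 128.0
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(np.float64)
    raise IOError(f"unsupported WAV sample format: {data.dtype}")


def read_recording(
    path: str | Path,
    lung_channel_index: int = 0,
    env_channel_index: int = 1,
) -> Recording:
    """Read a PCM WAV file into a :class:`Recording`.

    A mono file may serve both roles only when both indices are explicitly
    equal (the single channel is then used as lung and environment alike).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise IOError(f"could not decode WAV file {path}: {exc}") from exc
    data = np.atleast_2d(_pcm_to_float(np.asarray(data)))
    if data.shape[0] < data.shape[1]:  # wavfile returns (n, ch); mono -> (1, n)
        n_channels = data.shape[0]
        channels = data
    else:
        n_channels = data.shape[1]
        channels = data.T
    needed = max(lung_channel_index, env_channel_index)
    if needed >= n_channels:
        raise ValueError(
            f"{path} has {n_channels} channel(s); requested channel {needed}"
        )
    if n_channels == 1 and lung_channel_index != env_channel_index:
        raise ValueError(
            "mono file: lung and environment indices must be equal to share channel 0"
        )
    return Recording(
        lung=channels[lung_channel_index],
        environment=channels[env_channel_index],
        sample_rate=float(rate),
    )


def write_recording(path: str | Path, rec: Recording) -> None:
    """Write a recording as a 2-channel 16-bit PCM WAV file."""
    stacked = np.stack([rec.lung, rec.environment], axis=1)
    pcm = np.clip(np.round(stacked * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(round(rec.sample_rate)), pcm)


def quantize(x: np.ndarray, bits: int) -> np.ndarray:
    """Round samples to the nearest of 2**bits uniform levels on [-1, 1)."""
    scale = float(2 ** (bits - 1))
    return np.clip(np.round(x * scale), -scale, scale - 1) / scale


def _band_limit_and_resample(
    x: np.ndarray, rate: float, cfg: PreprocessConfig
) -> np.ndarray:
    # Anti-aliasing low-pass at the original rate, then rational resampling,
    # then high-pass at the target rate; all zero-phase.
    nyq = rate / 2.0
    if cfg.lowpass_hz < nyq:
        sos = signal.butter(
            cfg.filter_order, cfg.lowpass_hz, btype="lowpass", fs=rate, output="sos"
        )
        x = signal.sosfiltfilt(sos, x)
    if rate != cfg.target_rate:
        ratio = Fraction(int(cfg.target_rate), int(round(rate)))
        x = signal.resample_poly(x, ratio.numerator, ratio.denominator)
    sos = signal.butter(
        cfg.filter_order,
        cfg.highpass_hz,
        btype="highpass",
        fs=cfg.target_rate,
        output="sos",
    )
    return signal.sosfiltfilt(sos, x)


def preprocess(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Step 1: band-limit, resample to the target rate, and requantize.

    Returns a new :class:`Recording` at ``cfg.target_rate`` with both
    channels restricted to [highpass_hz, lowpass_hz] and rounded to
    ``cfg.quantization_bits``-bit amplitude levels.
    """
    cfg = cfg or PreprocessConfig()
    if rec.duration_s < RECOMMENDED_MIN_DURATION_S:
        warnings.warn(
            f"recording is {rec.duration_s:.1f} s; the recording protocol "
            f"recommends at least {RECOMMENDED_MIN_DURATION_S:.0f} s",
            stacklevel=2,
        )
    channels = [
        quantize(
            _band_limit_and_resample(ch, rec.sample_rate, cfg), cfg.quantization_bits
        )
        for ch in (rec.lung, rec.environment)
    ]
    return Recording(
        lung=channels[0], environment=channels[1], sample_rate=float(cfg.target_rate)
    )
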