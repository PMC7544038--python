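"""Step-2 short-time Fourier analysis.

Produces the framewise dB power spectra on which wheeze candidate peaks are
found: a Hamming window of 4096 points (371.5 ms at 11.025 kHz, commonly
quoted rounded to 372 ms) advanced 128 points per frame.

The dB scale is referenced to a full-scale sine: the windowed amplitude
spectrum is divided by the window's coherent gain (sum(w)/2), so a
full-scale bin-centered tone reads 0 dB regardless of window choice. All
detection thresholds downstream are relative (band mean plus an offset), so
the reference cancels there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

__all__ = [
    "SpectralConfig",
    "SpectralSeries",
    "compute_spectral_series",
    "band_mean_level",
    "band_bin_range",
    "export_spectrogram",
]


@dataclass(frozen=True)
class SpectralConfig:
    window_points: int = 4096
    hop_points: int = 128
    window_kind: str = "hamming"
    db_floor: float = -120.0

    def __post_init__(self) -> None:
        if not (0 < self.hop_points <= self.window_points):
            raise ValueError("require 0 < hop_points <= window_points")
        if self.window_points & (self.window_points - 1):
            raise ValueError("window_points must be a power of two")
        if self.window_kind != "hamming":
            raise ValueError(f"unsupported window kind: {self.window_kind!r}")

    def window_duration_s(self, sample_rate: float) -> float:
        return self.window_points / sample_rate

    def hop_duration_s(self, sample_rate: float) -> float:
        return self.hop_points / sample_rate


@dataclass(frozen=True)
class SpectralSeries:
    """Framewise one-sided dB power spectra of one channel.

    ``power_db`` has shape (n_frames, n_bins) with
    n_bins = window_points // 2 + 1; ``frame_times_s`` marks each window's
    start; ``bin_freqs_hz[k] = k * sample_rate / window_points``.
    """

    power_db: np.ndarray
    frame_times_s: np.ndarray
    bin_freqs_hz: np.ndarray
    sample_rate: float
    config: SpectralConfig

    @property
    def n_frames(self) -> int:
        return self.power_db.shape[0]

    @property
    def n_bins(self) -> int:
        return self.power_db.shape[1]

    @property
    def hop_seconds(self) -> float:
        return self.config.hop_duration_s(self.sample_rate)

    @property
    def bin_width_hz(self) -> float:
        return self.sample_rate / self.config.window_points

    @property
    def nyquist_hz(self) -> float:
        return self.sample_rate / 2.0


def compute_spectral_series(
    channel: np.ndarray, sample_rate: float, cfg: SpectralConfig | None = None
) -> SpectralSeries:
    """Slide a Hamming window over ``channel`` and return dB spectra.

    Frame count is floor((n - window) / hop) + 1; levels are clamped at
    ``cfg.db_floor``.
    """
    cfg = cfg or SpectralConfig()
    x = np.asarray(channel, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("channel must be one-dimensional")
    n = x.size
    if n < cfg.window_points:
        raise ValueError(
            f"channel has {n} samples, shorter than one analysis window "
            f"({cfg.window_points} points)"
        )
    w = get_window(cfg.window_kind, cfg.window_points, fftbins=True)
    n_frames = (n - cfg.window_points) // cfg.hop_points + 1
    frames = np.lib.stride_tricks.sliding_window_view(x, cfg.window_points)[
        :: cfg.hop_points
    ][:n_frames]
    spectrum = np.fft.rfft(frames * w, axis=1)
    # Coherent-gain normalization: full-scale bin-centered sine -> 0 dB.
    amplitude = np.abs(spectrum) / (w.sum() / 2.0)
    floor_amp = 10.0 ** (cfg.db_floor / 20.0)
    power_db = 20.0 * np.log10(np.maximum(amplitude, floor_amp))
    return SpectralSeries(
        power_db=power_db,
        frame_times_s=np.arange(n_frames) * cfg.hop_points / sample_rate,
        bin_freqs_hz=np.arange(cfg.window_points // 2 + 1)
        * sample_rate
        / cfg.window_points,
        sample_rate=float(sample_rate),
        config=cfg,
    )


def band_bin_range(
    series: SpectralSeries, band_lo: float, band_hi: float
) -> tuple[int, int]:
    """Inclusive bin-index range covering [band_lo, band_hi] Hz."""
    if not band_lo < band_hi:
        raise ValueError(f"empty band: ({band_lo}, {band_hi})")
    if band_lo < 0 or band_hi > series.nyquist_hz:
        raise ValueError(
            f"band ({band_lo}, {band_hi}) outside [0, {series.nyquist_hz}] Hz"
        )
    lo = int(np.ceil(band_lo / series.bin_width_hz))
    hi = int(np.floor(band_hi / series.bin_width_hz))
    if hi < lo:
        raise ValueError(f"band ({band_lo}, {band_hi}) contains no bins")
    return lo, hi


def band_mean_level(
    series: SpectralSeries, frame: int, band_lo: float, band_hi: float
) -> float:
    """Mean dB level over the bins with band_lo <= freq <= band_hi."""
    lo, hi = band_bin_range(series, band_lo, band_hi)
    return float(series.power_db[frame, lo : hi + 1].mean())


def export_spectrogram(
    series: SpectralSeries,
    path,
    band_lo: float | None = None,
    band_hi: float | None = None,
) -> None:
    """Write the spectrogram as columnar text (frame_time_s, freq_hz, power_db)."""
    lo, hi = 0, series.n_bins - 1
    if band_lo is not None or band_hi is not None:
        lo, hi = band_bin_range(
            series,
            0.0 if band_lo is None else band_lo,
            series.nyquist_hz if band_hi is None else band_hi,
        )
    with open(path, "w") as fh:
        fh.write("frame_time_s\tfreq_hz\tpower_db\n")
        for t, row in zip(series.frame_times_s, series.power_db):
            for k in range(lo, hi + 1):
                fh.write(f"{t:.6f}\t{series.bin_freqs_hz[k]:.3f}\t{row[k]:.3f}\n")
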