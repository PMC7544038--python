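"""Steps 3–4: threshold local spectral maxima and link them into tracks.

Step 3 extracts, per frame, every strict local maximum of the dB spectrum
that lies inside the 100–5000 Hz candidate band and exceeds a threshold set
10 dB above the mean level of the 90–5000 Hz band in that frame. Step 4
links the maxima across frames into candidate tracks and keeps only tracks
longer than 100 ms, the CORSA minimum wheeze duration.

Linking is greedy in frame order: each open track extends to the
nearest-frequency peak in the current frame within a drift budget of
``max_bin_drift_per_frame`` bins per elapsed frame, and gaps of up to
``max_gap_frames`` frames are bridged. Each peak joins at most one track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import SpectralSeries, band_bin_range

__all__ = [
    "DetectionConfig",
    "PeakPoint",
    "CandidateTrack",
    "frame_threshold",
    "extract_local_maxima",
    "link_tracks",
    "detect_tracks",
]


@dataclass(frozen=True)
class DetectionConfig:
    threshold_band_lo: float = 90.0
    threshold_band_hi: float = 5000.0
    threshold_offset_db: float = 10.0
    candidate_band_lo: float = 100.0
    candidate_band_hi: float = 5000.0
    min_duration_ms: float = 100.0
    max_duration_ms: float = 3000.0
    max_bin_drift_per_frame: int = 3
    max_gap_frames: int = 2

    def __post_init__(self) -> None:
        if not self.min_duration_ms < self.max_duration_ms:
            raise ValueError("require min_duration_ms < max_duration_ms")
        if self.max_bin_drift_per_frame < 0 or self.max_gap_frames < 0:
            raise ValueError("drift and gap limits must be >= 0")
        if not self.threshold_band_lo < self.threshold_band_hi:
            raise ValueError("empty threshold band")
        if not self.candidate_band_lo < self.candidate_band_hi:
            raise ValueError("empty candidate band")


@dataclass(frozen=True)
class PeakPoint:
    """One above-threshold strict local maximum in one frame."""

    frame: int
    bin: int
    freq_hz: float
    level_db: float
    margin_db: float  # level above that frame's threshold, >= 0


@dataclass(frozen=True)
class CandidateTrack:
    """A sequence of peaks linked across frames; a wheeze candidate.

    ``duration_ms`` counts the inclusive frame span times the hop period:
    the hop is the temporal resolution at which the maxima "continue".
    """

    points: tuple[PeakPoint, ...]
    hop_seconds: float
    start_s: float = field(init=False)
    end_s: float = field(init=False)
    duration_ms: float = field(init=False)
    mean_freq_hz: float = field(init=False)
    freq_sd_hz: float = field(init=False)
    mean_level_db: float = field(init=False)
    mean_margin_db: float = field(init=False)
    n_gap_frames: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("a track needs at least one point")
        frames = [p.frame for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")
        span = frames[-1] - frames[0] + 1
        freqs = np.array([p.freq_hz for p in self.points])
        levels = np.array([p.level_db for p in self.points])
        object.__setattr__(self, "start_s", frames[0] * self.hop_seconds)
        object.__setattr__(self, "end_s", (frames[-1] + 1) * self.hop_seconds)
        object.__setattr__(self, "duration_ms", span * self.hop_seconds * 1000.0)
        object.__setattr__(self, "mean_freq_hz", float(freqs.mean()))
        object.__setattr__(self, "freq_sd_hz", float(freqs.std()))
        object.__setattr__(self, "mean_level_db", float(levels.mean()))
        object.__setattr__(
            self, "mean_margin_db", float(np.mean([p.margin_db for p in self.points]))
        )
        object.__setattr__(self, "n_gap_frames", span - len(self.points))

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def frame_span(self) -> int:
        return self.points[-1].frame - self.points[0].frame + 1

    @property
    def gap_fraction(self) -> float:
        return self.n_gap_frames / self.frame_span

    def overlaps(self, other: "CandidateTrack") -> bool:
        return self.start_s < other.end_s and other.start_s < self.end_s

    def to_record(self) -> dict:
        return {
            "start_s": round(self.start_s, 6),
            "end_s": round(self.end_s, 6),
            "duration_ms": round(self.duration_ms, 3),
            "mean_freq_hz": round(self.mean_freq_hz, 2),
            "mean_level_db": round(self.mean_level_db, 2),
        }


def _frame_thresholds(series: SpectralSeries, cfg: DetectionConfig) -> np.ndarray:
    lo, hi = band_bin_range(series, cfg.threshold_band_lo, cfg.threshold_band_hi)
    return series.power_db[:, lo : hi + 1].mean(axis=1) + cfg.threshold_offset_db


def frame_threshold(
    series: SpectralSeries, frame: int, cfg: DetectionConfig | None = None
) -> float:
    """Detection threshold for one frame: band mean level plus the offset."""
    cfg = cfg or DetectionConfig()
    return float(_frame_thresholds(series, cfg)[frame])


def extract_local_maxima(
    series: SpectralSeries, cfg: DetectionConfig | None = None
) -> list[PeakPoint]:
    """Step 3: all strict in-band local maxima at or above the frame threshold.

    Returned sorted by (frame, bin).
    """
    cfg = cfg or DetectionConfig()
    thresholds = _frame_thresholds(series, cfg)
    clo, chi = band_bin_range(series, cfg.candidate_band_lo, cfg.candidate_band_hi)
    p = series.power_db
    interior = p[:, 1:-1]
    is_max = (interior > p[:, :-2]) & (interior > p[:, 2:])
    above = interior >= thresholds[:, None]
    frames, bins = np.nonzero(is_max & above)
    bins = bins + 1
    keep = (bins >= clo) & (bins <= chi)
    return [
        PeakPoint(
            frame=int(t),
            bin=int(b),
            freq_hz=float(series.bin_freqs_hz[b]),
            level_db=float(p[t, b]),
            margin_db=float(p[t, b] - thresholds[t]),
        )
        for t, b in zip(frames[keep], bins[keep])
    ]


def _finalize(
    points: list[PeakPoint], hop_s: float, cfg: DetectionConfig
) -> list[CandidateTrack]:
    """Apply the duration rules: keep > min, split tracks over the cap."""
    span_ms = (points[-1].frame - points[0].frame + 1) * hop_s * 1000.0
    if span_ms <= cfg.min_duration_ms:
        return []
    if span_ms > cfg.max_duration_ms and len(points) > 2:
        # Split at the weakest-margin interior point and re-test both halves.
        interior = range(1, len(points) - 1)
        cut = min(interior, key=lambda i: points[i].margin_db)
        return _finalize(points[:cut], hop_s, cfg) + _finalize(
            points[cut + 1 :], hop_s, cfg
        )
    return [CandidateTrack(points=tuple(points), hop_seconds=hop_s)]


def link_tracks(
    peaks: list[PeakPoint],
    series: SpectralSeries,
    cfg: DetectionConfig | None = None,
) -> list[CandidateTrack]:
    """Step 4: associate peaks across frames and keep tracks > 100 ms.

    Open tracks claim peaks in order of track seniority; among available
    peaks in a frame the nearest in frequency wins, ties to the lower bin.
    """
    cfg = cfg or DetectionConfig()
    hop_s = series.hop_seconds
    by_frame: dict[int, list[PeakPoint]] = {}
    for pk in peaks:
        by_frame.setdefault(pk.frame, []).append(pk)
    for lst in by_frame.values():
        lst.sort(key=lambda p: p.bin)

    open_tracks: list[list[PeakPoint]] = []
    finished: list[list[PeakPoint]] = []
    if not by_frame:
        return []
    for t in range(min(by_frame), max(by_frame) + 1):
        avail = by_frame.get(t, [])
        used = [False] * len(avail)
        for tr in open_tracks:
            last = tr[-1]
            gap = t - last.frame
            if gap == 0:
                continue
            budget = cfg.max_bin_drift_per_frame * gap
            best = -1
            best_d = budget + 1
            for i, pk in enumerate(avail):
                if used[i]:
                    continue
                d = abs(pk.bin - last.bin)
                if d < best_d:
                    best_d = d
                    best = i
            if best >= 0:
                used[best] = True
                tr.append(avail[best])
        still_open: list[list[PeakPoint]] = []
        for tr in open_tracks:
            if t - tr[-1].frame > cfg.max_gap_frames:
                finished.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        for i, pk in enumerate(avail):
            if not used[i]:
                open_tracks.append([pk])
    finished.extend(open_tracks)

    out: list[CandidateTrack] = []
    for pts in finished:
        out.extend(_finalize(pts, hop_s, cfg))
    out.sort(key=lambda tr: (tr.points[0].frame, tr.points[0].bin))
    return out


def detect_tracks(
    series: SpectralSeries, cfg: DetectionConfig | None = None
) -> list[CandidateTrack]:
    """Run steps 3 and 4 on one spectral series."""
    cfg = cfg or DetectionConfig()
    return link_tracks(extract_local_maxima(series, cfg), series, cfg)
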