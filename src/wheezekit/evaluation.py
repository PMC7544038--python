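"""Evaluation statistics: confusion-matrix metrics, the Jonckheere–Terpstra
ordered-trend test, and corpus-level wheeze summaries.

File-level verdicts are compared against specialist labels; sensitivity,
specificity, PPV and NPV are the standard ratios TP/(TP+FN), TN/(TN+FP),
TP/(TP+FP) and TN/(TN+FN), reported as percentages rounded half-up to one
decimal. The trend test asks whether a detection indicator drifts across
ordered age groups; with every observation tied (e.g. every wheeze file
detected in every group) the test is degenerate and p = 1 by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
from scipy.stats import norm

from .classify import Label, TrackLabel
from .detection import CandidateTrack

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "CorpusSummary",
    "metrics",
    "percent",
    "jonckheere_terpstra",
    "JTResult",
    "summarize_tracks",
    "local_maximum_histogram",
]


def percent(p: float | None, ndigits: int = 1) -> float | None:
    """Proportion -> percentage, rounded half-up to ``ndigits`` decimals."""
    if p is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(p * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @classmethod
    def from_pairs(cls, truth, prediction) -> "ConfusionCounts":
        """Build counts from aligned boolean-like positive indicators."""
        t = np.asarray(truth, dtype=bool)
        p = np.asarray(prediction, dtype=bool)
        if t.shape != p.shape:
            raise ValueError("truth and prediction must be aligned")
        return cls(
            tp=int(np.sum(t & p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
            tn=int(np.sum(~t & ~p)),
        )


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity, specificity, PPV, NPV as proportions; None = undefined."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def as_percentages(self) -> dict[str, float | None]:
        return {
            "sensitivity": percent(self.sensitivity),
            "specificity": percent(self.specificity),
            "ppv": percent(self.ppv),
            "npv": percent(self.npv),
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> MetricSet:
    """The four screening metrics; a zero denominator leaves that metric
    undefined (None) without disturbing the others."""
    return MetricSet(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


# ---------------------------------------------------------------------------
# Jonckheere–Terpstra trend test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JTResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "normal" | "degenerate"


def _jt_statistic(groups: list[np.ndarray]) -> float:
    total = 0.0
    for gi, gj in combinations(groups, 2):
        diff = gj[None, :] - gi[:, None]
        total += np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
    return float(total)


def _exact_distribution(pooled: np.ndarray, sizes: list[int]) -> list[float]:
    """All JT statistic values over distinct assignments of the pooled data
    to groups of the given sizes (brute-force enumeration)."""
    stats: list[float] = []

    def recurse(indices: tuple[int, ...], k: int, chosen: list[np.ndarray]) -> None:
        if k == len(sizes):
            stats.append(_jt_statistic(chosen))
            return
        for combo in combinations(indices, sizes[k]):
            remaining = tuple(i for i in indices if i not in combo)
            recurse(remaining, k + 1, chosen + [pooled[list(combo)]])

    recurse(tuple(range(pooled.size)), 0, [])
    return stats


def jonckheere_terpstra(
    groups: list, alternative: str = "two_sided", exact_n: int = 12
) -> JTResult:
    """Test for an ordered trend across groups.

    ``groups`` is an ordered list of numeric samples. The statistic sums the
    between-group Mann–Whitney counts over ordered pairs, ties counted 1/2.
    An exact permutation p-value is computed when the pooled size is at most
    ``exact_n``; otherwise a normal approximation with tie-corrected
    variance is used. If every pooled observation is identical the test is
    degenerate and p = 1.
    """
    if alternative not in ("increasing", "decreasing", "two_sided"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a for a in arrays if a.size > 0]
    if len(arrays) < 2:
        raise ValueError("need at least two non-empty groups in a stated order")
    pooled = np.concatenate(arrays)
    n = pooled.size
    sizes = [a.size for a in arrays]
    t_obs = _jt_statistic(arrays)

    if np.all(pooled == pooled[0]):
        return JTResult(statistic=t_obs, p_value=1.0, method="degenerate")

    eps = 1e-9
    if n <= exact_n:
        dist = np.array(_exact_distribution(pooled, sizes))
        p_inc = float(np.mean(dist >= t_obs - eps))
        p_dec = float(np.mean(dist <= t_obs + eps))
        method = "exact"
    else:
        n_arr = np.array(sizes, dtype=float)
        _, tie_counts = np.unique(pooled, return_counts=True)
        t_arr = tie_counts.astype(float)
        mean = (n * n - np.sum(n_arr**2)) / 4.0
        term1 = (
            n * (n - 1) * (2 * n + 5)
            - np.sum(n_arr * (n_arr - 1) * (2 * n_arr + 5))
            - np.sum(t_arr * (t_arr - 1) * (2 * t_arr + 5))
        ) / 72.0
        term2 = (
            np.sum(n_arr * (n_arr - 1) * (n_arr - 2))
            * np.sum(t_arr * (t_arr - 1) * (t_arr - 2))
        ) / (36.0 * n * (n - 1) * (n - 2))
        term3 = (
            np.sum(n_arr * (n_arr - 1)) * np.sum(t_arr * (t_arr - 1))
        ) / (8.0 * n * (n - 1))
        var = term1 + term2 + term3
        if var <= 0:
            return JTResult(statistic=t_obs, p_value=1.0, method="degenerate")
        sd = math.sqrt(var)
        # continuity correction of 1/2 toward the mean
        p_inc = float(norm.sf((t_obs - mean - 0.5) / sd))
        p_dec = float(norm.cdf((t_obs - mean + 0.5) / sd))
        method = "normal"

    if alternative == "increasing":
        p = p_inc
    elif alternative == "decreasing":
        p = p_dec
    else:
        p = min(1.0, 2.0 * min(p_inc, p_dec))
    return JTResult(statistic=t_obs, p_value=p, method=method)


# ---------------------------------------------------------------------------
# Corpus summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    minimum: float
    maximum: float


def _stats(values: list[float]) -> SummaryStats | None:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    return SummaryStats(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        minimum=float(arr.min()),
        maximum=float(arr.max()),
    )


@dataclass(frozen=True)
class CorpusSummary:
    """Corpus-level wheeze-sound summary.

    ``histogram`` maps the number of simultaneous local-maximum tracks per
    wheeze sound (distinct wheeze tracks overlapping its time span,
    including itself) to the number of wheeze sounds with that count.
    """

    histogram: dict[int, int]
    rates_pct: dict[int, float]
    total_wheeze_sounds: int
    n_monophonic: int
    n_polyphonic: int
    frequency_hz: SummaryStats | None
    intensity_db: SummaryStats | None
    duration_ms: SummaryStats | None


def local_maximum_histogram(counts: dict[int, int]) -> tuple[int, dict[int, float]]:
    """Total and per-bin percentage rates for a local-maximum-count histogram."""
    total = sum(counts.values())
    rates = {
        k: (percent(v / total) if total else 0.0) for k, v in sorted(counts.items())
    }
    return total, rates


def summarize_tracks(
    tracks_per_file: list[list[CandidateTrack]],
    labels_per_file: list[list[TrackLabel]],
    bin_width_hz: float,
) -> CorpusSummary:
    """Summarize wheeze-labeled tracks across a corpus of files."""
    histogram: dict[int, int] = {}
    freqs: list[float] = []
    intensities: list[float] = []
    durations: list[float] = []
    n_mono = 0
    n_poly = 0
    for tracks, labels in zip(tracks_per_file, labels_per_file):
        if len(tracks) != len(labels):
            raise ValueError("tracks and labels must be aligned per file")
        wheeze = [
            tr for tr, lb in zip(tracks, labels) if lb.label == Label.WHEEZE
        ]
        for w in wheeze:
            overlapping = [v for v in wheeze if v.overlaps(w)]
            histogram[len(overlapping)] = histogram.get(len(overlapping), 0) + 1
            poly = any(
                abs(v.mean_freq_hz - w.mean_freq_hz) > bin_width_hz
                for v in overlapping
                if v is not w
            )
            n_poly += poly
            n_mono += not poly
            freqs.append(w.mean_freq_hz)
            intensities.append(w.mean_margin_db)
            durations.append(w.duration_ms)
    total, rates = local_maximum_histogram(histogram)
    return CorpusSummary(
        histogram=dict(sorted(histogram.items())),
        rates_pct=rates,
        total_wheeze_sounds=total,
        n_monophonic=n_mono,
        n_polyphonic=n_poly,
        frequency_hz=_stats(freqs),
        intensity_db=_stats(intensities),
        duration_ms=_stats(durations),
    )
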