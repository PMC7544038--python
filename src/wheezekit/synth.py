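"""Seeded generator of two-channel synthetic lung-sound scenes.

Renders 30-second (by default) recordings that emulate the study's
conditions: tidal-breathing noise on the chest microphone, an independent
ambient floor on the environment microphone, and events drawn from the
sound classes the recordings contained — wheezes (tonal, 100–1380 Hz,
100–1616 ms, intensity 3–44 dB), heartbeats (sub-100 ms low-frequency
thumps), infant crying (loud chest-dominant harmonic phrases with strong
pitch movement), and voices (ambient-dominant harmonic bursts).

Channel coupling: every event is rendered on its native channel and leaks
onto the other channel attenuated by ``LEAKAGE_DB`` (a fixture constant, not
a claim about any device). ``channel_affinity`` = 1 places the source at the
chest, 0 in the room.

An event's ``snr_db`` is its plateau RMS relative to the breath-noise floor
RMS, in dB, on its native channel (broadband, time domain).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .audio_io import Recording

__all__ = [
    "SceneEvent",
    "SceneSpec",
    "Annotation",
    "render_scene",
    "sample_corpus",
    "scene_to_yaml",
    "scene_from_yaml",
    "write_annotations",
    "LEAKAGE_DB",
    "RENDER_RATE",
]

#: Inter-channel leakage attenuation applied to every event, dB.
LEAKAGE_DB = 12.0
#: Native rendering rate, Hz (the pipeline's analysis standard).
RENDER_RATE = 11025
#: Breath-noise floor used to anchor event SNRs when a scene has no floor.
NOMINAL_FLOOR_DB = -55.0

WHEEZE_FREQ_RANGE = (100.0, 1380.0)
WHEEZE_DURATION_RANGE_MS = (100.0, 1616.0)
WHEEZE_SNR_RANGE_DB = (3.0, 44.0)


@dataclass(frozen=True)
class SceneEvent:
    kind: str  # wheeze | heartbeat | crying | voice
    onset_s: float
    duration_ms: float
    freq_hz: float = 0.0  # fundamental; unused for heartbeat
    snr_db: float = 20.0
    polyphonic_partner_hz: float | None = None
    channel_affinity: float = 1.0  # 1 = lung-dominant, 0 = environment-dominant

    def __post_init__(self) -> None:
        if self.kind not in ("wheeze", "heartbeat", "crying", "voice"):
            raise ValueError(f"unknown event kind: {self.kind!r}")
        if not 0.0 <= self.channel_affinity <= 1.0:
            raise ValueError("channel_affinity must be in [0, 1]")
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.kind == "wheeze":
            lo, hi = WHEEZE_FREQ_RANGE
            if not lo <= self.freq_hz <= hi:
                raise ValueError(f"wheeze freq_hz must be in [{lo}, {hi}] Hz")
            lo, hi = WHEEZE_DURATION_RANGE_MS
            if not lo <= self.duration_ms <= hi:
                raise ValueError(f"wheeze duration_ms must be in [{lo}, {hi}] ms")
            lo, hi = WHEEZE_SNR_RANGE_DB
            if not lo <= self.snr_db <= hi:
                raise ValueError(f"wheeze snr_db must be in [{lo}, {hi}] dB")
        elif self.kind == "heartbeat":
            if not self.duration_ms < 100.0:
                raise ValueError("heartbeat duration_ms must be < 100 ms")
        elif self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_ms / 1000.0


@dataclass(frozen=True)
class SceneSpec:
    duration_s: float = 30.0
    events: tuple[SceneEvent, ...] = ()
    breath_noise_db: float | None = NOMINAL_FLOOR_DB  # dBFS RMS; None = no floor
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for ev in self.events:
            if ev.offset_s > self.duration_s:
                raise ValueError(
                    f"{ev.kind} event at {ev.onset_s:.2f}s runs past the scene end"
                )

    @property
    def has_wheeze(self) -> bool:
        return any(ev.kind == "wheeze" for ev in self.events)


@dataclass(frozen=True)
class Annotation:
    kind: str
    onset_s: float
    offset_s: float
    freq_hz: float
    channel_affinity: float


def _tukey(n: int, alpha: float = 0.25) -> np.ndarray:
    from scipy.signal import windows

    return windows.tukey(n, alpha)


def _phase(freq_inst: np.ndarray, fs: float) -> np.ndarray:
    return 2.0 * np.pi * np.cumsum(freq_inst) / fs


def _render_wheeze(ev: SceneEvent, fs: float, amp: float, rng) -> np.ndarray:
    n = int(round(ev.duration_ms / 1000.0 * fs))
    t = np.arange(n) / fs
    env = _tukey(n)
    x = amp * env * np.sin(2 * np.pi * ev.freq_hz * t + rng.uniform(0, 2 * np.pi))
    if ev.polyphonic_partner_hz:
        x = x + amp * env * np.sin(
            2 * np.pi * ev.polyphonic_partner_hz * t + rng.uniform(0, 2 * np.pi)
        )
    return x


def _render_heartbeat(ev: SceneEvent, fs: float, amp: float, rng) -> np.ndarray:
    # Low-frequency thump: Gaussian-enveloped tone well below the 100 Hz
    # candidate band; the envelope is wide enough that its spectral skirt
    # stays far below threshold inside the band.
    n = int(round(ev.duration_ms / 1000.0 * fs))
    t = np.arange(n) / fs
    center = ev.duration_ms / 2000.0
    sigma = ev.duration_ms / 7000.0
    f0 = ev.freq_hz if ev.freq_hz > 0 else 45.0
    env = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return amp * env * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))


def _render_crying(ev: SceneEvent, fs: float, amp: float, rng) -> np.ndarray:
    # One cry phrase: harmonic stack whose pitch glides through a rising-
    # falling arc and carries the rough, rapidly jittering phonation of an
    # infant cry, so the time-frequency image is a broad unstable band
    # rather than a wheeze's solitary steady ridge.
    from scipy.signal import butter, sosfiltfilt

    n = int(round(ev.duration_ms / 1000.0 * fs))
    t = np.arange(n) / fs
    dur = ev.duration_ms / 1000.0
    f0 = ev.freq_hz
    glide = 1.0 - 0.3 * np.cos(np.pi * t / dur)  # 0.7·f0 -> 1.3·f0
    jitter = rng.normal(0.0, 1.0, n)
    sos = butter(2, 20.0, fs=fs, output="sos")
    jitter = sosfiltfilt(sos, jitter)
    jitter = 0.12 * jitter / max(jitter.std(), 1e-12)
    inst = f0 * glide * (1.0 + jitter)
    env = _tukey(n, alpha=0.4)
    x = np.zeros(n)
    for h, a in ((1, 1.0), (2, 0.5), (3, 0.25)):
        x += a * np.sin(h * _phase(inst, fs) + rng.uniform(0, 2 * np.pi))
    return amp * env * x / 1.75  # normalize summed harmonic amplitudes


def _render_voice(ev: SceneEvent, fs: float, amp: float, rng) -> np.ndarray:
    # Ambient speech: steady-pitch harmonic burst with syllabic amplitude
    # modulation.
    n = int(round(ev.duration_ms / 1000.0 * fs))
    t = np.arange(n) / fs
    f0 = ev.freq_hz * (1.0 + 0.03 * np.sin(2 * np.pi * 2.5 * t))
    am = 1.0 - 0.5 * np.square(np.sin(2 * np.pi * 2.0 * t))
    env = _tukey(n, alpha=0.3) * am
    x = np.zeros(n)
    total = 0.0
    for h in range(1, 6):
        a = 1.0 / h
        total += a
        x += a * np.sin(h * _phase(f0, fs) + rng.uniform(0, 2 * np.pi))
    return amp * env * x / total


_RENDERERS = {
    "wheeze": _render_wheeze,
    "heartbeat": _render_heartbeat,
    "crying": _render_crying,
    "voice": _render_voice,
}


def render_scene(
    spec: SceneSpec, leakage_db: float = LEAKAGE_DB
) -> tuple[Recording, list[Annotation]]:
    """Render a scene to a two-channel recording plus exact annotations.

    Deterministic: the same spec (including its seed) yields bit-identical
    samples.
    """
    fs = float(RENDER_RATE)
    n = int(round(spec.duration_s * fs))
    rng = np.random.default_rng(spec.seed)
    floor_db = (
        spec.breath_noise_db if spec.breath_noise_db is not None else NOMINAL_FLOOR_DB
    )
    sigma = 10.0 ** (floor_db / 20.0)
    if spec.breath_noise_db is not None:
        lung = rng.normal(0.0, sigma, n)
        env = rng.normal(0.0, sigma, n)
    else:
        lung = np.zeros(n)
        env = np.zeros(n)
    leak = 10.0 ** (-leakage_db / 20.0)
    annotations: list[Annotation] = []
    for ev in spec.events:
        # plateau RMS = sigma * 10^(snr/20); sine plateau RMS = amp/sqrt(2)
        amp = np.sqrt(2.0) * sigma * 10.0 ** (ev.snr_db / 20.0)
        x = _RENDERERS[ev.kind](ev, fs, amp, rng)
        i0 = int(round(ev.onset_s * fs))
        i1 = min(i0 + x.size, n)
        a = ev.channel_affinity
        lung_gain = a + (1.0 - a) * leak
        env_gain = (1.0 - a) + a * leak
        lung[i0:i1] += lung_gain * x[: i1 - i0]
        env[i0:i1] += env_gain * x[: i1 - i0]
        annotations.append(
            Annotation(
                kind=ev.kind,
                onset_s=ev.onset_s,
                offset_s=ev.offset_s,
                freq_hz=ev.freq_hz,
                channel_affinity=ev.channel_affinity,
            )
        )
    peak = max(np.abs(lung).max(), np.abs(env).max(), 1e-12)
    if peak > 0.999:  # keep headroom for 16-bit PCM round trips
        lung = lung * (0.999 / peak)
        env = env * (0.999 / peak)
    return Recording(lung=lung, environment=env, sample_rate=fs), annotations


def _sample_wheeze(rng, duration_s: float, snr_range: tuple[float, float]) -> SceneEvent:
    dur_ms = rng.uniform(*WHEEZE_DURATION_RANGE_MS)
    freq = rng.uniform(*WHEEZE_FREQ_RANGE)
    partner = None
    if rng.random() < 0.626:  # observed polyphonic share of wheeze sounds
        partner = min(freq * rng.uniform(1.25, 2.2), WHEEZE_FREQ_RANGE[1])
    onset = rng.uniform(0.3, duration_s - dur_ms / 1000.0 - 0.3)
    return SceneEvent(
        kind="wheeze",
        onset_s=float(onset),
        duration_ms=float(dur_ms),
        freq_hz=float(freq),
        snr_db=float(rng.uniform(*snr_range)),
        polyphonic_partner_hz=None if partner is None else float(partner),
        channel_affinity=1.0,
    )


def _sample_noise_event(rng, duration_s: float) -> SceneEvent:
    kind = rng.choice(["crying", "voice", "heartbeat"], p=[0.30, 0.55, 0.15])
    if kind == "crying":
        dur_ms = rng.uniform(800.0, 2000.0)
        ev = dict(freq_hz=rng.uniform(350.0, 550.0), snr_db=rng.uniform(15.0, 30.0),
                  channel_affinity=1.0)
    elif kind == "voice":
        dur_ms = rng.uniform(300.0, 1000.0)
        ev = dict(freq_hz=rng.uniform(150.0, 300.0), snr_db=rng.uniform(15.0, 30.0),
                  channel_affinity=0.0)
    else:
        dur_ms = rng.uniform(60.0, 90.0)
        ev = dict(freq_hz=45.0, snr_db=rng.uniform(8.0, 16.0), channel_affinity=1.0)
    onset = rng.uniform(0.3, duration_s - dur_ms / 1000.0 - 0.3)
    return SceneEvent(kind=str(kind), onset_s=float(onset),
                      duration_ms=float(dur_ms), **{k: float(v) for k, v in ev.items()})


def sample_corpus(
    n_wheeze_files: int,
    n_nowheeze_files: int,
    seed: int,
    duration_s: float = 30.0,
    snr_db_range: tuple[float, float] = (10.0, 44.0),
) -> list[SceneSpec]:
    """Draw a corpus of scene specs mirroring the study's file split.

    Wheeze files carry 1–3 wheeze events with frequency and duration drawn
    uniformly over the observed wheeze ranges and SNR over ``snr_db_range``;
    every file additionally carries 0–3 noise events (crying, voice,
    heartbeat). Deterministic given ``seed``.
    """
    if n_wheeze_files < 0 or n_nowheeze_files < 0:
        raise ValueError("file counts must be >= 0")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_wheeze_files + n_nowheeze_files)
    specs: list[SceneSpec] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        scene_seed = int(child.generate_state(1)[0] % (2**31))
        events: list[SceneEvent] = []
        if i < n_wheeze_files:
            # Roughly one wheeze per breath of tidal breathing: the study's
            # wheeze files averaged ~12.5 wheeze sounds per 30 s recording.
            lo = max(1, int(np.ceil(duration_s / 5.0)))
            hi = max(lo + 1, int(np.ceil(duration_s / 2.5)) + 1)
            for _ in range(int(rng.integers(lo, hi))):
                events.append(_sample_wheeze(rng, duration_s, snr_db_range))
        for _ in range(int(rng.integers(0, 4))):
            events.append(_sample_noise_event(rng, duration_s))
        events.sort(key=lambda e: e.onset_s)
        specs.append(
            SceneSpec(
                duration_s=duration_s,
                events=tuple(events),
                breath_noise_db=NOMINAL_FLOOR_DB,
                seed=scene_seed,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Scene and annotation serialization
# ---------------------------------------------------------------------------

def scene_to_yaml(spec: SceneSpec, path: str | Path) -> None:
    doc = {
        "duration_s": spec.duration_s,
        "breath_noise_db": spec.breath_noise_db,
        "seed": spec.seed,
        "events": [
            {
                "kind": ev.kind,
                "onset_s": ev.onset_s,
                "duration_ms": ev.duration_ms,
                "freq_hz": ev.freq_hz,
                "snr_db": ev.snr_db,
                "polyphonic_partner_hz": ev.polyphonic_partner_hz,
                "channel_affinity": ev.channel_affinity,
            }
            for ev in spec.events
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scene_from_yaml(path: str | Path) -> SceneSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "events" not in doc:
        raise ValueError(f"{path} is not a scene description")
    events = tuple(SceneEvent(**ev) for ev in doc["events"])
    return SceneSpec(
        duration_s=float(doc.get("duration_s", 30.0)),
        events=events,
        breath_noise_db=doc.get("breath_noise_db", NOMINAL_FLOOR_DB),
        seed=int(doc.get("seed", 0)),
    )


def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["kind", "onset_s", "offset_s", "freq_hz", "channel_affinity"])
        for a in annotations:
            writer.writerow(
                [a.kind, f"{a.onset_s:.6f}", f"{a.offset_s:.6f}",
                 f"{a.freq_hz:.3f}", f"{a.channel_affinity:.3f}"]
            )


def with_seed(spec: SceneSpec, seed: int) -> SceneSpec:
    """Copy a scene spec with a different seed."""
    return replace(spec, seed=seed)
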