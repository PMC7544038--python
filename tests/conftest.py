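import numpy as np
import pytest

from wheezekit import Recording, SceneEvent, SceneSpec, render_scene

SAMPLE_RATE = 11025
BIN_WIDTH = SAMPLE_RATE / 4096
#: Bin-centered test tones (no spectral leakage for a Hamming window).
TONE_400 = 149 * BIN_WIDTH  # 401.06 Hz
TONE_800 = 297 * BIN_WIDTH  # 799.42 Hz


def make_tone(freq_hz: float, duration_s: float, sample_rate: float = SAMPLE_RATE,
              amplitude: float = 1.0) -> np.ndarray:
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    return amplitude * np.sin(2 * np.pi * freq_hz * t)


def make_recording(lung: np.ndarray, env: np.ndarray | None = None,
                   sample_rate: float = SAMPLE_RATE) -> Recording:
    if env is None:
        env = np.zeros_like(lung)
    return Recording(lung=lung, environment=env, sample_rate=sample_rate)


@pytest.fixture(scope="session")
def single_wheeze_scene():
    """One 500 ms / 400 Hz / 20 dB wheeze over the default breath floor."""
    spec = SceneSpec(
        duration_s=6.0,
        seed=11,
        events=(
            SceneEvent(kind="wheeze", onset_s=2.0, duration_ms=500.0,
                       freq_hz=400.0, snr_db=20.0),
        ),
    )
    rec, ann = render_scene(spec)
    return spec, rec, ann


@pytest.fixture(scope="session")
def noise_only_scene():
    """Voice + crying + heartbeat, no wheeze."""
    spec = SceneSpec(
        duration_s=8.0,
        seed=8,
        events=(
            SceneEvent(kind="voice", onset_s=1.5, duration_ms=800.0,
                       freq_hz=220.0, snr_db=25.0, channel_affinity=0.0),
            SceneEvent(kind="crying", onset_s=3.5, duration_ms=1500.0,
                       freq_hz=450.0, snr_db=25.0),
            SceneEvent(kind="heartbeat", onset_s=6.5, duration_ms=80.0,
                       freq_hz=45.0, snr_db=12.0),
        ),
    )
    rec, ann = render_scene(spec)
    return spec, rec, ann
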