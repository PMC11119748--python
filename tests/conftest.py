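import numpy as np
import pytest

from pathospeech import (
    CohortSpec,
    ScorePair,
    SyntheticSpeaker,
    Waveform,
    init_random_weights,
    sample_cohort,
)

SR = 16_000


def make_tone(freq: float, duration_s: float, sample_rate: int = SR, harmonics: int = 1):
    """Harmonic complex with unit peak, used as a controllable test signal."""
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    x = sum(np.sin(2 * np.pi * freq * h * t) / h for h in range(1, harmonics + 1))
    return Waveform(x / np.max(np.abs(x)), sample_rate)


def f0_autocorrelation(x: np.ndarray, sample_rate: int, fmin=60.0, fmax=500.0) -> float:
    """Independent pitch oracle: argmax of the autocorrelation in the F0 lag band."""
    x = np.asarray(x, dtype=np.float64) - np.mean(x)
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    lo, hi = int(sample_rate / fmax), int(sample_rate / fmin)
    lag = lo + int(np.argmax(ac[lo:hi]))
    return sample_rate / lag


def burst_recording(
    n_bursts=8, burst_s=0.4, gap_s=0.3, lead_s=0.25, freq=180.0, sample_rate=SR,
    envelope="hann",
):
    """Tone bursts separated by exact silences; returns (Waveform, true gap midpoints)."""
    n_b, n_g, n_l = (int(round(s * sample_rate)) for s in (burst_s, gap_s, lead_s))
    t = np.arange(n_b) / sample_rate
    env = np.hanning(n_b) if envelope == "hann" else np.ones(n_b)
    burst = np.sin(2 * np.pi * freq * t) * env * 0.9
    pieces = [np.zeros(n_l)]
    midpoints = []
    pos = n_l
    for i in range(n_bursts):
        pieces.append(burst)
        pos += n_b
        if i < n_bursts - 1:
            midpoints.append((pos + n_g / 2) / sample_rate)
            pieces.append(np.zeros(n_g))
            pos += n_g
    pieces.append(np.zeros(n_l))
    return Waveform(np.concatenate(pieces), sample_rate), midpoints


@pytest.fixture(scope="session")
def extractor_weights():
    return init_random_weights(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    return sample_cohort(CohortSpec(n_speakers=30, seed=11))


@pytest.fixture()
def dummy_speaker():
    def make(severity: float, intelligibility: float | None = None) -> SyntheticSpeaker:
        intel = severity if intelligibility is None else intelligibility
        return SyntheticSpeaker(
            id="spk",
            scores=ScorePair(intel, severity),
            embedding=np.zeros(512),
            ratings_int=np.zeros(6),
            ratings_sev=np.zeros(6),
        )

    return make
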