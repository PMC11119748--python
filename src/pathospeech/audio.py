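"""Reading-passage audio I/O, validation, resampling, and segmentation.

The raw input of the assessment pipeline is a mono recording of the canonical
French reading passage.  Recordings are normalized to 16 kHz mono with unit
peak amplitude, then cut into eight contiguous segments at natural breaks in
the text, located in the signal by an energy-based pause detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import InputError, SegmentationError, ValidationError

TARGET_SAMPLE_RATE = 16_000

_CANONICAL_PASSAGE = (
    "Monsieur Seguin n'avait jamais eu de bonheur avec ses chèvres. "
    "Il les perdait toutes de la même façon. "
    "Un beau matin, elles cassaient leur corde, s'en allaient dans la "
    "montagne, et là-haut le loup les mangeait. "
    "Ni les caresses de leur maître ni la peur du loup rien ne les retenait. "
    "C'était paraît-il des chèvres indépendantes voulant à tout prix le "
    "grand air et la liberté."
)

# Break anchors: the four sentence-final periods before the last sentence plus
# the three clause commas of the long third sentence.  Each anchor is the text
# that *ends* a segment; together they split the passage into eight spans.
_DEFAULT_BREAK_ANCHORS = (
    "avec ses chèvres.",
    "de la même façon.",
    "Un beau matin,",
    "cassaient leur corde,",
    "dans la montagne,",
    "le loup les mangeait.",
    "ne les retenait.",
)


def canonical_passage() -> str:
    """Return the canonical reading-passage text, verbatim."""
    return _CANONICAL_PASSAGE


@dataclass(frozen=True)
class Waveform:
    """A validated mono waveform with samples in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValidationError(f"expected mono samples, got shape {samples.shape}")
        if samples.size == 0:
            raise ValidationError("waveform is empty")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("waveform contains non-finite samples")
        if int(self.sample_rate) <= 0:
            raise ValidationError(f"sample rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate

    def slice_seconds(self, start_s: float, end_s: float) -> "Waveform":
        """Return the half-open interval [start_s, end_s) as a new Waveform."""
        i0 = int(round(start_s * self.sample_rate))
        i1 = int(round(end_s * self.sample_rate))
        if not (0 <= i0 < i1 <= self.samples.size):
            raise ValidationError(
                f"slice [{start_s}, {end_s}) outside recording of {self.duration:.3f} s"
            )
        return Waveform(self.samples[i0:i1], self.sample_rate)


@dataclass(frozen=True)
class PassageSegment:
    """One contiguous piece of a segmented passage recording.

    Times are a half-open interval [start_s, end_s) in seconds from the start
    of the recording; ``index`` is 1-based.
    """

    recording_id: str
    index: int
    start_s: float
    end_s: float
    text_span: str = ""

    def __post_init__(self):
        if self.index < 1:
            raise ValidationError(f"segment index must be >= 1, got {self.index}")
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"segment {self.index}: start_s {self.start_s} must be < end_s {self.end_s}"
            )

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


def peak_normalize(samples: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(samples))
    if peak > 0:
        return samples / peak
    return samples


def resample(w: Waveform, rate: int = TARGET_SAMPLE_RATE) -> Waveform:
    """Polyphase-resample to ``rate``; identity if already there."""
    if w.sample_rate == rate:
        return w
    g = math.gcd(w.sample_rate, rate)
    out = resample_poly(w.samples, rate // g, w.sample_rate // g)
    return Waveform(np.clip(out, -1.0, 1.0), rate)


def load_recording(path) -> Waveform:
    """Read a PCM/float WAV file as a peak-normalized 16 kHz mono Waveform.

    Stereo input is collapsed by channel averaging.  Integer PCM is scaled to
    [-1, 1] before peak normalization.
    """
    try:
        sr, data = wavfile.read(path)
    except FileNotFoundError:
        raise InputError(f"no such file: {path}") from None
    except Exception as exc:  # noqa: BLE001 - wavfile raises bare ValueError
        raise InputError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValidationError(f"zero-length audio: {path}")
    samples = np.asarray(data, dtype=np.float64)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if info.min < 0:
            samples = samples / max(abs(info.min), info.max)
        else:  # unsigned PCM is offset-binary
            half = (info.max + 1) / 2
            samples = (samples - half) / half
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    samples = peak_normalize(samples)
    return resample(Waveform(samples, sr))


def save_wav(path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV."""
    pcm = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(path, w.sample_rate, (pcm * 32767).astype(np.int16))


@dataclass(frozen=True)
class BreakSpec:
    """Where to cut a passage recording.

    Either ``cut_times_s`` gives explicit cut points in seconds, or the
    text-anchored default is used: ``break_anchors`` are substrings of the
    canonical passage whose ends mark the breaks, and each break is mapped to
    the nearest detected pause.  Pauses are runs of RMS energy below
    ``pause_threshold_dbfs`` (25 ms windows) lasting at least
    ``min_pause_s``.
    """

    cut_times_s: tuple[float, ...] | None = None
    passage: str = _CANONICAL_PASSAGE
    break_anchors: tuple[str, ...] = _DEFAULT_BREAK_ANCHORS
    pause_threshold_dbfs: float = -35.0
    min_pause_s: float = 0.15
    window_s: float = 0.025

    @classmethod
    def explicit(cls, cut_times_s) -> "BreakSpec":
        return cls(cut_times_s=tuple(float(t) for t in cut_times_s))

    def n_segments(self) -> int:
        if self.cut_times_s is not None:
            return len(self.cut_times_s) + 1
        return len(self.break_anchors) + 1

    def text_spans(self) -> list[str]:
        """Split the passage at the break anchors."""
        spans = []
        pos = 0
        for anchor in self.break_anchors:
            idx = self.passage.find(anchor, pos)
            if idx < 0:
                raise SegmentationError(f"break anchor not found in passage: {anchor!r}")
            end = idx + len(anchor)
            spans.append(self.passage[pos:end].strip())
            pos = end
        spans.append(self.passage[pos:].strip())
        return spans

    def break_fractions(self) -> list[float]:
        """Character position of each break as a fraction of passage length."""
        fractions = []
        pos = 0
        for anchor in self.break_anchors:
            idx = self.passage.find(anchor, pos)
            if idx < 0:
                raise SegmentationError(f"break anchor not found in passage: {anchor!r}")
            pos = idx + len(anchor)
            fractions.append(pos / len(self.passage))
        return fractions


def detect_pauses(
    w: Waveform,
    threshold_dbfs: float = -35.0,
    min_pause_s: float = 0.15,
    window_s: float = 0.025,
) -> list[tuple[float, float]]:
    """Return (start_s, end_s) intervals of sustained low energy.

    Energy is windowed RMS (non-overlapping windows) relative to full scale;
    a pause is a maximal run of windows below ``threshold_dbfs`` spanning at
    least ``min_pause_s``.
    """
    win = max(1, int(round(window_s * w.sample_rate)))
    n_win = w.samples.size // win
    if n_win == 0:
        return []
    frames = w.samples[: n_win * win].reshape(n_win, win)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    floor = 10.0 ** (threshold_dbfs / 20.0)
    quiet = rms < floor
    pauses: list[tuple[float, float]] = []
    start = None
    for i, q in enumerate(np.append(quiet, False)):
        if q and start is None:
            start = i
        elif not q and start is not None:
            t0, t1 = start * win / w.sample_rate, i * win / w.sample_rate
            if t1 - t0 >= min_pause_s:
                pauses.append((t0, t1))
            start = None
    return pauses


def _speech_span(w: Waveform, pauses: list[tuple[float, float]]) -> tuple[float, float]:
    """[start, end) of the speech portion: trim leading/trailing pauses."""
    start, end = 0.0, w.duration
    for p0, p1 in pauses:
        if p0 <= start + 1e-9:
            start = p1
        if p1 >= end - 1e-9:
            end = p0
    if start >= end:
        raise SegmentationError("recording contains no speech above the pause threshold")
    return start, end


def segment_passage(
    w: Waveform, breaks: BreakSpec | None = None, recording_id: str = "rec"
) -> list[PassageSegment]:
    """Cut a recording into contiguous passage segments.

    With explicit cut times the whole recording [0, duration) is split at the
    given points.  With the text-anchored default, pauses are detected, each
    text break is mapped to the nearest unused pause midpoint (in passage
    order), and the speech span is split there — yielding exactly eight
    segments for the canonical passage.
    """
    breaks = breaks or BreakSpec()
    if breaks.cut_times_s is not None:
        cuts = sorted(breaks.cut_times_s)
        if any(t <= 0 or t >= w.duration for t in cuts):
            raise ValidationError(
                f"cut times must lie strictly inside (0, {w.duration:.3f}) s"
            )
        bounds = [0.0, *cuts, w.duration]
        spans = [""] * (len(bounds) - 1)
    else:
        pauses = detect_pauses(
            w, breaks.pause_threshold_dbfs, breaks.min_pause_s, breaks.window_s
        )
        start, end = _speech_span(w, pauses)
        interior = [(p0, p1) for p0, p1 in pauses if p0 > start - 1e-9 and p1 < end + 1e-9]
        midpoints = [0.5 * (p0 + p1) for p0, p1 in interior]
        fractions = breaks.break_fractions()
        spans = breaks.text_spans()
        if len(midpoints) < len(fractions):
            missing = breaks.break_anchors[len(midpoints)]
            raise SegmentationError(
                f"only {len(midpoints)} pauses detected for {len(fractions)} breaks; "
                f"first unmatched break anchor: {missing!r}"
            )
        cuts = []
        available = list(midpoints)
        for frac in fractions:
            target = start + frac * (end - start)
            usable = [m for m in available if not cuts or m > cuts[-1]]
            if not usable:
                raise SegmentationError(
                    f"no remaining pause after {cuts[-1]:.3f} s for break at "
                    f"fraction {frac:.3f}"
                )
            nearest = min(usable, key=lambda m: abs(m - target))
            cuts.append(nearest)
            available.remove(nearest)
        bounds = [start, *cuts, end]
    return [
        PassageSegment(recording_id, i + 1, bounds[i], bounds[i + 1], spans[i])
        for i in range(len(bounds) - 1)
    ]


def segment_audio(w: Waveform, segments: list[PassageSegment]) -> list[Waveform]:
    """Extract the audio of each segment, in index order."""
    return [w.slice_seconds(s.start_s, s.end_s) for s in sorted(segments, key=lambda s: s.index)]


def segments_to_table(segments: list[PassageSegment]) -> str:
    """Serialize segments as a TSV table with a header row."""
    lines = ["recording_id\tindex\tstart_s\tend_s"]
    for s in sorted(segments, key=lambda s: s.index):
        lines.append(f"{s.recording_id}\t{s.index}\t{s.start_s:.6f}\t{s.end_s:.6f}")
    return "\n".join(lines) + "\n"
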