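"""Pitch-preserving temporal-distortion augmentation.

Training variants are produced by waveform-similarity overlap-add (WSOLA)
time-scale modification: the output plays ``1/alpha`` times as long as the
input while keeping the pitch and the spectral envelope, so the perceptual
character of the speech is preserved while its tempo changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import Waveform
from .errors import ValidationError

TEMPO_RANGE = (0.7, 1.3)


@dataclass(frozen=True)
class TempoFactor:
    """Dimensionless speed multiplier; output duration ~ input / alpha."""

    alpha: float

    def __post_init__(self):
        lo, hi = TEMPO_RANGE
        if not (lo <= self.alpha <= hi):
            raise ValidationError(
                f"tempo factor {self.alpha} outside allowed range [{lo}, {hi}]"
            )


def _wsola(x: np.ndarray, alpha: float, frame: int, tolerance: int) -> np.ndarray:
    """Waveform-similarity overlap-add time-scale modification.

    Synthesis frames are laid down every ``frame//2`` samples; each is chosen
    near its nominal analysis position (scaled by ``alpha``) at the lag, within
    ``+-tolerance``, that best continues the previously copied frame.
    """
    syn_hop = frame // 2
    window = np.hanning(frame)
    n_out = int(round(x.size / alpha))
    n_frames = max(1, int(np.ceil((n_out - frame) / syn_hop)) + 1)
    # Pad so every candidate window stays in bounds.
    pad = frame + tolerance + int(np.ceil(syn_hop * alpha)) + 1
    xp = np.concatenate([np.zeros(tolerance), x, np.zeros(pad)])
    out = np.zeros(n_out + frame)
    norm = np.zeros(n_out + frame)

    offset = 0  # deviation of the previously selected frame from nominal
    for m in range(n_frames):
        syn_pos = m * syn_hop
        ana_pos = int(round(syn_pos * alpha)) + tolerance
        if m == 0:
            sel = ana_pos
        else:
            # The natural continuation of the previous frame, advanced by one
            # synthesis hop, is the similarity target.
            target = prev_sel + syn_hop
            lo = ana_pos - tolerance
            cands = xp[lo : ana_pos + tolerance + frame]
            ref = xp[target : target + frame]
            corr = np.correlate(cands, ref, mode="valid")
            sel = lo + int(np.argmax(corr))
        seg = xp[sel : sel + frame]
        out[syn_pos : syn_pos + frame] += seg * window
        norm[syn_pos : syn_pos + frame] += window
        prev_sel = sel
        offset = sel - ana_pos  # kept for clarity; not used further

    norm[norm < 1e-8] = 1.0
    return (out / norm)[:n_out]


def tempo_distort(w: Waveform, factor: TempoFactor | float, seed: int = 0) -> Waveform:
    """Time-scale a waveform by ``alpha``, preserving pitch and envelope.

    ``seed`` is accepted for interface uniformity; the algorithm itself is
    deterministic.
    """
    if not isinstance(factor, TempoFactor):
        factor = TempoFactor(float(factor))
    alpha = factor.alpha
    if alpha == 1.0:
        return Waveform(w.samples.copy(), w.sample_rate)
    frame = int(round(0.040 * w.sample_rate))  # 40 ms frames
    frame += frame % 2
    tolerance = frame // 4
    out = _wsola(w.samples, alpha, frame, tolerance)
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out = out / peak
    return Waveform(out, w.sample_rate)


def augment_set(
    waveforms: list[Waveform],
    factors: list[TempoFactor | float],
    seed: int = 0,
) -> list[tuple[Waveform, dict]]:
    """Originals plus one tempo-distorted copy per (waveform, factor).

    Returns ``len(waveforms) * (len(factors) + 1)`` waveforms, each tagged
    with a provenance dict ``{"source": i, "alpha": a}`` (``alpha`` is None
    for originals).  Order is deterministic: for each source, the original
    first, then factors in the given order.
    """
    if not waveforms:
        raise ValidationError("augment_set requires at least one waveform")
    normalized = [f if isinstance(f, TempoFactor) else TempoFactor(float(f)) for f in factors]
    out: list[tuple[Waveform, dict]] = []
    for i, w in enumerate(waveforms):
        out.append((w, {"source": i, "alpha": None}))
        for f in normalized:
            out.append((tempo_distort(w, f, seed=seed), {"source": i, "alpha": f.alpha}))
    return out
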