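"""Fixed-length speaker embeddings from a TDNN with statistics pooling.

A waveform of arbitrary duration is mapped to a 512-dimensional vector:
log-mel filterbank frames pass through five time-delay (dilated 1-D
convolution) layers, a statistics-pooling layer concatenates the per-dimension
mean and standard deviation of the frame activations, and two fully connected
segment-level layers follow.  The embedding is read from the affine
(pre-nonlinearity) output of a designated segment layer.

Pretrained weights can be imported from the documented ``.npz`` container;
seeded random weights provide a deterministic stand-in for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .audio import Waveform
from .errors import ConfigurationError, ValidationError

EMBEDDING_DIM = 512
FRAME_LENGTH_S = 0.025
FRAME_SHIFT_S = 0.010
N_MELS = 24
MIN_DURATION_S = 0.5
LOG_FLOOR = 1e-10
DYNAMIC_RANGE_DB = 20.0

# (context offsets, output dim) for the five frame-level layers.
FRAME_LAYER_SPECS: tuple[tuple[tuple[int, ...], int], ...] = (
    ((-2, -1, 0, 1, 2), 512),
    ((-2, 0, 2), 512),
    ((-3, 0, 3), 512),
    ((0,), 512),
    ((0,), 1500),
)
SEGMENT_DIMS = (512, 512)


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, sample_rate: int, fmin: float = 20.0, fmax: float = 7600.0
) -> np.ndarray:
    """Triangular mel filters as an (n_mels, n_fft // 2 + 1) matrix."""
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bin_freqs = np.linspace(0, sample_rate / 2, n_fft // 2 + 1)
    fb = np.zeros((n_mels, bin_freqs.size))
    for i in range(n_mels):
        left, center, right = hz_pts[i : i + 3]
        up = (bin_freqs - left) / max(center - left, 1e-12)
        down = (right - bin_freqs) / max(right - center, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def compute_features(
    w: Waveform,
    n_mels: int = N_MELS,
    mean_normalize: bool = True,
) -> np.ndarray:
    """Log-mel filterbank frames (n_frames, n_mels), 25 ms window / 10 ms hop.

    Per-utterance mean normalization (subtracting each coefficient's mean over
    frames) is applied by default.  Inputs shorter than 0.5 s are rejected.

    Band energies are floored at ``DYNAMIC_RANGE_DB`` below the utterance's
    median band power (with ``LOG_FLOOR`` as the absolute minimum), so silent
    frames compress toward the speech level instead of becoming extreme
    outliers that would dominate the pooled statistics downstream.
    """
    if w.sample_rate != 16_000:
        raise ValidationError(f"features require 16 kHz input, got {w.sample_rate} Hz")
    if w.duration < MIN_DURATION_S:
        raise ValidationError(
            f"input of {w.duration:.3f} s is shorter than the minimum {MIN_DURATION_S} s"
        )
    win = int(round(FRAME_LENGTH_S * w.sample_rate))
    hop = int(round(FRAME_SHIFT_S * w.sample_rate))
    n_frames = (w.samples.size - win) // hop + 1
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = w.samples[idx] * np.hanning(win)[None, :]
    n_fft = 512
    power = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(n_mels, n_fft, w.sample_rate)
    banded = power @ fb.T
    floor = np.maximum(
        LOG_FLOOR, np.median(banded, axis=0) * 10.0 ** (-DYNAMIC_RANGE_DB / 10.0)
    )
    feats = np.log(np.maximum(banded, floor))
    if mean_normalize:
        feats = feats - feats.mean(axis=0, keepdims=True)
    return feats


def statistics_pool(frames: np.ndarray) -> np.ndarray:
    """Concatenate per-dimension mean and population standard deviation.

    Maps a (T, D) frame matrix to a length-2D vector; invariant to frame
    order by construction.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 2 or frames.shape[0] == 0:
        raise ValidationError("statistics_pool requires a non-empty (T, D) matrix")
    return np.concatenate([frames.mean(axis=0), frames.std(axis=0)])


@dataclass
class _Layer:
    """One affine layer with batch-norm statistics (inference only here)."""

    weight: np.ndarray  # (out_dim, fan_in)
    bias: np.ndarray  # (out_dim,)
    bn_gamma: np.ndarray
    bn_beta: np.ndarray
    bn_mean: np.ndarray
    bn_var: np.ndarray

    def batchnorm(self, x: np.ndarray) -> np.ndarray:
        return self.bn_gamma * (x - self.bn_mean) / np.sqrt(self.bn_var + 1e-5) + self.bn_beta


@dataclass
class ExtractorWeights:
    """All parameters of the embedding extractor, plus provenance metadata."""

    frame_layers: list[_Layer]
    segment_layers: list[_Layer]
    n_mels: int = N_MELS
    tap_layer: str = "last"  # "last" or "first" segment layer
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        in_dim = self.n_mels
        for i, ((ctx, out_dim), layer) in enumerate(zip(FRAME_LAYER_SPECS, self.frame_layers)):
            fan_in = in_dim * len(ctx)
            if layer.weight.shape != (out_dim, fan_in):
                raise ConfigurationError(
                    f"frame layer {i}: expected weight shape {(out_dim, fan_in)}, "
                    f"got {layer.weight.shape}"
                )
            in_dim = out_dim
        in_dim = 2 * FRAME_LAYER_SPECS[-1][1]
        for i, (out_dim, layer) in enumerate(zip(SEGMENT_DIMS, self.segment_layers)):
            if layer.weight.shape != (out_dim, in_dim):
                raise ConfigurationError(
                    f"segment layer {i}: expected weight shape {(out_dim, in_dim)}, "
                    f"got {layer.weight.shape}"
                )
            in_dim = out_dim

    @property
    def receptive_field(self) -> int:
        """Minimum number of feature frames the TDNN stack requires."""
        return 1 + sum(max(c) - min(c) for c, _ in FRAME_LAYER_SPECS)


def init_random_weights(seed: int, n_mels: int = N_MELS, tap_layer: str = "last") -> ExtractorWeights:
    """Deterministic Glorot-initialized weights; a test double for pretraining."""
    rng = np.random.default_rng(seed)

    def make_layer(fan_in: int, fan_out: int) -> _Layer:
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        return _Layer(
            weight=rng.normal(0.0, scale, size=(fan_out, fan_in)),
            bias=np.zeros(fan_out),
            bn_gamma=np.ones(fan_out),
            bn_beta=np.zeros(fan_out),
            bn_mean=np.zeros(fan_out),
            bn_var=np.ones(fan_out),
        )

    frame_layers = []
    in_dim = n_mels
    for ctx, out_dim in FRAME_LAYER_SPECS:
        frame_layers.append(make_layer(in_dim * len(ctx), out_dim))
        in_dim = out_dim
    segment_layers = []
    in_dim = 2 * FRAME_LAYER_SPECS[-1][1]
    for out_dim in SEGMENT_DIMS:
        segment_layers.append(make_layer(in_dim, out_dim))
        in_dim = out_dim
    return ExtractorWeights(
        frame_layers,
        segment_layers,
        n_mels=n_mels,
        tap_layer=tap_layer,
        provenance={"kind": "seeded-random", "seed": int(seed)},
    )


def _tdnn_layer(x: np.ndarray, ctx: tuple[int, ...], layer: _Layer) -> np.ndarray:
    """Apply one TDNN layer with 'valid' framing: (T, D) -> (T - span, out)."""
    offsets = np.asarray(ctx) - min(ctx)
    span = max(ctx) - min(ctx)
    t_out = x.shape[0] - span
    if t_out < 1:
        raise ValidationError(
            f"too few frames ({x.shape[0]}) for temporal context {ctx}"
        )
    gathered = np.concatenate([x[o : o + t_out] for o in offsets], axis=1)
    h = gathered @ layer.weight.T + layer.bias
    return layer.batchnorm(np.maximum(h, 0.0))


def extract_embedding(w: Waveform, weights: ExtractorWeights) -> np.ndarray:
    """Map a waveform to its 512-dimensional speaker embedding.

    Deterministic for fixed weights; the vector is the affine output of the
    segment layer selected by ``weights.tap_layer``.
    """
    feats = compute_features(w, n_mels=weights.n_mels)
    if feats.shape[0] < weights.receptive_field:
        raise ValidationError(
            f"{feats.shape[0]} frames < TDNN receptive field {weights.receptive_field}; "
            f"provide at least {MIN_DURATION_S} s of audio"
        )
    x = feats
    for (ctx, _), layer in zip(FRAME_LAYER_SPECS, weights.frame_layers):
        x = _tdnn_layer(x, ctx, layer)
    pooled = statistics_pool(x)

    seg1 = weights.segment_layers[0]
    affine1 = pooled @ seg1.weight.T + seg1.bias
    if weights.tap_layer == "first":
        return affine1
    h1 = seg1.batchnorm(np.maximum(affine1, 0.0))
    seg2 = weights.segment_layers[1]
    return h1 @ seg2.weight.T + seg2.bias


def save_weights(weights: ExtractorWeights, path) -> None:
    """Serialize to an ``.npz`` container with an embedded JSON manifest."""
    arrays = {}
    manifest = {
        "n_mels": weights.n_mels,
        "tap_layer": weights.tap_layer,
        "provenance": weights.provenance,
        "layers": [],
    }
    for group, layers in (("frame", weights.frame_layers), ("segment", weights.segment_layers)):
        for i, layer in enumerate(layers):
            for name in ("weight", "bias", "bn_gamma", "bn_beta", "bn_mean", "bn_var"):
                key = f"{group}{i}.{name}"
                arr = getattr(layer, name)
                arrays[key] = arr
                manifest["layers"].append(
                    {"key": key, "shape": list(arr.shape), "dtype": str(arr.dtype)}
                )
    arrays["__manifest__"] = np.frombuffer(
        json.dumps(manifest).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_weights(path) -> ExtractorWeights:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode("utf-8"))

        def read_layer(group: str, i: int) -> _Layer:
            return _Layer(
                *(data[f"{group}{i}.{name}"] for name in
                  ("weight", "bias", "bn_gamma", "bn_beta", "bn_mean", "bn_var"))
            )

        frame_layers = [read_layer("frame", i) for i in range(len(FRAME_LAYER_SPECS))]
        segment_layers = [read_layer("segment", i) for i in range(len(SEGMENT_DIMS))]
    return ExtractorWeights(
        frame_layers,
        segment_layers,
        n_mels=int(manifest["n_mels"]),
        tap_layer=manifest["tap_layer"],
        provenance=manifest.get("provenance", {}),
    )
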