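"""Synthetic cohorts with known ground truth.

Clinical speech corpora are private, so every other module is exercised on
generated data whose structure is known exactly: speakers carry coupled
intelligibility/severity scores on [0, 10]; embeddings are a linear function
of the two scores along fixed orthonormal directions plus optional nuisance
components and isotropic noise (so ordinary least squares on the signal
directions bounds achievable prediction quality); judge panels follow a
subject + judge-bias + error variance-components model; toy passage audio is
eight voiced bursts whose harmonic-to-noise ratio degrades with severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import Waveform
from .errors import ValidationError
from .metrics import RatingsMatrix
from .regressor import LabeledExample, ScorePair


@dataclass(frozen=True)
class JudgePanelSpec:
    k: int = 6
    bias_sd: float = 1.0
    error_sd: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    n_speakers: int = 100
    severity_distribution: str = "uniform"  # uniform on [0, 10]
    int_sev_coupling_sd: float = 1.0
    embedding_dim: int = 512
    signal_directions_seed: int = 0
    nuisance_dim: int = 0
    nuisance_sd: float = 1.0
    noise_sd: float = 0.5
    judges: JudgePanelSpec = field(default_factory=JudgePanelSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_speakers < 2:
            raise ValidationError(f"need >= 2 speakers, got {self.n_speakers}")
        for name in ("int_sev_coupling_sd", "noise_sd", "nuisance_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.nuisance_dim >= self.embedding_dim:
            raise ValidationError(
                f"nuisance_dim {self.nuisance_dim} must be < embedding_dim {self.embedding_dim}"
            )
        if self.severity_distribution != "uniform":
            raise ValidationError(
                f"unknown severity distribution {self.severity_distribution!r}"
            )


@dataclass(frozen=True)
class SyntheticSpeaker:
    id: str
    scores: ScorePair
    embedding: np.ndarray
    ratings_int: np.ndarray  # per-judge intelligibility ratings
    ratings_sev: np.ndarray


def signal_directions(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """The two fixed orthonormal directions that carry INT and SEV."""
    rng = np.random.default_rng(spec.signal_directions_seed)
    a = rng.normal(size=spec.embedding_dim)
    b = rng.normal(size=spec.embedding_dim)
    u1 = a / np.linalg.norm(a)
    b = b - (b @ u1) * u1
    u2 = b / np.linalg.norm(b)
    return u1, u2


def sample_cohort(spec: CohortSpec) -> list[SyntheticSpeaker]:
    """Draw a fully reproducible synthetic cohort from the spec.

    SEV ~ Uniform[0, 10]; INT = clamp(SEV + N(0, coupling_sd), 0, 10);
    embedding = u1*INT + u2*SEV + nuisance + N(0, noise_sd) per dimension;
    ratings_ij = clamp(true_i + bias_j + N(0, error_sd), 0, 10).
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_speakers, spec.embedding_dim
    sev = rng.uniform(0.0, 10.0, size=n)
    intel = np.clip(sev + rng.normal(0.0, spec.int_sev_coupling_sd, size=n), 0.0, 10.0)

    u1, u2 = signal_directions(spec)
    emb = np.outer(intel, u1) + np.outer(sev, u2)
    if spec.nuisance_dim > 0:
        dir_rng = np.random.default_rng(spec.signal_directions_seed + 1)
        V = dir_rng.normal(size=(d, spec.nuisance_dim))
        V /= np.linalg.norm(V, axis=0, keepdims=True)
        z = rng.normal(0.0, spec.nuisance_sd, size=(n, spec.nuisance_dim))
        emb = emb + z @ V.T
    if spec.noise_sd > 0:
        emb = emb + rng.normal(0.0, spec.noise_sd, size=(n, d))

    k = spec.judges.k
    bias = rng.normal(0.0, spec.judges.bias_sd, size=k)
    err_int = rng.normal(0.0, spec.judges.error_sd, size=(n, k))
    err_sev = rng.normal(0.0, spec.judges.error_sd, size=(n, k))
    ratings_int = np.clip(intel[:, None] + bias[None, :] + err_int, 0.0, 10.0)
    ratings_sev = np.clip(sev[:, None] + bias[None, :] + err_sev, 0.0, 10.0)

    width = len(str(n - 1))
    return [
        SyntheticSpeaker(
            id=f"spk{str(i).zfill(width)}",
            scores=ScorePair(float(intel[i]), float(sev[i])),
            embedding=emb[i],
            ratings_int=ratings_int[i],
            ratings_sev=ratings_sev[i],
        )
        for i in range(n)
    ]


def cohort_to_training_table(cohort: list[SyntheticSpeaker]) -> list[LabeledExample]:
    """One labeled example per speaker, targets = true scores."""
    return [
        LabeledExample(
            embedding=s.embedding,
            target=s.scores,
            provenance={"speaker_id": s.id, "segment_index": None, "alpha": None},
        )
        for s in cohort
    ]


def cohort_ratings_matrix(cohort: list[SyntheticSpeaker], task: str = "int") -> RatingsMatrix:
    if task not in ("int", "sev"):
        raise ValidationError(f"task must be 'int' or 'sev', got {task!r}")
    rows = [s.ratings_int if task == "int" else s.ratings_sev for s in cohort]
    values = np.stack(rows)
    return RatingsMatrix(
        values,
        subjects=[s.id for s in cohort],
        judges=[f"judge{j}" for j in range(values.shape[1])],
    )


def synth_passage_audio(
    speaker: SyntheticSpeaker,
    seed: int = 0,
    sample_rate: int = 16_000,
    burst_s: float = 0.6,
    gap_s: float = 0.35,
    f0: float | None = None,
) -> Waveform:
    """Toy passage recording: 8 voiced bursts separated by silences.

    Each burst mixes a harmonic complex at the speaker's fundamental with
    white noise; the noise share grows as severity drops, so spectral
    flatness is monotone in (10 - SEV).  The silences exceed the default
    pause detector's minimum, so the output always segments into 8 pieces.
    """
    rng = np.random.default_rng(seed)
    sev = speaker.scores.severity
    if f0 is None:
        f0 = 90.0 + 120.0 * rng.random()
    noise_share = 0.05 + 0.9 * (10.0 - sev) / 10.0

    n_burst = int(round(burst_s * sample_rate))
    t = np.arange(n_burst) / sample_rate
    envelope = np.hanning(n_burst)
    pieces = [np.zeros(int(round(0.25 * sample_rate)))]
    for _ in range(8):
        harm = sum(
            np.sin(2 * np.pi * f0 * h * t + rng.uniform(0, 2 * np.pi)) / h
            for h in range(1, 6)
        )
        harm = harm / np.max(np.abs(harm))
        noise = rng.normal(0.0, 0.3, size=n_burst)
        burst = ((1.0 - noise_share) * harm + noise_share * noise) * envelope
        pieces.append(burst / max(np.max(np.abs(burst)), 1e-9) * 0.9)
        pieces.append(np.zeros(int(round(gap_s * sample_rate))))
    samples = np.concatenate(pieces)
    return Waveform(samples, sample_rate)


def save_cohort_tables(cohort: list[SyntheticSpeaker], outdir) -> None:
    """Write the training table, embeddings and both ratings matrices as TSV."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "scores.tsv", "w") as fh:
        fh.write("speaker_id\tintelligibility\tseverity\n")
        for s in cohort:
            fh.write(f"{s.id}\t{s.scores.intelligibility:.6f}\t{s.scores.severity:.6f}\n")
    emb = np.stack([s.embedding for s in cohort])
    header = "speaker_id\t" + "\t".join(f"e{j}" for j in range(emb.shape[1]))
    with open(outdir / "embeddings.tsv", "w") as fh:
        fh.write(header + "\n")
        for s in cohort:
            fh.write(s.id + "\t" + "\t".join(f"{v:.8g}" for v in s.embedding) + "\n")
    cohort_ratings_matrix(cohort, "int").to_tsv(outdir / "ratings_int.tsv")
    cohort_ratings_matrix(cohort, "sev").to_tsv(outdir / "ratings_sev.tsv")
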