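# pathospeech

Automatic assessment of speech intelligibility (INT) and speech-disorder
severity (SEV) from passage-reading recordings, plus longitudinal patient
score tracking. The pipeline:

1. **audio** — load/validate WAV, downsample to 16 kHz mono, peak-normalize,
   and cut the canonical French reading passage into eight contiguous
   segments at natural text breaks, located by an energy-based pause detector.
2. **augment** — pitch- and envelope-preserving tempo distortion (WSOLA
   time-scale modification) to multiply training material.
3. **xvector** — 512-dimensional speaker embeddings from a five-layer TDNN
   with statistics pooling and two fully connected segment layers (log-mel
   front end, 25/10 ms framing, utterance mean normalization). Pretrained
   weights can be imported from the documented `.npz` container; seeded
   random weights are the built-in test double.
4. **regressor** — shallow multi-task network ([emb×128], [128×64], two
   [64×1] heads; ReLU + batch norm + 20 % dropout on the hidden layers)
   trained with Adam (lr 0.001, batch 8, 20 epochs) on the 50/50-weighted
   sum of per-task MSE losses. Inference outputs are clamped to the 0–10
   clinical scale.
5. **metrics** — Spearman's ρ, RMSE, and the intraclass correlation
   coefficient (two-way model, absolute agreement; single and average forms)
   computed from the ANOVA mean squares.
6. **cohort** — synthetic speakers/embeddings/judge panels with known ground
   truth, so everything is testable without clinical data.
7. **store** — patient registry with timestamped sessions, sorting,
   filtering, cascade deletion, and plain-TSV persistence.

Everything is numpy/scipy; no deep-learning framework is required.

## CLI

```bash
pathospeech segment rec.wav                      # 8-segment table (+ --out dir for WAVs)
pathospeech augment wavdir/ --factors 0.9,1.1 -o augdir/
pathospeech embed rec.wav -o emb.tsv             # 512-dim embedding (seeded weights by default)
pathospeech simulate --n-speakers 200 -o cohort/ # synthetic cohort tables
pathospeech train train.tsv -o model.npz
pathospeech predict rec.wav --model model.npz --strategy whole|segments
pathospeech evaluate --pred pred.tsv --ref ref.tsv
pathospeech icc ratings.tsv --form average
pathospeech patient add IP001 "Alice Martin" 1960-04-02 --store store/
pathospeech session add IP001 6.5 5.5 --store store/
pathospeech history IP001 --sort score --from 2024-01-01 --store store/
```

Training tables are TSV with columns `speaker_id`, `intelligibility`,
`severity` and either embedding columns `e0..eN` or an `embedding_path`
column. Ratings matrices are TSV with a header row of judge ids and a first
column of subject ids.

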