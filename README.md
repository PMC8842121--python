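# corepromoter

Analysis toolkit for core-promoter structure–function studies built on
dual-luciferase reporter assays of designed synthetic promoters. The package
covers the full computational path of such a study:

- **`motifs` / `motifs_io`** — PPM/PWM motif models with log2-odds scoring,
  enriched-region scanning, information content, and consensus extraction;
  MEME-minimal and a JSON dialect (threshold, enriched region, background,
  source tag) for serialization.
- **`tss`** — TSS tag-cluster calling (rectangular-kernel smoothing,
  min-tag/isolation/association filters) and the size-independent MAD
  peakedness score.
- **`architecture`** — quantile gene sets, mutual-information-optimized PWM
  score thresholds on a −15..30 × 0.1 grid, MCC motif–feature association,
  binomial enrichment Z-profiles, architecture class assignment, positioned
  dinucleotide profiles, and smoothed site-position histograms.
- **`conservation`** — binding-site conservation scores against per-species
  null sets sampled from position-specific substitution models learned on
  alignment context (±10 bp).
- **`design`** — the synthetic-promoter mutation engine: knockouts (random /
  background / pairwise / all), consensus replacement and insertion, strength
  series, saturation point mutations, cross-architecture substitution with
  TSS-anchor alignment, positional shifts (motif / all motifs / context),
  context exchange, intra- and inter-block combinatorics, block assembly
  (703 / 459 nt with 4-nt junction overhangs), downstream-ATG sanitization,
  side-effect validation, and 3-fold-enrichment clone resolution.
- **`plates`** — dual-luciferase normalization: pooled negative-control
  background, pUG9 normalization factor, FF1/FF2 selection at 2×10⁵ RLU,
  REN range filtering (300–10,000), log2 expression, and replicate outlier
  flagging at 3× the library noise scale.
- **`effects`** — fold-change effects vs wild type, pairwise additivity with
  3×SD noise gating, expression-based activity logos, positional-shift
  profiles, hormone inducibility, and standard two-sample tests.
- **`models`** — 0/1 mutation-indicator linear regression (minimum-norm on
  rank-deficient designs) and the parameter-free additive predictor, with
  Pearson-r / prediction-band evaluation.
- **`synth`** — seeded generators for every input: motif sets with
  calibrated thresholds, promoters with planted annotations, TSS tag tracks,
  toy species alignments, and plate simulations driven by an explicit
  additive-log2 truth model (lognormal noise, FF2 quenching, ecdysone boost
  with saturation ceiling) for parameter-recovery testing.
- **`ev1`** — benchmark statistics recomputed from the study's deposited
  raw dataset when a local conversion is present (see module docstring for
  the expected schema).

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion;
criterion 10 requires the study's deposited supplementary dataset under
`data/ev1/` (`plates.csv` + `constructs.tsv`, schema in `corepromoter.ev1`)
and fails with an explanatory message when it is absent.

## CLI

```bash
corepromoter make-fixtures --seed 1 --out fixtures/
corepromoter design --promoters fixtures/promoters.fasta \
    --motifs fixtures/motifs.json --spec plan.yaml --seed 1 --out designs/
corepromoter normalize --plates fixtures/plates.csv --out normalized.tsv --qc qc.json
corepromoter effects --normalized normalized.tsv --reference prom0 --out effects.tsv
corepromoter architecture --promoters fixtures/promoters.fasta \
    --motifs fixtures/motifs.json --gene-sets sets.tsv --out thresholds.tsv
corepromoter conserve --motifs fixtures/motifs.json --pairs pairs.fasta \
    --motif INR --out conservation.tsv
corepromoter logo --normalized normalized.tsv --manifest pointmutants.tsv \
    --motif INR --out logo.meme
corepromoter fit --normalized normalized.tsv --manifest designs/manifest.tsv \
    --out model_card.json
corepromoter report --effects effects.tsv --out report/
corepromoter run --config pipeline.yaml     # staged end-to-end run
```

All commands are deterministic given `--seed` (or the config seed) and write
plain text outputs plus a `run_report.json` with checksums where applicable.

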