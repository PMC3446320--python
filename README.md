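# circasplice

Probe-level exon-array modelling and circadian alternative-splicing
screening, with a synthetic-data generator so the whole pipeline is testable
without external array data.

The package covers:

- **`synth`** — seeded generation of probe-level intensity matrices with
  additive chip + probe structure, 24-h transcript rhythms, probeset-level
  circadian (24-h) or ultradian (12-h) splice departures, matched pseudo-Ct
  QPCR tables, and promoter sets with planted motifs, all with a ground-truth
  table.
- **`chipmodel`** — quantile normalization, per-transcript-cluster Tukey
  median-polish fits of the additive log2 probe model, transcript-level
  expression estimates, and per-probeset splice-departure scores
  (`2**median(residuals)`, so 1 = no departure).
- **`rhythmscreen`** — per-probeset one-way ANOVA for an effect of circadian
  time on log2 scores, optional empirical-Bayes variance moderation,
  Benjamini–Hochberg FDR control, and an antiphase `{t, t+12}` vs
  `{t+6, t+18}` contrast that removes 12-h ultradian probesets.
- **`profiles`** — signed fold changes vs CT0, acrophase/amplitude, Pearson
  profile correlation, moving-average smoothing + z-scoring, signal-to-noise
  ranking of two-day profiles, SOTA and average-linkage hierarchical
  clustering with correlation distance, balanced two-way ANOVA with
  Bonferroni planned comparisons.
- **`qpcr`** — relative quantification from Ct or relative concentrations,
  normalizer correction, fold vs a reference group, the exon/transcript
  splicing index, and gel-band percent inclusion.
- **`motifscan`** — pseudocount-regularized PSSMs (with consensus-derived
  stand-ins for the E-box, E'-box, D-box and RRE), promoter extraction
  (5 kb upstream of the TSS through the end of the first intron), a
  both-strand log-odds scan, and one-tailed Fisher enrichment between gene
  sets.
- **`nmdframe`** — classification of cassette-exon skipping consequences
  (frame-preserving, new N/C terminus, NMD candidate, penultimate-exon NMD
  insensitivity).
- **`cli_io`** — TSV/FASTA/PSSM formats, YAML pipeline configuration,
  logging, and the `circasplice` command-line interface.

## CLI

```sh
# generate a synthetic dataset with planted circadian splice departures
circasplice simulate --outdir data --seed 1 --frac-circadian-splice 0.05

# fit the probe model and compute splice-departure scores
circasplice fit --layout data/layout.tsv --intensities data/intensities.tsv \
    --out scores.tsv

# run the circadian screen with the ultradian-exclusion filter
circasplice screen --scores scores.tsv --design data/design.tsv \
    --out screen.tsv --alpha 0.05 --moderated

# or run everything from one YAML config
circasplice run --config pipeline.yaml
```

A minimal `pipeline.yaml`:

```yaml
outdir: results/run1
seed: 1
alpha: 0.05
n_clusters: 4
simulate:
  n_clusters: 20
  probesets_per_cluster: 50
  frac_circadian_splice: 0.05
  seed: 1
```

Other subcommands: `cluster` (SOTA on z-scored CT profiles), `phase`
(acrophase/amplitude), `compare` (two-way ANOVA + Bonferroni post hoc),
`validate` (QPCR relative expression), `scan` (PSSM promoter scan), `nmd`
(cassette-exon frame report).

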