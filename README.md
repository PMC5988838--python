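# sangerhts

Simulation and analysis toolkit for asking when classical Sanger sequencing of
a mixed symbiont community (e.g. lichen photobionts) recovers the same
dominant taxon as high-throughput amplicon metabarcoding.

The package covers the full comparison pipeline:

- **`sangerhts.synthetic_data`** — generate a panel of closely related ITS
  reference haplotypes (ITS1–5.8S–ITS2, substitution-only divergence within a
  95–99% identity band), per-sample mixed communities with a well-defined
  dominant member, multinomial HTS read-count vectors, and mixed-template
  Sanger chromatograms whose peak heights mix the templates in proportion to
  abundance.
- **`sangerhts.hts_pipeline`** — OTU count tables with the two-stage clean-up
  (per-sample 0.005% abundance floor, then 5%-of-samples prevalence floor)
  plus the optional "predominant rescue" that restores a prevalence-filtered
  OTU if it was the most abundant member of at least one sample.
- **`sangerhts.sanger`** — base calling under the 25% secondary-peak rule
  (IUPAC codes for every base above the threshold), zero-tolerance ambiguity /
  truncation QC, and anchor-motif extraction of the ITS1/ITS2 subregions.
- **`sangerhts.assignment_concordance`** — affine-gap global alignment percent
  identity (hand-rolled Gotoh DP, IUPAC-aware queries), best-hit OTU
  assignment (95% floor, 99% acceptance, unique best hit with a margin),
  secondary-abundance categories 1–5, per-category success summaries,
  abundance-sorted greedy clustering, and the ITS1-vs-ITS2 resolution
  comparison.
- **`sangerhts.cli_io`** — plain-text formats (FASTA, TSV, YAML config, JSON
  manifest) and the deterministic end-to-end pipeline runner.

## CLI

A single entry point with stagewise subcommands:

```sh
sangerhts run-all --seed 1 --out runs/demo           # full simulated experiment
sangerhts simulate --seed 1 --out runs/sim           # panel, communities, counts, traces
sangerhts filter --table runs/sim/hts_counts.tsv \
    --abundance-floor 5e-5 --prevalence-floor 0.05 \
    --rescue-predominant --out runs/filtered.tsv
sangerhts basecall --chromatograms runs/sim/chromatograms.tsv \
    --secondary-peak-threshold 0.25 --out runs/called
sangerhts assign --sequences runs/called/called_sequences.fasta \
    --panel runs/sim/panel.fasta --qc runs/called/qc.tsv --out runs/assignments.tsv
sangerhts categorize --abundances runs/demo/relative_abundances.tsv --out runs/cats.tsv
sangerhts concordance --qc runs/called/qc.tsv --assignments runs/assignments.tsv \
    --categories runs/cats.tsv --out runs/concordance
sangerhts cluster-its1 --sequences its1.fasta --identity 99 --out clusters.tsv
```

All thresholds live once in a YAML `PipelineConfig` (`--config file.yaml`);
`run-all` writes a `manifest.json` with the config, seed and per-file SHA-256
checksums, and re-running the same config reproduces identical checksums.

## File formats

- FASTA (70-column wrap) for panels and called sequences; record ids of
  called sequences are `<sample_id>|<marker>`.
- TSV with one header line and a leading `sample_id` column for count tables,
  relative abundances, QC tables, assignments and categories (`#` lines are
  comments; the generating seed is recorded there and in FASTA headers).
- Chromatograms as a long TSV: `sample_id  marker  position  A  C  G  T`.

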