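# effluxkit

Functional characterization of ABCA1 missense variants from raw assay
readouts: the package turns plate-reader cholesterol-efflux wells into
corrected, WT-normalized activities, derives pathogenic/benevolent
thresholds from control constructs and cross-species conservation,
assigns three-class pathogenicity calls (loss-of-function / uncertain /
benevolent), quantifies total and cell-surface protein from densitometry,
calls treatment-rescue and ApoA1-stabilization responses, and scores
membrane colocalization — all exercised end-to-end on a synthetic-data
generator with known ground truth.

## What it computes

- **Efflux**: `medium / (medium + lysate)` per well, corrected for
  acceptor-independent leakage (mock wells without acceptor) and
  unspecific efflux (mock wells), optionally rescaled by co-transfected
  renilla luminescence, and normalized per experiment to WT (= 100%).
- **Statistics**: two-sample t-tests choosing pooled vs Welch form by a
  two-sided variance-ratio F-test at α=0.05; one- or two-tailed; star
  annotations (`*` p<0.05 … `****` p<1e-4).
- **Calibration**: the pathogenic cutoff anchors at the highest-activity
  pathogenic control (50% of WT with the default panel); the benevolent
  cutoff is the rounded mean of the three lowest-activity variants whose
  alternate residue appears as reference in >2 of 29 alignment species
  (80% with the published calibration values).
- **Protein**: total ABCA1 = sum of both specific bands / β-actin,
  relative to same-blot WT; surface = pull-down signal corrected for
  total protein; treatment responders by one-tailed tests vs matched
  mock-treated arms.
- **Colocalization**: whole-image Pearson r between the transporter and
  membrane-marker channels, averaged within then across experiments.

## CLI

```sh
# generate the study-shaped synthetic fixture (51 query variants,
# 5 controls, 4 experiments, 29-species alignment, image pairs)
effluxkit simulate --out inputs/ --seed 7

# full pipeline -> report.tsv + provenance.json
effluxkit all --out run/ --input-dir inputs/ --seed 7

# individual stages
effluxkit efflux   --wells inputs/wells.tsv --out run/
effluxkit classify --variants inputs/variants.tsv \
                   --summary run/activity_summary.tsv \
                   --msa inputs/msa.fasta --out run/
effluxkit quant    --blots inputs/blots.tsv --surface inputs/surface.tsv --out run/
effluxkit coloc    --input-dir inputs/ --out run/
```

Useful flags: `--renilla-normalize` (apply the transfection-efficiency
rescaling, off by default), `--benevolent-boundary {ge,gt}` (≥80% vs
strictly >80%), `--seed`, `--log-level`.

All inputs and outputs are plain TSV/FASTA/JSON (images are 16-bit
single-channel TIFF pairs); runs are deterministic for a given seed.

## Layout

| module | role |
| --- | --- |
| `effluxkit.simulate` | synthetic wells, blots, surface assays, alignments, image pairs |
| `effluxkit.efflux` | efflux fractions, corrections, WT normalization, aggregation |
| `effluxkit.stats` | F-test-gated t-tests, star annotation |
| `effluxkit.classify` | HGVS p. parsing, conservation counting, thresholds, 3-class calls, domain annotation |
| `effluxkit.quant` | densitometry/surface quantification, treatment-response calls |
| `effluxkit.coloc` | Pearson colocalization and nested summaries |
| `effluxkit.fixtures` | study-shaped fixture panel and writer |
| `effluxkit.pipeline` / `effluxkit.cli` | stage orchestration, provenance, command line |
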