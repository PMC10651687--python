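# tmtcycle

Analysis toolkit for multi-plex TMT proteomes of genotype × feeding designs,
with a matching diurnal-transcriptome rhythmicity engine. It implements, as
reusable and tested components:

- **syndata** — synthetic proteome/transcriptome generator with planted
  ground truth (genotype-dependent proteins, rescue status, feeding
  responses, rhythmic and mean-shifted genes, secreted annotation, QC
  flags, an optional corrupted sample).
- **normalize** — contaminant/decoy/single-oxidized-peptide filtering,
  pooled-reference log-ratio normalization with per-sample median
  centering, PCA QC and parametric outlier flagging.
- **diffabund** — vectorized two-sample t-tests (pooled or Welch) with
  Benjamini–Hochberg FDR, plus per-protein type-II two-way ANOVA with
  Tukey–Kramer cell comparisons.
- **classify** — decision rules: genotype dependence (q < α on the WT vs
  KO contrast), rescued/nonrescued/partial labels from the rescue-genotype
  contrasts, per-genotype feeding response at strict and relaxed
  thresholds, cross-tissue overlap, secreted-fraction Fisher testing,
  subunit-set averaging and exact percentage summaries.
- **rhythm** — two-group cosinor model enumeration (5 models, fixed
  24 h period) selected by BIC weights, shared-vs-distinct mean models,
  and a peak-phase window filter.
- **concord** — proteome–transcriptome join with concordance fractions
  and reverse (gene → protein) lookup.
- **enrich** — hypergeometric overrepresentation analysis against GMT
  gene sets over a detection universe.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria. One clause is
an intentionally red assertion: recall of planted effects at the
σ = 0.25 operating point cannot reach 95% with a pooled t-test at n = 4
(the test message and `scripts/acceptance.py` docstring explain the
power analysis).

## CLI

All stages are exposed as subcommands of the `tmtcycle` console script:

```sh
tmtcycle simulate --seed 1 --out sim/
tmtcycle normalize --abundance sim/abundance_raw.tsv --design sim/design.tsv --out norm/
tmtcycle diff --abundance norm/abundance_normalized.tsv --design norm/design_used.tsv \
    --contrast WT_AL:KO_AL --contrast RE_AL:KO_AL --contrast WT_AL:RE_AL --out contrasts.tsv
tmtcycle classify --contrasts contrasts.tsv --out labels.tsv
tmtcycle rhythm --expression sim/expression.tsv --out fits.tsv
tmtcycle concord --labels labels.tsv --fits fits.tsv --id-map map.tsv --out records.tsv
tmtcycle enrich --query query.txt --gmt sets.gmt --universe universe.txt --out ora.tsv
tmtcycle run-all --config config.yaml --seed 1 --out results/
```

`run-all` executes every configured stage and writes per-stage TSVs plus a
single `summary.json` recording counts, thresholds, the seed and the
package version. A YAML config can either point at input files
(`inputs: {abundance, design, expression, id_map, secreted}`) or carry a
`simulate:` block of generator parameters.

## Data formats

TSV throughout (UTF-8, `.` decimal, 12 significant digits — lossless
write/read round-trips at that precision), GMT for gene sets, plain id
lists for annotations, JSON for summaries.
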