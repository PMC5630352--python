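# bivtrans

Bivalent-chromatin transition analysis: classify promoters into
bivalency transition groups (I–IV) from dual histone-mark peak calls
(H3K4me3 / H3K27me3) in two conditions, and run the downstream
statistics on real or synthetic inputs.

## What it does

* **annotation_io** — BED peak and GTF/BED gene annotation reading on a
  unified 0-based half-open coordinate convention; strand-aware
  promoter windows (default TSS ± 2 kb, configurable).
* **state_classifier** — binary mark-presence calls (≥ 1 bp overlap),
  per-condition chromatin states, and the Group I–IV transition
  partition of genes bivalent in the second condition (I: K4-premarked
  gaining K27; II: K27-premarked gaining K4; III: unmarked acquiring
  both; IV: constitutively bivalent).
* **signature_overlap** — Fisher's exact test (two-sided,
  minimum-likelihood rule) and odds ratios (Haldane–Anscombe corrected
  on zero cells) for group-vs-signature 2×2 overlap tables.
* **enrichment** — term enrichment from GMT files in two-list
  hypergeometric mode and ranked minimum-hypergeometric (mHG) mode
  with the exact lattice-path dynamic-programming p-value.
* **expression_analysis** — strict FPKM filter (> threshold), per-group
  fraction of lower-expressed genes, mean/SEM expression differences
  with Mann–Whitney comparisons (exact enumeration for small tie-free
  samples), per-sample cumulative gene-set scores, Welch's t-test, and
  TN / Non-TN receptor-status labeling.
* **wetlab_quant** — 2^−ΔΔCt fold changes, Holm–Šidák step-down
  adjustment, the three-criterion reactivation call, percent-input
  ChIP quantification, and H3-normalized enrichment with IgG
  background subtraction.
* **synthetic_data** — download-free datasets with planted ground
  truth for every stage (peaks exactly realizing planted states,
  planted Group I repression, planted cohort gene-set depression,
  planted qPCR fold changes); all generators are deterministic in the
  seed.
* **cli / config** — YAML-configured subcommands with aggregated
  validation and reproducible, provenance-stamped reports.

## CLI

```sh
# generate a planted synthetic dataset
bivtrans simulate --n-genes 2000 --seed 1 --outdir data/

# run individual stages from a YAML config
bivtrans classify  -c config.yaml --outdir results/
bivtrans overlap   -c config.yaml --outdir results/
bivtrans enrich    -c config.yaml --group I --outdir results/
bivtrans expression -c config.yaml --outdir results/
bivtrans cohort    -c config.yaml --outdir results/
bivtrans qpcr      -c config.yaml --outdir results/

# or everything the config provides inputs for
bivtrans run-all -c config.yaml --outdir results/
```

A config file names the four peak BEDs (`"<mark>:<condition>"` keys
under `peaks`), the gene annotation, expression/cohort/Ct tables, the
promoter window, thresholds and the A/B condition labels; see
`bivtrans.config.RunConfig` for all keys. `bivtrans simulate` writes a
dataset in exactly the formats the other subcommands consume.

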