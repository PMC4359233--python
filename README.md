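# polpoised

Pipeline for identifying genes *poised* for transcription — promoter-bound
by RNA polymerase II in high-marker cell lines yet not consistently
regulated there — and classifying which of them become differentially
expressed in marker-stratified tumor cohorts.

Stages:

1. **simulate** — synthetic promoter tiling arrays (probes ~200 nt apart
   over −5000..+2500 around each TSS), replicated two-group cell-line
   expression, and several independently scaled tumor cohorts, with a
   planted ground truth (bound / regulated / poised / tissue-dependent /
   stalled genes).
2. **binding** — probe-triple neighborhood caller (composite Stouffer
   p-value of each adjacent triple within 1100 nt, dual neighbor-threshold
   admission rule), gene-level combination via Fisher's method (χ², 2n df)
   and the geometric-average transform (χ², 2 df), tight/loose/unbound
   classification, and a stalling index (peak proximal over mean distal
   enrichment).
3. **expression** — quantile normalization, empirical-Bayes moderated t
   with method-of-moments prior estimation, per-gene standardization,
   cohort merging on the common gene set, top/bottom-quantile sample
   stratification by a marker gene, and the 2^(−ΔΔCt) qPCR fold change.
4. **concordance** — 2×2 direction tables, Cohen's kappa with null and
   alternative standard errors, a random-gene permutation null, and a
   gene-list overlap resampling test.
5. **regulon** — the set-algebra cascade: regulon → regulated →
   concordant → poised → tissue-context-dependent (up/down partitioned).

## CLI

```sh
polpoised simulate --outdir out/ --seed 1
polpoised callbind --probes out/probes_MCF7HER2.tsv --out out/binding.tsv
polpoised de --matrix matrix.tsv --group-pos BT474 --group-neg MCF7 --out de.tsv
polpoised concord --de-a de_line.tsv --de-b de_tumor.tsv --out kappa.json
polpoised overlap --list-a a.txt --universe-a ua.txt --list-b b.txt \
    --universe-b ub.txt --rounds 10000 --seed 1 --out overlap.json
polpoised run --config config.yaml --outdir out/       # full pipeline
```

`run` simulates data, calls binding per line, performs the cell-line and
merged-tumor differential expression, computes per-comparison kappa
statistics, applies the classification cascade, and writes TSV/JSON
artifacts plus a `manifest.json` recording seeds, the config hash, class
sizes and planted-truth recovery metrics. Identical configs produce
byte-identical artifacts.

Configuration is a YAML/JSON file with `sim`, `binding`, `de` sections
mirroring `SimConfig`, `BindingConfig` and `DEConfig` fields.

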