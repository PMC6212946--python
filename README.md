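# endoref

Tools for choosing and validating endogenous normalizer (reference) miRNAs
for RT-qPCR expression profiling:

- **Stability estimators** — four per-gene expression-stability scores
  (model-based residual variation, pairwise-variation M with stepwise
  exclusion, raw-Cq descriptive statistics against a composite index, and
  the comparative delta-Ct method) plus a comprehensive
  geometric-mean-of-ranks aggregate and top-k overlap (Venn) counts.
- **Iterative selection** — a greedy forward search that averages the
  current reference set with each remaining candidate, rescores the
  combined pseudo-gene, and records the per-iteration minimum and mean
  scores so the number of references to use can be read off the trace.
- **qPCR quantification** — standard-curve fitting with amplification
  efficiency `E(%) = (10^(-1/slope) - 1) * 100`, multi-reference
  delta-delta-Cq fold changes with t-tests, and per-gene one-way ANOVA
  across sample groups with Benjamini–Hochberg correction.
- **Sequence similarity** — pairwise Needleman–Wunsch global alignment of
  mature miRNA sequences, seed (positions 2–7) identity, and expression
  correlation, for flagging cross-hybridization risk.
- **Synthetic data** — seeded generators for replicate-level Cq tables
  with planted stable genes, negative-binomial count matrices, and
  dilution series of known true efficiency, each with a ground-truth
  manifest.

## CLI

All subcommands write TSV output plus a JSON run manifest (`<out>.run.json`).

```sh
# simulate a Cq dataset with 3 planted stable genes, then rank candidates
endoref simulate cq --n-groups 2 --group-sizes 10,10 --seed 7 --out sim/
endoref stability --cq sim/cq.tsv --top-k 5 --out stability.tsv

# greedy selection of reference sets from a count matrix
endoref simulate counts --n-samples 20 --n-genes 40 --n-stable 5 --seed 7 --out simc/
endoref select-iterative --counts simc/counts.tsv --max-k 10 --out trace.tsv

# standard-curve efficiency
endoref simulate dilution --efficiency 95 --seed 7 --out dil/
endoref efficiency --series dil/dilution.tsv --out curves.tsv

# delta-delta-Cq quantification against a 3-gene reference
endoref quantify --cq sim/cq.tsv --targets noisy_01 \
    --refs stable_01,stable_02,stable_03 --calibrator-group grp1 --out rq.tsv

# pairwise sequence similarity
endoref similarity --fasta mature.fa --out sim.tsv
```

Exit codes: 0 success, 1 validation/data error, 2 usage error.

## Layout

```
src/endoref/
  io_core.py     data model, readers, replicate collapsing, CPM filter/log2
  stability.py   four stability estimators + comprehensive rank + overlap
  selection.py   greedy iterative reference-set construction
  qpcr.py        standard curves, delta-delta-Cq, group uniformity ANOVA
  similarity.py  global alignment, seed identity, expression correlation
  simulate.py    seeded synthetic Cq / count / dilution generators
  cli.py         `endoref` command group
```
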