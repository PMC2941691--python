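# microtc

Cross-experiment microarray integration through **treatment-over-control
(T/C) ratio statistics**: standardize heterogeneous expression
experiments into comparable contrasts, compute per-gene log-ratio
statistics with significance, relate genes and conditions through a
Dice-overlap/correlation relation index, and emit searchable,
renderable Gene-View / T/C-View / Slide-View artifacts from a flat-file
offline pipeline.

It is written for computational biologists and curators who want to ask
gene-centric questions across many public microarray experiments — "under
which conditions does PR-1 go up?", "which conditions share this
expression signature?" — without a database or web stack.

## The model

Raw intensities from different laboratories are not comparable; ratios
of well-chosen contrasts are. A **sample set** groups the replicate
chips of one factor-level combination; a **T/C** pairs a treatment
sample set against a control sample set whose factor profile differs in
*exactly one factor*, the control side holding that factor's declared
control level. Enumerating all such pairs turns any factorial design
into a homogeneous list of contrasts (a 2-genotype × 4-cold-duration
experiment yields exactly 10 T/Cs).

Per feature and T/C, on log2 scale:

    M = LOG2R = mean(treatment) − mean(control)      fold = 2^M
    A = (mean(treatment) + mean(control)) / 2
    P = two-sample two-tailed t-test over replicates (Welch default)

Regulation sets use the double cutoff **|fold| ≥ 2 and P < 0.05**. Two
genes (or two T/Cs) are related through their regulation sets A and B:

    OP = 100 · 2|A∩B| / (|A|+|B|)        (Sørensen–Dice, percent)
    CC = Pearson correlation of the two LOG2R vectors over A∩B
    RI = (OP/100) · CC²                  (relation index, in [0,1])

ranking co-responsive genes and co-regulation T/Cs; squaring CC makes
strong negative relations rank as highly as positive ones.

Supporting stages: quantile normalization and median-polish probe-set
summarization, mean-%CV replicate QC (default flag threshold 4.68),
probe-set→transcript annotation by exact 25-mer matching (≥9 of 11
probes), a bespoke tf·idf inverted index for full-text search, MA-plot
rendering as 480×480 rasters with machine-readable point overlays, and a
seeded synthetic-experiment generator with ground-truth tables.

## Worked example

`examples/coregulation_reference_table.py` recomputes a published
co-regulation table for the "16 hr Pseudomonas infection" condition from
its raw counts (packaged in `microtc/data/`):

```
derived reference regulated-gene count N = 381

T/C                                                   OP        CC        RI
24 hr Pseudomonas infection                           64   0.98292  0.623816
Leaf, WT, Golovinomyces orontii infection for 5 d vs  43   0.93683  0.385622
BTH Effect for 8 hr in wrky18 mutant                  36   0.94364  0.324200
...
Leaf, eds16, Golovinomyces orontii infection for 5 d  38  -0.82538  0.262858
high nitrogen effects                                 17  -0.89249  0.135868

max |recomputed RI - printed RI| over 78 rows: 2.44e-06
```

The reference condition's own regulated-gene count N is not printed in
the source table; inverting the top row's equation RI = (2C/(N+B))·CC²
recovers N = 381, after which every row's relation index is reproduced
from bare counts to ~1e-5 — including the negatively correlated *eds16*
rows whose positive RI comes from the squared correlation. The closest
co-regulated condition is the same infection 8 hours later, as a
biologist would expect.

The other examples each exercise one capability end to end:
`enumerate_tcs_and_stats.py` (T/C enumeration + ratio statistics on
synthetic ground truth), `ma_plot_two_layer.py` (raster + overlay
rendering), `full_text_search.py` (inverted index, OR queries,
hyphen-compound tokens), `offline_pipeline.py` (pipeline store and the
three views).

A thin CLI mirrors the pipeline: `microtc run|synth|normalize|tc|
annotate|index|view|plot` (see `microtc --help`).

## Layout

- `src/microtc/` — the library (`matrix`, `design`, `soft`, `annotation`,
  `preprocess`, `tc`, `relations`, `search`, `plots`, `synth`, `store`,
  `cli`, `reference_tables`).
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
- `examples/` — one short narrative script per capability.
- `tests/` — pytest suite with brute-force oracles and property tests.
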