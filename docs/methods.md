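# Methods

## The treatment-over-control model

Cross-experiment integration of microarray data fails on raw intensities:
every laboratory's design, tissue, platform run and control condition
differ. `microtc` standardizes experiments into **T/C pairs**: a
*treatment* sample set (replicate chips sharing one factor-level
combination) contrasted against a *control* sample set whose profile
differs in **exactly one factor**, with the control side holding that
factor's declared control level. Given sample sets with factor profiles,
all such pairs are enumerated; a treatment level is only contrasted
against its factor's control level, never against another non-control
level — the canonical 2-genotype × 4-cold-duration factorial (8 sample
sets) therefore yields exactly 10 T/Cs (3 + 3 cold contrasts per
genotype, 3 + 1 genotype contrasts per duration). Level-vs-level
contrasts ("32 hr vs 9 hr infection") are supported only as explicit
declarations in the design file.

Per feature *g* and T/C, with mean log2 intensities
$\bar t_g$ (treatment) and $\bar c_g$ (control):

- $M = \mathrm{LOG2R} = \bar t_g - \bar c_g$, fold change $2^M$;
- $A = (\bar t_g + \bar c_g)/2$ — the MA-plot x-axis;
- a two-sample two-tailed t-test over the replicate log2 intensities.

The t-test is **Welch** by default (unequal variances; Welch–Satterthwaite
degrees of freedom), with a pooled-variance option, because replicate
variances of independently produced chip groups have no reason to be
equal. Degenerate inputs are resolved deterministically: both groups with
zero variance give (t=0, P=1) when means are equal, and P=0 with a
`degenerate` flag when not. No multiple-testing correction is applied;
the downstream selection rule is defined on raw P values with fixed
thresholds, and changing that would change the meaning of every published
cutoff this toolkit mirrors.

## Normalization and summarization

Within one experiment chips are made comparable by **quantile
normalization** (each column mapped onto the across-chip mean of order
statistics, ties receiving the mean of the tied quantile means), and
probe-level input is summarized to probe sets by **Tukey median polish**,
reporting overall + chip effects — the normalization and summarization
components of RMA-style preprocessing. The RMA convolution background
correction is deliberately not implemented: the toolkit's contract is
"normalized log2 matrix in", and the two included stages make that
contract self-sufficient for both probe-set-level and probe-level input.
Between-experiment normalization is intentionally absent — experiments
are only ever compared through ratios, which is the point of the T/C
model.

Median polish runs at most `max_iter` = 10 sweeps or until row and column
medians of the residuals drop below `tol` = 1e-6; single-probe sets pass
through unchanged with a warning.

## Replicate quality: mean %CV

Per sample set, each feature's percentage coefficient of variation is
$100\cdot s/\bar x$ (sample SD, n−1), averaged over features into one
scalar. The default QC threshold is **4.68**: in the published
301-experiment compendium most sample sets fall between 0.5 and 4.68
while a poor-quality tail stretches to ~16, so the upper edge of the bulk
is the natural flag line. Some sources print the reciprocal formula
(mean/SD); that reading is inconsistent with the reported 0.5–16 range
and is treated as an erratum, but remains available as
`cv_definition="mean_over_sd"`. Whether %CV is taken on log2 or linear
intensities is a config switch (`cv_scale`, default log2, matching the
canonical scale of the normalized matrix).

## Regulation sets and the relation index

Within the genes × T/Cs ratio compendium, an entity's **regulation set**
is chosen by the double cutoff |fold| ≥ 2 **and** P < 0.05 (both bounds
as stated: the fold bound inclusive, the P bound strict), split into up-
and down-regulated members. Relations between two genes (co-responsive)
or two T/Cs (co-regulation) are scored by:

- **OP** — Sørensen–Dice overlap percentage
  $100\cdot 2|A\cap B|/(|A|+|B|)$ of the two *sign-blind* regulation sets
  (union of up and down). Sign-blind overlap is required so that
  anti-correlated partners (mutant vs wild-type infections, for example)
  are admitted at all.
- **CC** — Pearson correlation of the two LOG2R vectors over the
  *overlapped items only*.
- **RI** — the relation index $(\mathrm{OP}/100)\cdot \mathrm{CC}^2 \in [0,1]$.

The square in RI is deliberate: published tables show negative-CC rows
with positive RI equal to OP·CC², so a strong negative correlation ranks
as highly as a strong positive one. `cc_exponent=1` preserves the
unsquared alternative. Displayed OP is floored to an integer, as in the
published tables; stored OP keeps full precision. Relations with fewer
than `min_overlap` = 3 overlapped items are skipped (Pearson correlation
on <3 points is unstable); this floor is a package choice, configurable.

The packaged co-regulation reference table omits the reference T/C's own
regulated-gene count; it is recovered by inverting the top row's
equation, $\mathrm{RI} = \frac{2C}{N+B}\mathrm{CC}^2 \Rightarrow N =
2\cdot277\cdot0.982917^2/0.623816 - 477 = 381.0$, and N = 381 is treated
as a derived fixture constant. With it, all 78 table rows reproduce the
printed RI within 1e-4 and the printed floored OP exactly — the evidence
that Dice is the right denominator and the square the right exponent.

Ranking is by RI descending, ties by CC² descending then candidate ID,
making output deterministic.

## Full-text search

A bespoke inverted index covers gene identifiers/symbols/annotations,
T/C names/descriptions and experiment titles/descriptions. Tokens are
lowercase alphanumeric runs; compound words additionally contribute their
joined form (`PR-1` → `pr`, `1`, `pr1`) so gene-symbol spellings with and
without hyphens meet. Queries OR their terms ("any matching word") and
rank by summed tf·idf with idf = ln((N+1)/(df+1)) + 1 — a scoring choice
of this package, since only matching semantics are contractual. No
stemming or stop words (exact-token recall is the contract); a slow
substring mode covers partial-word matching.

## Display artifacts

Every MA plot is emitted as a **2-layer artifact**: a static raster
(default 480 × 480 px, PNG by default with lossless pixels; JPEG
available) and a JSON-lines overlay recording each point's item ID, data
coordinates, pixel coordinates (origin top-left), P-value color class and
highlight state. Color classes: blue for P < 0.01, green for
0.01 ≤ P ≤ 0.05, yellow for P > 0.05 — both boundary values are assigned
to green, a documented resolution of the open interval wording.
Highlight windows are inclusive rectangles in data coordinates with
optional open edges. Slide decks fix one axis range across all slides
(global data extent) so a highlighted item's movement between slides is
positionally meaningful; the highlight set is selected by a window on the
first slide and persists, with items missing from a later slide marked
`missing` in that slide's overlay rather than dropped. Axis ranges
default to the data extent padded 5%.

## Synthetic experiments

The generator emulates a replicated factorial experiment *after*
RMA-style preprocessing: per-feature baseline ~ N(8, 1.5²) log2 units,
additive condition-specific shifts (spikes) on selected features, and
i.i.d. Gaussian replicate noise with σ = 0.25 log2 units, 3 replicates
per sample set — values a practitioner would call a clean modern
Affymetrix experiment. It does **not** emulate intensity-dependent
variance, probe-level effects, heavy-tailed outliers, batch structure or
array spatial artifacts; tests passing on this generator therefore
demonstrate correctness of the statistics and plumbing, not robustness to
real-array pathology. Ground truth (true LOG2R per spiked feature and
T/C) is written beside each fixture so checks never re-derive truth from
the pipeline under test. All randomness flows from one seed;
equal-seed runs are byte-identical.

`spike_relations` copies one gene's spike pattern onto a partner (scaled,
optionally sign-flipped), constructing a ground-truth co-responsive pair:
the partner's regulation set coincides with the source's and their
LOG2Rs correlate with the requested sign.

## Pipeline and store

The offline pipeline (ingest → annotate → normalize → T/C stats →
relations → index → plots) writes a flat-file store of TSV/JSON/YAML
artifacts. Each stage records a manifest of its config hash and input
checksums; re-runs skip unchanged stages. The store is deterministic:
identical config and inputs give byte-identical artifacts (manifests
carry no timestamps).

## Problem sizes and scope

The test suite and the reproduction script run on deliberately small
problems: factorials of 8 sample sets × 3 replicates, 20–400 features,
ratio compendia of 20 genes × 15 T/Cs — sizes at which every statistic
can be cross-checked against brute-force oracles. Corpus-scale results
from the published 301-experiment compendium (1,450 T/Cs × 22,810 probe
sets) are **out of reach by construction**, not re-downloaded: absolute
fold changes and P values of individual published rows, the "199
co-regulation T/Cs" count for the 16 hr Pseudomonas infection T/C, the
composition counts of the PR-1 list, and the compendium-wide %CV
distribution all depend on that corpus. What the toolkit reproduces
instead is everything derivable from printed numbers (the 95-row double
cutoff, the co-regulation table's OP/RI arithmetic, the 10-T/C
enumeration, the 30-fold ↔ LOG2R 4.9 threshold) plus the full property
battery on synthetic ground truth.

## Probe-set annotation

Probe sets map to transcripts when ≥ `min_probes` (default 9 of 11)
probes occur verbatim in the transcript sequence; for 25-mers at 100%
identity and length, exact substring matching is equivalent to a
100%-identity BLAST hit and needs no aligner. Both strands are scanned by
default (`strand="both"`) since probe/cDNA strand conventions vary;
multi-transcript hits are all retained and flagged `multi_mapped`, with
the transferred annotation taken from the best-matching transcript —
downstream views can filter, which is safer than silently dropping
ambiguous sets.

## Known limitations

- No missing-value support: chips must be complete (hard error).
- No between-experiment normalization; comparability rests on ratios.
- The inverted index holds postings in memory; it is a desk-scale tool.
- Quantile normalization's tie handling can differ from other
  implementations in the last decimal for heavily tied integer data.
- The generator's Gaussian noise understates real-array tails; QC
  thresholds validated only against it should not be ported to real data
  unexamined.
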