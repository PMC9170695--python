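# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions used throughout.

## Coordinate and file conventions

All coordinates are 0-based half-open (BED convention); TSS inputs are
declared 0-based. Chromosome sizes come from a two-column TSV so nothing
requires a sequence parse. bedGraph aggregation into bins is a per-base
sum (each bin holds Σ value × overlapping bases), not a mean: the sum over
bins then equals the read mass of the file, which is what the Poisson
binarization downstream assumes. The generator writes binned count tracks
with value = count / bin_size so this rule recovers integer counts exactly
(the binarizer rounds with `rint` on read).

## Chromatin-state model

Two marks, H3K4me3 (activating) and H3K27me3 (repressive), are binned at
200 bp. Binarization uses a global background: per mark, λ̂ is the
genome-wide mean bin count and a bin is called present iff
P(X ≥ count | λ̂) < α with α = 1e-4. The global-mean background is the
standard default for this task; it behaves well when marked regions are a
small fraction of the genome (true for real genomes, and enforced in the
generator's geometry — see below).

Segmentation is a hidden Markov model with K = 4 states and independent
Bernoulli emissions per mark. Training is Baum–Welch with scaled
forward/backward recursions (no underflow on chromosome-length
sequences), 5 random restarts with emissions initialized uniformly in
[0.2, 0.8] (random restarts avoid degenerate symmetric starts; transition
matrices start diagonally dominant), an absolute log-likelihood gain
tolerance of 1e-4 and a 200-iteration cap. Row-stochasticity of the
transition matrix and start vector is asserted at every update, and a
decreasing log-likelihood raises rather than warns — EM monotonicity is a
correctness invariant here, not a diagnostic. Decoding is Viterbi: a
single deterministic labeling simplifies the downstream set logic;
posteriors remain available via `predict_proba`. The model is fit on the
first stage and applied to all stages (a per-stage refit is available
behind `refit_per_stage`); fitting on the starting population and decoding
the rest keeps state identities comparable across stages.

States are labeled semantically from the emission matrix at a 0.5
threshold: both marks on → bivalent, only H3K4me3 → H3K4me3_only, only
H3K27me3 → H3K27me3_only, neither → unmarked. If two states map to the
same label a warning is recorded and both are kept; the fitted model is
not forced into the 4-label alphabet.

## Bivalent-promoter calls and transitions

The promoter is TSS ± 2.5 kb, clamped at chromosome ends; the definition
is symmetric so strand never matters, and one TSS per gene is assumed. A
gene is bivalent when the summed overlap of its promoter with bivalent
segments strictly exceeds 200 bp; overlaps are aggregated across segments
before the test because binning can fragment one domain. Non-bivalent
promoters take the label with the largest promoter overlap, ties broken
H3K4me3_only > H3K27me3_only > unmarked — a deterministic,
order-independent rule for a case the bivalency threshold does not cover.

A promoter bivalent at stage A has exactly four fates in the 4-label
alphabet, which define the transition modes: stable_bivalent, activated,
repressed, resolved_unmarked. Ratios are counts over the number of
bivalent promoters at A; with none, ratios are reported as 0 with a
degenerate flag. Gains of bivalency (non-bivalent → bivalent) are not one
of the four modes — the analysis tracks existing bivalent domains — and
can be recovered from the per-stage calls if needed.

The promoter correlation matrix uses log2(expression + 1) and
log2(promoter-window summed signal + 1) per assay; sum-then-log was fixed
as the promoter statistic (mean-vs-sum only rescales within an assay and
Pearson r is scale-invariant, so the choice is presentational).
Zero-variance features produce missing correlations, not errors.

## Accessibility matrix and temporal clustering

Consensus peaks are the union of per-stage peak calls merged transitively
within 100 bp. Counts per peak are per-base sums of the cut-count track;
the library size is the total mass of the stage's track (conventional
RPKM, configurable). The transform chain is: presence filter (RPKM
strictly > 5 in ≥ 2 stages), quantile normalization, CV filter (keep rows
with population-sd/mean ≥ 0.10; the boundary is kept), quantile
normalization again, row z-scores with population sd. The double quantile
normalization is deliberate and matches the stated processing order;
`--single-qnorm` gives the simpler variant. Quantile normalization maps
each column's sorted values to the across-column mean of sorted values;
ties receive the mean of their target values. It is exactly idempotent on
tie-free data; with ties the tie-averaging perturbs the pooled
distribution slightly, so idempotence is only approximate there.

Fuzzy c-means uses c = 6 and fuzzifier m = 1.25. On z-scored rows m = 2
over-fuzzifies (memberships collapse toward uniform); 1.25 keeps soft
boundaries while preserving contrast. Ten random restarts are run and the
lowest final objective wins; collapsed or duplicate centroids are
re-seeded with a warning. Hard assignments are argmax memberships with
ties to the lowest cluster index.

Categories are assigned per cluster by the mean centroid value over the
three consecutive stage pairs (1+2, 2+3, 3+4); the argmax pair gives
category I/II/III, ties to the earlier category. This is an
operationalization of a grouping that is manual in practice; it is only
defined for 4-stage series. Note that because the matrix is
quantile-normalized before z-scoring, the rule effectively compares
within-stage ranks, not raw signal levels.

## Motifs, enrichment, candidates, footprints

PWMs come from position count matrices with pseudocount 1 and a uniform
background; scores are log2 odds. Scanning reports windows on either
strand with score ≥ 0.8 × the maximum achievable score (no scanning
threshold is canonical; 0.8 of max is strict enough that weak spurious
matches are rare at the motif information contents used here). N bases
contribute 0 (background). Minus-strand hits are scored on the reverse
complement and reported at the forward coordinate of the window start.

Enrichment counts peaks *containing* at least one occurrence (binary per
peak, matching the proportion-of-sequences convention), forms the 2×2
table against a background of all consensus peaks not in the foreground
category (self-contained at desk scale; the GC-matched genome-wide
backgrounds of dedicated motif tools are a documented deviation), and
computes the one-sided Fisher exact p — implemented as the hypergeometric
upper tail — with BH correction across the TFs of one call. Candidate
regulators are TFs passing q ≤ 0.05 in categories II ∪ III intersected
with the activated bivalent gene set, ordered by best q then name.

Footprint profiles average per-base cut counts over motif sites aligned
on the motif (minus-strand windows reversed). Depth is
1 − mean(core)/mean(flank) with the flank taken as the outermost
radius/2 positions per side: a flat profile scores 0, a core at half the
flank level scores 0.5. Sites whose window leaves the chromosome are
skipped and counted.

## Knockout classification

With pseudocount 0.5 (stabilizes fold changes at low counts),
r = (wt + 0.5)/(ko + 0.5); r ≥ 2 → dependent, 1/r ≥ 2 → independent,
else unchanged. The gained ("independent") side uses the same symmetric
two-fold rule — the threshold for gains is not separately canonical, so
symmetry is the least arbitrary choice. Percentages are rounded half-up
to one decimal next to the exact ratios (34.07…% prints as 34.1%).

## The synthetic genome

The generator is the package's test bed: a uniform-random genome with
gene slots of 25 kb (TSS at slot centers, so promoter windows never
overlap each other or the intergenic peaks) across 4 × 13.5 Mb
chromosomes, 2000 genes and 900 intergenic 500-bp peaks by default.

- **Chromatin states.** Initial promoter states are drawn as bivalent
  0.30, H3K4me3_only 0.15, H3K27me3_only 0.10, unmarked 0.45; at each
  stage step a currently-bivalent promoter draws a transition mode with
  proportions activated 0.20, stable 0.70, repressed 0.05, resolved 0.05.
  The 20% activated share is the planted quantity the transition analysis
  recovers. A handful of named regulator genes (POU5F1, CTCF, SOX17,
  JUNB, GATA2, RUNX1) follow fixed programs so the candidate-intersection
  logic has exact truth: SOX17/JUNB activate at VME→EPC, GATA2/RUNX1 at
  EPC→HPC, CTCF stays bivalent, POU5F1 stays active.
- **ChIP tracks.** Per-bin Poisson counts: λ_hi = 20 inside promoter
  windows whose state carries the mark, λ_lo = 2 elsewhere. The 10×
  ratio is the planted contrast; the absolute rates were chosen so the
  global-mean binarization threshold sits between the two rates with
  high per-bin detection probability, and the 25-kb gene spacing keeps
  marked bins a small fraction of the genome so λ̂ stays near λ_lo.
- **Accessibility.** Six temporal archetypes (two per category) drive
  per-peak expected cut counts (fully open ≈ 300 cuts per 500-bp peak);
  a peak enters a stage's peak call iff its expected count exceeds 100.
  Archetype shapes are designed in rank space — within each stage the
  intended category ordering holds at the rank level — because the
  pipeline's category rule operates after quantile normalization.
  Motifs are synthetic 10-bp PWMs derived deterministically from the TF
  name (one dominant base per column); each category-assigned TF is
  planted (as its consensus, either strand) into 80% of that category's
  peaks, away from peak edges. Cut rates dip by a factor 0.5 over the
  motif core at stages where the peak is open, giving a known footprint
  depth of 0.5.
- **Expression.** Negative binomial per gene and stage with
  state-dependent means (H3K4me3_only 200, bivalent 20, H3K27me3_only
  and unmarked 10; dispersion 10). This gives the qualitative signs the
  promoter correlation checks (positive with H3K4me3, negative with
  H3K27me3); `nb_dispersion = inf` is the Poisson limit.
- **Knockout.** 34.1% of peaks are dependent (KO mean = WT/4), 13.2%
  independent (×4), the rest unchanged, with Poisson counts around a WT
  mean of 100; a KO-only motif (ERG) is planted into 40% of dependent
  and 5% of independent peaks for the differential-enrichment check. The
  4-fold planted effect against the 2-fold calling threshold keeps
  Poisson noise from blurring the planted labels.

All randomness flows from one root seed through fixed-offset child
streams, so the full output is a pure function of the configuration and
regenerating one layer never reshuffles another.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: overlapping promoters and multi-TSS genes,
GC/mappability bias and read-level artifacts, fragment-length and Tn5
insertion-sequence effects, peaks overlapping promoters, enhancer–gene
distance structure (nearest-gene coupling of expression to peak dynamics
is not planted), replicate structure, and chromatin states at sub-bin
resolution. Recovery results certify the pipeline's internal
correctness, not its robustness to those real-data complications.

## Problem sizes and determinism

The bundled analyses run at desk scale: 2000 genes / 54 Mb / 900 peaks
for the full recovery study, 10,000 peaks for the knockout recovery, and
smaller geometries in unit tests. Pipeline runs are deterministic given
(config, seed): reports are byte-identical across repeat runs, with file
paths stored relative to the output directory.

## Known limitations

- One TSS per gene; transcript-level promoter handling is out of scope.
- Each stage is decoded with the stage-one model by default; if marks
  redistribute so strongly that emission identities change, use
  `refit_per_stage` and re-check label consistency.
- The peaks-as-background enrichment choice makes q-values relative to
  the consensus set, not the genome.
- `bedgraph_coverage` assumes records do not span more than two target
  intervals, which holds for the binned and per-base tracks produced
  here but not for arbitrary bedGraphs with very long records.
- Category assignment is fixed to 4-stage designs.
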