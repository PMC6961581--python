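# Methods

This note documents the models and procedures implemented in `bagseq`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Read structure and demultiplexing

Each protocol defines a positional layout over its identifying read
(1-based inclusive coordinates, the bench convention; all genomic intervals
elsewhere are 0-based half-open and converted only at this boundary):

| protocol | anchor(s) | barcode slices | tag slices | composite length |
|---|---|---|---|---|
| DNA (read 2) | `CATG` @ 31–34, ≤ 1 mismatch | 1–6, 22–26 | 27–30 | 11 |
| RNA 2-split A | primer `AGTGGAAAAGGAAGGTGGT` @ 7–25, ≤ 2 mm; `GGG` @ 38–40 exact | 1–6, 26–31 | 32–37, 43–48 | 12 |
| RNA 2-split B | `GGG` @ 38–40, ≤ 1 mm | 1–6, 26–31 (whitelisted) | 32–37, 43–48 | 12 |
| RNA 3-split | `GGG` @ 67–69, ≤ 1 mm | 1–6, 30–35, 55–60 (whitelisted) | 61–66, 72–77 | 18 |

Whitelist matching is exact by default; a 1-mismatch rescue (accept iff a
unique whitelist entry is within Hamming distance 1) exists but is off, as
the protocol defines validity by exact membership. DNA positions 7–21 are
a constant linker and are not validated — the protocol specifies nothing to
check there. Adapter trimming uses suffix-overlap matching (minimum
overlap 5, ≤ 10 % mismatches); pairs are kept only when both mates remain
≥ 100 bases. A proper pair maps to one chromosome within 2 kb, convergent,
with the read-2 restriction site present.

## Cell calling

Cells are the barcodes left of the inflection of the barcode-rank curve.
The knee is the point of maximum perpendicular distance between the curve
of (rank fraction, cumulative count fraction) and its end-to-end chord,
with ties at the knee included. A knee requires distance
≥ 0.02 (normalized units, default `min_knee_distance`): below it — equal
or near-equal depths — the caller reports "no knee" and selects nothing
rather than guessing. Consequence: an input consisting *only* of cells at
similar depth is also knee-free; detection needs the background to bend
against. A manual count threshold can override detection.

## Templates

The collapsing key is (BAG barcode, varietal tag, map position, strand),
with map position the 5′-most aligned base and tags compared as exact
strings. Strand is part of the key because NlaIII capture is
strand-marked (the cut site fixes the template 3′ end); the alternative
(strandless keys) would merge opposite-strand captures of one site.
Genome coverage is computed over aligned read footprints, not inferred
fragments. Downsampling samples reads without replacement from a single
shuffled order per seed, so realized curves are monotone, not only in
expectation.

## Copy number

**Bins.** Bin boundaries are empirical quantiles of the pooled *distinct*
capture positions of the admitted cells, so each bin holds an equal number
of capturable sites — the uniform-expectation construction under constant
copy number. Counting each distinct site once (rather than read
multiplicities) makes the scheme insensitive to the pooled sample's own
copy-number states once sites are saturated, and gives the exact ±1
self-consistency property. Bins are allocated to chromosomes by largest
remainder; because whole bins cannot cross a chromosome end, the ±1
equal-count guarantee is exact within each chromosome and approximate
across them. Admission requires ≥ 100 000 unique tags per BAG (desk
presets lower this in proportion to their genome size).

**Normalization.** `r_i = (c_i + 1)/mean(c + 1)`, then lowess of `log r`
on per-bin GC (span `f = 0.05`), residuals exponentiated and rescaled to
mean exactly 1. Two guards keep the local regression well-conditioned:
correction is skipped when the GC span is < 0.02 (nothing to fit; a
robustified fit over a spread-free predictor chases copy-number structure
instead), and the span is floored so each local fit covers ≥ 30 bins — at
the intended bin counts (5 000–20 000) `f = 0.05` is a 250+-bin window and
the floor never binds. The linear-ratio reading (rather than a literal
log-ratio vector) is required for the normalized vector to have mean one
and for the integer-grid ploidy step to operate on linear scale.

**Segmentation.** CBS reimplemented: for each segment, the maximal
mean-shift statistic over circular arcs (linear arcs suffice — an arc and
its wrap-around complement score identically), with arc enumeration
restricted so every resulting linear segment has ≥ `min_width` bins. A
within-segment permutation test (exact, early-stopped once rejection is
certain) accepts the split at `alpha = 0.02` with `nperm = 1000`;
accepted splits recurse. Afterwards, sdundo-style pruning removes the
weakest breakpoint while adjacent segment means differ by less than
`undo.SD = 0.5` × residual SD. All randomness flows from one seeded
generator; results are deterministic per seed.

**Ploidy.** The multiplier grid 1.5 : 0.05 : 4.5 is searched for the
minimum of `Σ w_s (m·s − round(m·s))²` with bin-length weights; rounding
is half away from zero and SSE ties break toward the smallest multiplier
(biasing ambiguous cases toward lower ploidy). Two intrinsic
identifiability limits: a constant profile is fit perfectly by every
integer multiplier (the tie-break returns 2), and doubling any
integer-state solution is again a solution, so profiles with mean copy
number < 2.25 are ambiguous with their doubled reading — noise resolves
this in favor of the smaller multiplier (the doubled fit amplifies segment
noise fourfold) when the true multiplier lies on the grid.

**Clustering.** Manhattan distances between ploidy-scaled segment
vectors, Ward.D2 agglomeration (scipy `linkage(method="ward")` on the
precomputed condensed distances — Ward's squared-update form applied to an
arbitrary dissimilarity). High-amplitude display uses `log(y + 1)` with
guide lines at copy numbers {1, 2, 3, 4, 20, 50, 80}.

## Error model

A consensus call requires a template read set of ≥ 2 members with the
majority base at ≥ 80 % (exactly 80 % calls). The raw baseline samples
one read per template uniformly (seeded). Rates are tabulated per
trinucleotide context (reference strand) × alternative base with explicit
opportunity denominators; zero-opportunity cells are missing, never zero.
The two error processes behave differently by construction: a read-level
error must recur independently across reads to survive consensus
(probability ≈ e²/3 at depth 2), while template damage precedes
amplification, is copied into every read, and passes through consensus at
its full rate. Candidate variants require the same alt allele as a
concordant consensus in ≥ 2 BAGs (either capture strand — requiring the
same strand is the stricter alternative, noted but not adopted); each
candidate reports whether its position is captured on the opposite strand
and whether the alt is seen there, the signature separating double-strand
somatic variants from single-strand damage artifacts.

## Identity

Panel calling: a variant needs ≥ 3 alt reads and ≥ 5 % of covering reads;
source specificity needs the other genome clean (zero alt) at ≥ 12
qualifying reads — under-covered sites are assignable to neither. SNV
observations are counted at template (consensus) level, decoupling the
ratio from amplification depth. The minority ratio is `min(a, b)/(a+b)`;
a BAG is MIXED when its source share falls strictly inside (15 %, 85 %),
applied to all protocols (the band is configurable). RNA identity
admission drops BAGs with fewer than 5 000 unique tags. The collision
expectation `N − N(1−1/N)^n − n(1−1/N)^(n−1)` counts barcodes hit at least
twice; it is exact, no simulation.

## Expression

Bulk mode assigns a read to a transcript only when every aligned base lies
within its exons; single-cell mode requires ≥ 50 % of read length
(boundary inclusive) within a gene's exons. A read qualifying for two
genes is ambiguous and dropped; a tag seen on two genes within a cell goes
to the gene with more supporting reads, ties dropped (the multi-gene
policy is a documented choice — no standard exists). RPKM is
`reads · 10⁹ / (length · total)`, genes reduced to their highest-RPKM
transcript. The PCA normalization sequence is: per-cell mean
normalization, `log(x+1)`, per-gene centering, then PCA with per-feature
centering and unit scaling; constant genes are dropped and recorded. Bulk
profiles are pushed through the same transform and projected with the
fitted scaler/rotation. Markers are the 20 most positive and 20 most
negative PC1 correlations; the marker heatmap orders cells by Euclidean
complete-linkage clustering.

## Synthetic data

The generator emulates: exact positional read layouts (byte-level, with
controllable anchor mismatches), split-round barcode assignment with
natural collision rates (or forced-unique for round-trip tests),
clone-specific integer copy-number states sampled through real NlaIII
sites of a random genome, geometric read depths per template (mean 3.5),
empty-droplet background barcodes, two-source SNV genotypes with
contamination and doublets, and the two error processes (damage shared
within a template, read errors independent). Same seed, byte-identical
output.

It does **not** emulate: GC-dependent capture bias (the random toy genome
has essentially flat GC, so the GC-correction path is exercised by a
dedicated planted-bias test, not the end-to-end runs), mappability and
repeat structure, polymerase chimeras, barcode hopping, ambient RNA
profiles, or droplet physics. Passing tests therefore demonstrate
correctness of the computational contracts on clean planted signal, not
robustness to every artifact of real libraries.

Desk-scale presets (chosen once for recoverability, not per-test): DNA —
2-Mb two-chromosome genome, 2 clones (60/40) with 0.3–0.4-Mb planted CNVs,
24 cells × 20 000 templates, 300 background barcodes, 120 bins, admission
2 000 tags. The depth is set so per-bin multinomial noise (σ ≈ 0.07)
leaves integer states ≥ 7σ apart after ploidy scaling. RNA — 40 genes
(8 markers per source at 8-fold), 60 cells × 1 500 templates, 60-site
panel, 200 background barcodes. In round-trip checks, bins straddling a
planted CNV edge are excluded from exact-state comparison: a bin
containing both states has no single true integer state.

## Known limitations

- CBS at `alpha = 0.02` accepts ~2 % spurious splits per recursion test by
  construction; with `undo.SD = 0.5` the pruning threshold (0.5 σ) is
  arithmetically below the mean shift of any accepted narrow arc, so
  occasional over-segmentation survives. This mirrors the reference
  parameterization rather than deviating from it.
- Equal-count bins cannot be globally ±1 across chromosomes (whole bins
  cannot cross chromosome ends); the guarantee is per-chromosome.
- Ploidy is unidentifiable for constant or all-even-state profiles (see
  above); real near-homogeneous genomes inherit this ambiguity.
- The aligner is external: `bagseq` consumes SAM/BAM or pre-mapped
  synthetic tables and records aligner parameters in configuration only.
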