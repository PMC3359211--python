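# Methods

This note documents the models, algorithms and numerical choices behind
strainomics, and what the synthetic-data generators do and do not emulate.

## Genome model

Genomes are single circular chromosomes over the strict {A,C,G,T} alphabet;
ambiguity codes are rejected at load because the diff engine relies on exact
k-mer identity. Coordinates are 1-based inclusive (GFF3 convention)
throughout. Circular topology is recorded, but features spanning the
replication origin are rejected and the two genomes are compared as
linearised at position 1: this removes wrap-around ambiguity from anchor
finding and gap alignment, and the synthetic generator never plants events
at the junction. CDS translation uses the bacterial code (NCBI table 11);
the alternative starts GTG/TTG render as methionine at codon 1 only,
internal stops render as `*` with translation continuing (so nonsense
positions stay visible), and a trailing stop is excluded from the reported
protein length — a 861-nt CDS yields a 286-aa protein, matching the usual
"length in amino acids" convention of mutation tables.

## Collinear genome comparison

The diff engine is a self-contained anchor–chain–align pipeline rather than
a wrapper around external aligners, so its behaviour is fully testable:

* **Anchors** are maximal exact matches whose seed k-mer (default k = 20,
  minimum 12 — shorter seeds collide too often on 71%-GC genomes) is unique
  in both sequences. Seeds interior to an already-extended match on the
  same diagonal are skipped, making anchor finding linear in practice.
* **Chaining** selects the heaviest strictly increasing, non-overlapping
  subset of anchors (weight = anchored bases, LIS-style dynamic programme).
  Equal-weight ties break toward the lexicographically smallest sequence of
  reference starts, so output is deterministic. Off-chain anchors are kept:
  a displaced copy of a mobile element appears there.
* **Gap resolution.** Each inter-anchor gap pair is resolved recursively:
  the gap is re-anchored locally first (a copy that is repeated genome-wide
  is usually unique within the gap pair), and only irreducible gaps are
  globally aligned with unit match/mismatch/gap costs (edlib). Without this
  refinement, a unit-cost alignment of a segment against its tandem
  duplicate has many co-optimal paths and fragments the insert into
  scattered pieces. A fast path handles the containment case (one segment a
  verbatim substring of the other) for the same reason.
* **Variants.** Mismatch runs are emitted as individual SNVs; gap runs as
  indels, left-aligned to the lowest reference position consistent with the
  alignment (VCF normalisation). An insertion of ≥100 bp whose sequence
  matches the reference elsewhere at ≥95% identity is promoted to a
  transposition, or to a duplication when the copy sits within 2 bp of its
  source interval (a tandem repeat). The 100-bp and 95% thresholds are
  package choices; they cleanly separate mobile-element copies from novel
  sequence at the identity levels of within-species strain pairs.
* **Probe verification** checks 25-mer probes for perfect full-length
  matches on either strand, including the origin junction on circular
  genomes.

Variant calling refuses to run when the anchor chain covers less than half
of either genome — the collinearity assumption has then failed and a
rearrangement-aware comparison would be needed (out of scope).

## Variant effect classification

Variants are mapped onto CDSs and classified mechanically. Notation
positions are nucleotide positions on the coding strand, which is the only
reading under which frameshift positions can exceed the protein length
(`-C 717` in a 335-aa CDS). SNVs are evaluated per codon, with several SNVs
in one codon applied jointly before translation. A frameshift is an indel
whose net length inside the CDS is not divisible by 3; in-frame indels are
re-translated and the reference/mutant proteins diffed by trimming the
common prefix and then the common suffix, which in runs of identical
residues places the change at the most C-terminal position (the HGVS
protein convention). A substitution creating a stop before the annotated
stop is nonsense. Insertion notation is standardised to `+B p/p+1` (base B
inserted after coding position p). Silent and intergenic records are kept
but excluded from the "affected proteins" tally, which counts distinct
locus tags over the remaining records — the accounting under which disjoint
class counts sum to the published total.

## Synthetic strain pairs

`random_genome` draws i.i.d. bases at a target GC (default 71.14%, the
GC content of the *S. erythraea* chromosome) and tiles non-overlapping
ORFs (ATG…stop, 300–1500 nt, both strands) over ~85% of the sequence by
minimally editing the random bases, so the empirical GC stays within 1% of
target at ≥100 kb. `mutate_genome` plants SNVs, short indels (≤4 bp), long
indels (100–1200 bp), mobile-element insertions (copies of existing ≥300-bp
reference segments, transposase-style) and tandem duplications of whole
annotated CDSs. Positions are allocated by stick-breaking: event order is
shuffled, the slack beyond the required spacing is distributed over the
inter-event gaps with a Dirichlet draw, and duplications snap to the first
CDS starting inside a reserved window downstream of their allocated
position. This construction is feasible whenever the arithmetic allows it,
unlike naive rejection sampling, which jams near the random-packing density.
Events keep at least `min_spacing` bases apart end-to-start (default
2000 bp, and never below twice the anchor seed length), which guarantees
each planted event is individually identifiable — a deliberate idealisation:
in real strain pairs nearby edits can be mutually confounded, so perfect
recovery on this generator does not imply perfect recovery on real genomes.

## Time-course differential expression

Expression is modelled directly on the log scale, post-normalisation
(probe-level processing is out of scope). For each gene the null fit is the
intercept and the alternative a natural cubic spline in time with
`spline_df` = 3 basis columns (knots at quantiles of the distinct time
points; df = 1 degenerates to a straight line); the statistic
`(RSS₀ − RSS₁)/RSS₁` is scale- and shift-free. An ODP-style variant is
provided in which each gene is scored by the summed Gaussian likelihood of
its profile under every gene's alternative fit over the same sum under the
null fits, sharing information across genes; it is O(G²) and off by
default.

The null is generated by permuting sample time labels (replicate indices
travel with their samples) and pooling the permuted statistics across genes:
`p = (1 + #{null ≥ observed}) / (1 + B·G)`. Storey q-values use the
single-λ estimator `π̂₀ = #{p > λ}/(m(1−λ))` with λ = 0.5, capped at 1 — a
documented simplification of the spline-over-λ original; with π̂₀ fixed at
1 the computation reproduces Benjamini–Hochberg adjusted p-values bit for
bit. Fermentation phases are an input partition of the time axis (they come
from growth curves, not from the expression data); selected genes are
standardized per gene to mean 0 / SD 1, clustered hierarchically with
1 − Pearson distance and centroid linkage (on standardized rows this is
monotone in squared Euclidean distance, so scipy's centroid linkage applies
directly), the tree is cut into as many clusters as phases, and each cluster
is labelled with the phase containing its mean profile's peak. COG
representation uses the doubling/halving rule: a category is
over-represented when its share of the DEG set is at least twice its
chip-wide share, under-represented when at most half; categories with a
zero share on either side are left unflagged.

## Positional (LAP) region analysis

The per-gene statistic is a moderated difference of class means,
`(x̄_a − x̄_b)/(s + s₀)`, with `s` the pooled standard error and `s₀` the
median of `s` across genes — the shrinkage keeps near-constant genes from
dominating the ranking. Smoothing along the chromosome uses a tricube
kernel with a locally adaptive bandwidth equal to the distance to the
knn-th nearest gene (default knn = 11, odd; circular distance on circular
chromosomes), so sparse and dense regions are treated comparably; the
kernel and the knn rule are package choices within the "local variable
bandwidth kernel estimator" family, and both are configurable. The
permutation test shuffles the raw statistics across positions, re-smooths,
and computes a two-sided position-specific p-value with the +1 correction —
no pooling across genes, because each position's smoothed value lives on its
own neighbourhood scale. The two strands are analysed independently.
Regions are maximal runs of consecutive same-strand genes with q below
threshold, absolute raw class-mean difference above the fold-change filter,
and a consistent smoothed-statistic sign; the fold-change filter applies to
the raw per-gene difference, not the smoothed value.

Because the smallest attainable permutation p-value is 1/(B+1), the number
of permutations bounds the smallest attainable q-value at roughly
`π̂₀·m/(k·(B+1))` for k genes at the floor; with ~1000 genes and a 30-gene
block, q ≤ 0.01 requires B above ~2000. Null-calibration runs are cheaper
(no call should survive any B), so tests use B = 500 for null suites and
B = 2500 for recovery suites.

## Expression simulator

`simulate_timecourse` draws per-gene baselines N(8, 1.5²), adds to each DEG
a piecewise-constant bump confined to one phase with amplitude
`effect_sd × noise_sd` (the simplest shape the spline alternative must
detect; amplitude is the single effect-size knob), gives genes in
chromosomally contiguous blocks a shared ±offset in the second phase of the
designated contrast, and adds i.i.d. Gaussian noise (default SD 0.25
log-units — a convenience default, as array noise levels vary by platform).
The default design is 6 time points (12–72 h) × 2 replicates, the design
used for the null-calibration suites. Power analyses of the F-like
statistic show that a 2-noise-SD bump is not reliably detectable at
q ≤ 0.05 under that duplicate design (a typical planted gene reaches only
F ≈ 4 on 3 and 8 degrees of freedom), so the recovery suites use richer but
still realistic designs — 10 time points × 3 replicates for DEG recall and
triplicates for block recovery, with the fold-change filter at half the
planted offset so that membership reflects the positional procedure rather
than per-gene estimator noise at exactly the threshold. The simulator omits
probe-level artifacts, batch effects, and correlated noise; passing tests
demonstrate correctness of the procedures under the stated model, not
performance on any particular array platform.

## Known limitations

* No rearrangement detection beyond single-segment transposition; the
  engine assumes dot-plot collinearity and enforces ≥50% chain coverage.
* Multi-contig drafts, origin-spanning features, introns and selenocysteine
  recoding are unsupported.
* The exact statistic EDGE/ODP uses internally is under-determined in the
  literature it descends from; the F-like spline statistic is the default
  here and the ODP-sum statistic an option, both comparing the same pair of
  nested fits.
* The q-value floor of permutation tests ties region sensitivity to B (see
  above); choose B by the q threshold sought.
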