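# Methods

This note documents the models, algorithms, parameter choices and
known limits of `operonscope`. The package analyses long rRNA-operon
amplicon reads (16S–ITS–23S, 3.7–5.7 kb) for species/strain-level
community differences, and ships a generator that emulates such an
experiment so every stage is testable against ground truth.

## Synthetic data model

**Reference panel.** One random "genus backbone" operon is drawn per
panel: 1550 nt 16S + ~620 nt ITS + 2900 nt 23S (total ~5 kb, inside
the 3700–5700 amplicon window). Each additional species is derived
from the backbone by substituting bases only inside fixed variable
intervals — nine V-region-like windows in 16S and periodic 100 nt
windows in 23S — so that:

* realized species-vs-backbone identity is exact by construction
  (`round((1 − target) · L)` substitutions at distinct positions);
  divergence targets therefore verify to well under ±0.5 pp;
* a conserved 275 bp window at 16S positions 280–555 is never touched,
  which is what makes short-window identity read systematically higher
  than full-gene identity — the short-read inflation the phylo stage
  demonstrates;
* canonical universal-primer sites (27F, 343F, 519F, 907F, 1392F,
  1492F; degenerate codes resolved to concrete bases) are planted at
  conserved positions, so primer annotation behaves as on real 16S.

Divergence targets are defined **relative to the backbone species**;
pairwise identity between two derived species is not independently
controlled (their substitution sets may overlap).

**Operon copies.** Within a species, copies differ by ~0.3 %
point substitutions (outside anchors and the conserved window), by the
presence/absence of a planted 76 nt tRNA-Ile marker (tRNA-Ala is in
every copy), and by one 0–150 nt ITS indel block. Copy identity over
the 16S+23S genes stays ≥ 99 %; the ITS is deliberately polymorphic,
because that polymorphism is exactly the feature the consensus stage
groups on. Gene anchors (first/last 40 nt of 16S and 23S) are held
fixed so reads and consensus sequences can be dissected by motif
search.

**Reads.** Each sample draws reads multinomially from its taxon
weights; copy uniform; direction fair-coin. Errors are i.i.d. per base
(defaults 5 % substitution, 1.5 % insertion, 1.5 % deletion ⇒ ~92 %
read accuracy, the accuracy scale of 2D chemistry), scaled per strand
by `strand_bias`. Reverse reads are emitted reverse-complemented.

**Strand-asymmetric component.** A purely i.i.d. per-strand rate
multiplier cannot reproduce forward/reverse reads separating by
similarity: doubling a read's random error makes it *farther from
every other read*, including other reverse reads (d(rev,rev) ≈ 2e_rev
> d(fwd,rev)), so noisy reads chain rather than cluster. What makes
direction-split clusters possible is *systematic* strand-specific
miscalling. `ErrorModel.strand_profile` plants a deterministic set of
substitutions (that fraction of template positions, fixed per template
and seed) in every reverse-direction read. Reverse reads then share
those miscalls, reproducing the observed two-cluster direction split;
the multiplier is retained for rate-level asymmetry. The cohort
default is `strand_profile = 0`; the direction-split analyses use
0.05, which separates fwd/rev pair distances by ~5 pp.

**Cohort.** The default design is the study layout: AC5KO-exercise
n=3, AC5KO-sedentary n=4, WT-exercise n=4, WT-sedentary n=6. Two
optional structured effects: a taxon enriched k-fold in exercise
samples, and a "sister species" that *replaces* the backbone taxon in
WT-sedentary samples (the cryptic-variant scenario: that group's
population of the taxon simply is a different species).

## Best-hit assignment

Reads are size-filtered to 3700–5700 bp inclusive. Candidate
references are found by exact spaced-seed matches with the classic
coding-region template `111010010100110111` (weight 11, span 18) on
both strands; seed diagonals are clustered (gap > band width starts a
new cluster) and each cluster is extended once by banded local
alignment with affine scores +2/−3, gap open 5, gap extend 2, band 200
(≈ 2× the expected indel drift at a 15 % indel load). The single
best-scoring reference wins; ties break by higher identity then
lexicographic reference id. Alignments must exceed 1000 columns
(strict) to be counted.

Identity is defined once and used everywhere: matches / alignment
columns, internal gaps counting as columns, terminal overhangs
excluded. E-values are not computed — selection is by raw score.

Counts are normalized by multiplying each sample row by
(max row total / row total), so counts only scale up; zero-read
samples are kept as zero rows and skipped by normalization.

## Community statistics

* **Transform**: element-wise fourth root of the normalized counts.
* **Bray-Curtis**: Σ|x−y| / Σ(x+y); an all-zero pair is defined as 0
  with a warning.
* **NMDS**: SMACOF iterations with monotone regression (PAVA) under
  Kruskal's primary tie treatment and Guttman updates; Kruskal
  stress-1; default 16 starts, tolerance 1e−6, 300 iterations max.
  The first start is the classical-scaling configuration and the rest
  are seeded random starts, so start sets nest and best-of-n stress is
  monotone in n.
* **PERMANOVA**: Gower-centered −½D² decomposition with sequential
  (Type I) hat-projector sums of squares for the terms (activity,
  genotype, activity×genotype), pseudo-F against the residual mean
  square, and raw permutation of sample indices;
  p = (1 + #{F* ≥ F}) / (1 + n_perm), default 999 permutations.
  `n_perm=None` enumerates all n! permutations exactly. The residual
  mean square is floored at 1e−12 × total SS so perfectly separated
  groups yield stable, comparable F across permutations instead of
  floating-point noise. The implementation reproduces vegan `adonis2`
  (by="terms") SS/R²/F to printed precision; this cross-check is part
  of the test suite. Note that small balanced designs make permutation
  p-values conservative through permutation-class ties (with 4+4
  samples only 35 distinct splits exist); calibration checks use 6+6.
* **Alpha diversity**: bias-corrected Chao1
  (S_obs + F₁(F₁−1)/(2(F₂+1))) and Shannon with natural log;
  counts are rounded to integers for Chao1 and rarefaction only.
  Rarefaction is the exact hypergeometric expectation.
* **Enrichment**: per-taxon difference of group means, ranked by
  |difference|; mean ± SD reported within the enriched group. No
  multiple-testing control (none is part of the protocol emulated).

## Heatmap (cryptic-variant detection)

Per taxon, the top n reads per sample (default 15, rank = identity ×
alignment length, ties by read id) are annotated with the bundled
universal primers — ungapped IUPAC-aware scan at ≥ 85 % identity over
the full primer span, both orientations tried, direction by majority
strand vote — and oriented forward; unannotatable reads are discarded.
All-pairs global alignment gives distance = 1 − identity; pairs
differing more than 2× in length are flagged and set to max + ε.

Ordering is average-linkage dendrogram leaf order. The automatic cut
takes the largest gap between consecutive sorted merge heights,
restricted to cuts producing ≤ 8 clusters, and only accepts it when
the gap exceeds 8× the mean of the remaining gaps; otherwise the
matrix is one cluster. The factor was calibrated on the generator:
unstructured single-species matrices show largest-gap factors ≤ ~6,
while programmed direction splits or 94 %-sister-species structure
show factors ≥ ~40, so the rule has a wide safety margin on both
sides. A manual threshold overrides the auto cut, and the silhouette
of the accepted clustering is reported for audit.

Cluster composition is reported by genotype×activity group and by read
direction; a cluster is flagged *group-exclusive* when one group holds
≥ 90 % of its reads.

## Consensus reconstruction

Reads of one taxon (optionally per genotype×activity group) are
annotated for the tRNA markers (≥ 80 % identity motif search) and for
ITS length (distance between the 3′ 16S anchor hit and the 5′ 23S
anchor hit), then partitioned by (ala, ile, ITS-length bin of 25 nt).
Groups under 5 reads are dropped with a logged reason — the
inadequate-coverage path. Per group: the medoid read (minimum summed
edit distance) seeds the template; all reads are star-aligned to it
(banded global affine alignment); each column is majority-voted with
deletion as a votable symbol, insertion columns requiring majority
support, and ties keeping the template symbol; the vote iterates until
the template is a fixed point (max 10 rounds, unconverged results are
flagged). Variant names carry an `rRNA_A`/`rRNA_B`… suffix by
descending group size. At the default error model, 20 reads polish to
≥ 99.5 % identity and identity is monotone in coverage (5→40 reads).

## Species-level verification

16S/23S regions are cut from operon-scale sequences by locating the
conserved anchor motifs (≥ 80 % identity; reverse complement tried, so
extraction is orientation-invariant). Sequences are star-aligned to
the longest one; "unambiguously aligned" columns are those gap-free
and ACGT-only in every row. Identity matrices are computed over masked
columns, optionally restricted to a window given in the center
sequence's coordinates (default 280 + 275 nt, the conserved slice).
Species calls are strict: same species iff identity > 0.97.

Trees are neighbor-joining on Jukes-Cantor distances
(d = −¾ ln(1 − 4p/3); p ≥ 0.75 is an error naming the offending pair)
over masked columns, with column-resampling bootstrap (default 100)
and majority-position supports written as internal node labels;
negative NJ branch lengths are clamped to zero. A distance method is
deliberate: the question the trees answer — do operon copies and
group-specific consensus variants resolve into species clusters — does
not require likelihood machinery at this scale.

## Alignment engines and numerical choices

Two engines: a numba-jitted banded dynamic program (local with
traceback for scored best-hit extension; global for paths used in star
alignment and identity) and edlib for unit-cost edit distance where
only relative distance matters (medoid selection, anchor/marker
location). The global aligner uses the same +2/−3/5/2 scores: affine
gap costs matter here because unit-cost optimal paths systematically
convert substitution runs into indel pairs, which both shrinks column
masks and inflates masked-column identity by ~1 pp at 7 % divergence —
enough to break threshold calibration. Bands are ±200 diagonals around
the corner-to-corner diagonal (indel drift at these lengths is ≤ ~50).
Alignment paths are canonicalized by merging adjacent I/D runs into
mismatches.

Determinism: every stochastic step takes a seed; sub-seeds are derived
by fixed offsets from the global seed; reruns are byte-identical
(checked via the manifest's output hashes).

## What the synthetic data does and does not show

The generator reproduces the *structure* of the experiment — multicopy
operons, feature polymorphism, group-structured communities, strand
asymmetry, error load — but not sequencing physics: no positional or
homopolymer error profiles, no quality scores (qualities, if FASTQ is
requested, are placeholders; the pipeline never uses them), no
chimeras, no barcode demultiplexing. Passing tests demonstrate the
pipeline's correctness and its qualitative diagnostic patterns under
realistic error loads; they do not certify performance on real flow
cells, where error structure is richer and reference databases are
incomplete. Divergence between derived species pairs (both non-
backbone) is emergent rather than programmed. PERMANOVA p-values on
very small balanced designs are conservative by permutation-class
discreteness.

## Problem sizes used in checks

Acceptance-style checks run at desk scale: 200 reads for assignment
recovery, 20 reads × 5 references for oracle agreement, 17-sample
cohorts at 30 reads/sample for community statistics, 4 × 8–12 reads
for heatmap patterns (5 replicate seeds for the group-exclusive
pattern), 5–40 reads for consensus, a 5-point identity grid
{93, 96, 97, 98, 99.5} % for threshold calibration, and 4–16 leaf
trees with 50–100 bootstrap replicates.
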