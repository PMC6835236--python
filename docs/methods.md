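# Methods

This note documents the models and procedures implemented in `dupscape`,
the defaults they use and why, what the simulators do and do not emulate,
and the numerical conventions that make results reproducible.

## Coordinates and distances

All genomic coordinates are 1-based inclusive (the GFF3 convention).
The distance between two genes is the intergenic gap between their nearer
boundaries, `start_downstream − end_upstream − 1`, clamped at 0 for
overlapping or book-ended genes. Genes are ordered along a chromosome by
start, ties broken by end then gene id, so adjacency (and therefore the
tandem call) is deterministic for any input permutation. Only features of
type `gene` define the order; nested or overlapping genes keep separate
positions.

## Architecture classification

Inputs are predictions, not sequences: signal peptide with cleavage
position, transmembrane segments, coiled-coil segments with probabilities,
and profile-HMM domain hits already filtered by e-value (default ≤ 0.05)
and model coverage. The partial-domain filter discards hits covering less
than 60% of the domain model — the filter is standard practice when screening
for complete globular domains but no canonical cutoff exists, so it is
configurable.

The cascade is total and deterministic; the first matching rule wins:
no C1q hit → error; no signal peptide or any TM segment → other/uncertain;
≥ 2 C1q domains → smultiC1q; SUEL preceding the C1q domain → sSUEL/C1q;
collagen preceding → C1q-like type I; a coiled-coil segment (probability
> 0.5) strictly between the cleavage site and the C1q start → type II;
C1q starting within 30 aa of the cleavage site → sghC1q; else
other/uncertain. The 30-aa linker tolerance operationalises "immediately
followed by the C1q domain": no numeric definition is standard, 30 aa
comfortably covers real inter-domain linkers while excluding unannotated
N-terminal domains; it is a keyword argument. SUEL/collagen checks take
precedence over the coiled-coil check, and the multi-domain check over all
N-terminal checks, because multi-C1q proteins may or may not carry a
coiled-coil.

## Paralog clustering

Pairwise identity uses a global (Needleman–Wunsch) alignment with BLOSUM62
and affine gaps (open 10, extend 1; a gap of length L costs
`open + (L−1)·extend`). Identity is the number of identical aligned
columns divided by the length of the **shorter** sequence — the convention
of representative-clustering tools, and the reading that best matches a
"> 50% pairwise identity" cluster definition. The alignment-length
denominator is available as an option. When several alignments are
co-optimal the aligner's first (deterministic) enumeration is used; the
test suite checks the reported identity against an exhaustive enumeration
of all optimal alignments at small sizes.

The default partition is single-linkage: connected components of the graph
with an edge wherever identity is **strictly** greater than the threshold
(default 0.5). Single linkage is order-independent, admits an exact
brute-force oracle, and refines monotonically as the threshold rises. A
greedy representative mode (longest sequence first, join the first
representative above threshold) mirrors CD-HIT's behaviour but depends on
visit order, so it is not the default. Clusters are reported sorted by
descending size then smallest member id. "Large" clusters are those with
≥ 10 members.

## Duplication modes

A family gene in a size-1 cluster is SINGLETON. Otherwise it is TANDEM if
either immediate neighbour in the full gene order (background genes
included, strand ignored) belongs to the same cluster; else PROXIMAL if the
nearest same-chromosome, same-cluster paralog lies within 100,000 bp
(inclusive, intergenic gap); else DISPERSED. Only same-cluster family
genes count as paralogs — a flanking family gene from a different cluster
does not make a tandem. The 100-kb threshold is applied to the intergenic
gap rather than start-to-start distance because the gap is well defined for
overlapping genes and is the conservative reading of "within 100 kb".
Summary fractions are percentages of the family size, printed at 2 decimals
with half-away-from-zero rounding (the convention of published summary
tables; banker's rounding would print 62.395% as 62.39 split by binary
representation accidents).

## Density landscape

Chromosome density is `genes / (length in Mb)` at 2 decimals. Windows tile
the chromosome as `[k·w+1, (k+1)·w]` (default w = 1 Mb, last window
partial); a gene belongs to the window containing its **start** coordinate.
Midpoint assignment differs only for boundary-spanning genes and start is
the simplest convention to reproduce. BED output uses 0-based half-open
windows.

## Per-site selection test

The caller is a counting method in the SLAC family. Pipeline: protein MSA
(mafft when lengths differ; substitution-only paralog sets are already
columnwise comparable) → back-translation to a codon alignment (the CDS
must translate exactly to the protein; trailing stop codons are ignored) →
trimming to gap-free columns, optionally within a declared domain region,
with a provenance map back to original columns → NJ guide tree from
Jukes–Cantor-corrected nucleotide p-distances (saturated pairs capped at
p = 0.749) → Fitch parsimony codon ancestors → per-branch, per-site
substitution counts → binomial test.

Determinism: NJ breaks Q-criterion ties toward the smallest index pair and
clamps negative limb lengths to zero; Fitch ties prefer the state with the
fewest nucleotide differences from the neighbouring candidate sets, then
lexicographic codon order.

Counting: between parent and child codons differing at d positions, all d!
orderings are enumerated; orderings passing through a stop codon are
discarded and the synonymous/nonsynonymous step counts of the remainder
are averaged (so counts may be fractional). If every ordering hits a stop,
the pair contributes d nonsynonymous counts with a warning. Per site,
observed syn + nonsyn always equals the parsimony nucleotide-change count.

Test: the expected synonymous fraction at a site is the mean
potential-synonymous-site content of the codons observed there divided
by 3, with stop mutants excluded from both numerator and denominator
position-wise. The two-sided p-value doubles the smaller tail of the
binomial, continuously extended through the regularised incomplete beta so
fractional counts are handled exactly. Sites without substitutions are
NEUTRAL with p = 1. P-values are reported raw at α = 0.05, matching how
per-site selection methods are conventionally thresholded; an optional
Benjamini–Hochberg mode is provided but off by default. Likelihood-based
site methods are not re-implemented; their positive-site lists can be
merged via the consensus rule (≥ 2 methods → STRONG, exactly 1 →
MODERATE).

### Statistical behaviour and a known limitation

On neutral alignments the caller is strongly conservative: the measured
POSITIVE rate at α = 0.05 is below 1% (the discrete two-sided binomial plus
parsimony undercounting both push p upward). Power for detecting planted
ω = 5 sites in 20-sequence alignments is, however, intrinsically low. The
binomial needs roughly 13 substitutions with zero synonymous counts, or
≥ 20 with at most one, to clear α = 0.05; true synonymous events accrue in
proportion to total tree length regardless of ω, and Fitch parsimony caps
the recoverable substitution count near the number of distinct leaf
codons (~12–18 at 20 taxa), collapsing the 25–40 events that actually
occur at a fast site. Feeding the simulator's *true* substitution
histories through the same binomial machinery detects 70–100% of planted
sites (a unit test pins this), so the loss is attributable to parsimony
counting at small sample sizes, not to the test statistic — consistent
with the well-known conservativeness of counting methods on few
sequences. Practical guidance: treat the internal caller as a
high-precision, low-recall member of a method ensemble and rely on the
consensus merger for sensitivity.

## Genome simulator

`simulate_genome` plants a family on `n_chromosomes` chromosomes (default
3 × 12 Mb) among background genes (default 300). Defaults define the study
conditions: 12 tandem arrays of 3–15 copies (1–10 kb gaps, one shared
strand per array), 10 proximal pairs (20 genes; 30–90 kb apart with 1–3
intervening background genes), and 15 dispersed copies seeded from array
founders and placed in separate blocks. Event blocks are always separated
by ≥ 110 kb with at least one background gene between them, so flanking
never leaks across events and nothing non-proximal falls inside 100 kb.

Each copy diverges from its **event founder** by the configured expected
substitutions per site (default 0.05), transition:transversion 2:1, with
mutations that would create internal stops reverted. Divergence is
founder-relative rather than serially accumulated: serial accumulation
over a 15-copy array would drive within-array protein identity below the
clustering threshold, whereas real tandem arrays show copies that are all
recognisably similar to the array consensus; founder-relative divergence
keeps mean within-array identity above 0.7 at the default rate. With
probability `near_identical_fraction` (default 0.1) a copy is emitted with
zero coding divergence, mimicking very recent duplications; its single
intron still drifts (3× exon rate plus occasional 1–10 bp indels,
echoing microsatellite-rich intronic divergence between otherwise
identical paralogs). Architecture features are emitted directly from the
per-category template (predictor behaviour is not simulated; a noise
option can drop signal-peptide annotations).

What the simulator does **not** emulate: annotation errors and truncated
gene models, transposable-element mechanics beyond dispersed placement,
whole-genome duplication, pseudogenes, GC/codon-usage bias, and realistic
intergenic sequence (coordinates only, no genome FASTA). Passing tests
therefore demonstrate correctness of the classification logic under clean
annotations, not robustness to annotation noise.

## Alignment simulator

`simulate_selection_alignment` evolves `n_sites` codons along a random
bifurcating topology (random sequential joins) with exponential branch
lengths rescaled so the mean root-to-tip path equals `tree_depth`
(default 1.0 expected neutral substitutions per site). Each viable
single-nucleotide change has base rate 1/9 — so the total neutral rate is
≈ 1 per unit branch length — multiplied by the site's ω when
nonsynonymous; stop codons are unreachable. The true per-site synonymous
and nonsynonymous event counts are recorded. The default depth of 1.0 is
a compromise fixed by two closed-form constraints: below ~0.6 the binomial
cannot reach significance at all (too few substitutions), while much above
~1.5 parsimony saturation dominates; 1.0 sits between them.

## Problem sizes used in validation

The shipped validation runs use compact instances chosen to exercise every
code path with exact ground truth: genomes at the default study conditions
(~130–150 family genes, ~440 genes total), a 2-chromosome small genome for
unit tests, 50 random ≤ 25-protein sets for the clustering oracle, and
20 × 200-codon alignments for the selection studies.
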