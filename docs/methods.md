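# Methods

## Model of synteny

A synteny block is a set of homologous gene pairs whose order is conserved
between two genomes. The package treats gene order — the rank of each gene
along its chromosome — as the primary coordinate system; nucleotide
coordinates are carried along when available but nothing in the
reconstruction requires them. Scaffolds are treated exactly like
chromosomes. Genes without strand information are treated as forward in
orientation logic.

Two homology criteria are deliberately kept distinct, trading sensitivity
against specificity:

* **RBH (anchors).** Reciprocal best hits are conservative and nearly
  always one-to-one orthologs; they form the backbone of blocks. The RBH
  relation is a matching by construction (each gene has at most one best
  partner, and reciprocity is required).
* **Non-RBH homologs (completions).** A permissive local-alignment
  criterion (≥ 30% positive columns, coverage of the shorter protein
  strictly > 0.5) adds diverged or duplicated homologs to an existing
  block, but only within Δ₂ genes of an anchor and only when at least one
  member is not an RBH-gene. Completions may repeat across blocks and may
  pair one gene with several partners inside a block, which permits
  overlapping and included blocks; per-block statistics also report a
  deduplicated count (at most one relationship per gene per block).

## Alignment scoring

The candidate search is a two-stage FASTA-style scan. The prefilter slides
the two ungapped sequences against each other and scores each offset
independently by the number of shared k-tuples (k = 2); a candidate is
kept when its best offset reaches 5 shared words, and the K = 6
highest-scoring candidates are refined. The refinement is an end-gap-free
global alignment (Gotoh affine gaps: open 12, extend 2, a gap of length L
costing 12 + 2(L−1); terminal gaps free) implemented as a numba-compiled
kernel; it is validated in the test suite against a pure-Python DP oracle
and against Biopython's `PairwiseAligner` on identical gap conventions.

Two derived quantities are reported per alignment:

* `similarity_pct` — the percentage of alignment columns, between the
  first and last aligned residue pair, with a strictly positive
  substitution score. This is the "percent positives" figure used by the
  non-RBH criterion and by the reported mean ortholog similarity.
* `score_0_100` — the raw alignment score divided by the smaller of the
  two self-alignment scores, × 100. This is the 0–100 normalized score
  that ranks candidates and is thresholded at 40 for RBH. Percent
  positives was considered for this role and rejected: under end-gap-free
  alignment an unrelated pair can align a short high-identity island
  (e.g. 9 positives in 10 columns → 90%) and outrank a true full-length
  ortholog, which inverts best-hit selection. Normalizing the raw score by
  the smaller self-score gives 100 for identical sequences, near 0 for
  spurious overlaps, and a monotone measure of full-length similarity.

The default substitution matrix is BLOSUM62 for both refinement and the
local non-RBH test; any matrix from Biopython's collection or an
NCBI-format matrix file can be named in `AlignmentParams`. Best-hit ties
are broken toward the lexicographically smallest gene id, so results are
deterministic. The length-ratio bound (≤ 1.3, inclusive) is applied after
reciprocity.

## Chaining and completion semantics

Δ₁ chaining counts *RBH-genes only* between two anchors: the number of
RBH-genes strictly between the two genes must be < Δ₁ in both genomes, and
both genes must share chromosomes in both genomes (chains never cross
chromosome boundaries). Any number of non-RBH genes may sit inside a
block. Δ₂ completion distances count *all* genes, and the bound is strict
(< Δ₂ from the same anchor in both genomes); completions attach to anchors
only, not transitively to other completions. When a single Δ is given it
sets both Δ₁ and Δ₂; the default Δ = 5 tolerates up to four intervening
RBH-genes. Blocks need ≥ 2 anchors; smaller components are reported as
non-syntenic RBH in the pairs output.

Block orientation is the sign of the Kendall rank correlation of anchor
positions (0 for an exactly balanced pattern). Block spans cover all
member genes, completions included. Breakpoint regions are computed per
genome after merging overlapping block projections: one region per gap
between consecutive merged spans plus the two terminal regions, each
listing the genes strictly outside the flanking spans and the features
inside the nucleotide gap. By construction blocks and breakpoint regions
tile each chromosome's rank axis.

## Ortholog families

Families are connected components of the graph whose vertices are genes
and whose edges are syntenic homology relationships (anchors and
completions pooled over all pairwise comparisons). Only components with
exactly one gene from every input genome are kept; components containing
duplicated genes, or missing a genome, are discarded. A `min_genomes`
option relaxes the every-genome requirement for exploratory use.

## Congruence scanning

Block sets from 2–3 reconstructions are projected on a common reference
genome. Within each atomic interval (delimited by all block endpoints),
two tools are congruent when some covering block of each maps overlapping
target intervals (≥ 1 shared nucleotide, no minimum-overlap fraction);
when a tool's own blocks overlap, one congruent block suffices. Atomic
intervals are merged into maximal regions of constant classification. The
coarse classes are `all-three-congruent`, `pair-congruent`, `single-tool`,
`covered-but-discordant` and (implicitly, not emitted) uncovered; the full
coverage × pairwise-verdict pattern is preserved in a `detail` field,
whose vocabulary is the cross-product of coverage patterns and verdicts.
Regions produced by a block nested inside a larger block of the same tool
are flagged `included` and summarized separately, since such blocks mostly
reflect duplicated regions.

## The direct-neighbor null model

Two-anchor blocks are the smallest reportable synteny signal, so their
false-positive risk matters. Under independent uniform random gene orders,
the probability that a specific homolog pair is adjacent in a genome with
chromosome sizes c₁…c_k and n genes in total is Σⱼ 2(cⱼ−1)/(n(n−1)) —
both genes must land on the same chromosome and occupy adjacent positions
— and the probability that two homolog pairs are direct neighbors in both
genomes simultaneously is the product of the per-genome terms. This closed
form is a reconstruction derived here; the test suite validates it against
permutation simulation (10⁶ draws, agreement within 3 Monte-Carlo standard
errors for n ∈ {5, 10, 50}).

## Synthetic data generator

`simul` evolves an ancestral genome of random proteins (residues drawn
from Robinson–Robinson background frequencies, lengths uniform 100–500)
along two independent lineages: per-site substitutions with probability
`divergence` (replacement drawn from the background, so a site may revert
to itself — realized divergence is ≈ 0.95 × nominal), optional per-gene
loss, gain and tandem duplication, then the configured numbers of
inversions (segment reversal with strand flip), reciprocal translocations,
fusions and fissions per lineage, with breakpoints drawn uniformly over
internal positions. Nucleotide coordinates are laid out deterministically
(3 nt per residue plus a 200 nt intergene). Default conditions are two
chromosomes of 500 genes, divergence 0.15, five inversions and two
translocations per lineage, and no gene turnover.

Ground truth is derived from the final pair rather than replayed from the
event log: the ortholog matching is the set of ancestor genes surviving in
both lineages, and true blocks/breakpoints are the maximal runs of
orthologs whose partners are consecutive (in either direction) among the
other genome's orthologs on one chromosome. This makes the truth exact
even when later events split or merge earlier segments. Recovery scoring
reports ortholog-pair precision/recall over in-block relationships and
breakpoint recall/precision, a true gap counting as recovered when a
predicted block boundary lies within the tolerance (in genes) of it.

What the generator does *not* emulate: substitution-matrix-biased
mutation, indels within proteins, rate heterogeneity across sites and
genes, intergenic sequence, unbalanced rearrangements, and segmental
duplications beyond single-gene tandem copies. Passing tests therefore
demonstrate correct reconstruction under idealized divergence, not
performance on real annotations with fragmented scaffolds or
fast-evolving families.

## Numerical and design choices

* Ranks are 0-based; nucleotide coordinates 1-based inclusive. Overlapping
  genes in imported annotations are ordered by start, then end, then id.
* All tie-breaks (best-hit, traceback preference, block ids, palette
  assignment) are fixed, so identical inputs give byte-identical outputs,
  images included.
* The coverage bound of the non-RBH test is strict (> 0.5) while the
  similarity bound is inclusive (≥ 30%), and the completion distance bound
  is strict (< Δ₂) — these asymmetries are deliberate and tested.
* Test and validation workloads use compact proteins (uniform 80–200
  residues) and 100–1,000-gene genomes; these sizes exercise every code
  path while keeping the suite fast. The simulator default of 100–500
  residues reflects typical eukaryotic protein lengths.
* `refine_score`/`test_nonrbh_homology` canonicalize argument order
  internally (by length, then sequence), making results exactly symmetric;
  reported lengths are (shorter, longer).

## Known limitations

* Multi-genome k-way block reconstruction is out of scope; multi-genome
  analyses are assembled from pairwise runs (families, congruence).
* No statistical significance is attached to blocks beyond the
  direct-neighbor null for two-anchor blocks.
* The importer handles GenBank, EMBL and a structured-header FASTA
  dialect; GFF3 is not supported.
* Whole-proteome searches are quadratic in genome count within a pair
  (prefilter) and were tuned for desk-scale genomes (10³–10⁴ genes), not
  for mammalian-scale annotation sets in a single process.
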