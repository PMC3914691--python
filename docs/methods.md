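# Methods

`paleograss` implements the inference chain used in grass paleogenomics to
reconstruct ancestral karyotypes and quantify subgenome dominance after
whole-genome duplication (WGD), together with a forward simulator that
produces fully ground-truthed inputs so that every stage can be scored
without external data.

## Homology metrics and filtering

Pairwise CDS BLAST hits are aggregated per gene pair.  With HSP = high
scoring pair:

* AL (aligned length) = number of distinct query columns covered by HSPs;
  overlapping HSP query intervals are clipped so every column counts once,
  with each HSP's identities prorated by its surviving fraction.
* CIP = 100 x (sum of clipped identities) / AL.
* CALP = 100 x AL / query length (clipping guarantees CALP <= 100).

Acceptance thresholds depend on how long ago the two genomes diverged:
CIP/CALP 70/70 for closely related genomes (< 50 Ma) and 50/50 for distant
ones (> 50 Ma).  The published threshold sentence ("70% and 50%") does not
state which metric takes which value; we read it symmetrically and expose
both numbers in `FilterPolicy`.  Overlap clipping is applied on the query
(the definitions are silent on overlap), which preserves the
"fraction of the query aligned" semantics of CALP.  Candidate orthologs
are reciprocal best hits per genome pair (bit score, ties broken
lexicographically by subject id); candidate paralogs are each gene's best
non-self intra-genome hit.  The pairing rule beyond the CIP/CALP filter is
this package's choice.

## Ks estimation and dating

Synonymous divergence is estimated with Nei-Gojobori (1986) counting:
per-codon synonymous site fractions (fraction of the three alternative
nucleotides per position that give a non-stop synonymous codon) averaged
over both sequences; synonymous differences averaged over all minimal
substitution paths between differing codons with equal path weights, paths
through stop codons excluded whenever a stop-free path exists; Jukes-Cantor
correction Ks = -(3/4) ln(1 - (4/3) ps).  ps >= 3/4 is reported as
saturated (NaN) and excluded from dating.  The original study does not name
its Ks estimator; NG86 was chosen because it is fully specifiable and can
be checked codon-by-codon against a brute-force path-enumeration oracle
(see `tests/test_dating.py`).

Ages follow the strict molecular clock T = Ks / (2 r) with
r = 6.5e-9 substitutions per synonymous site per year.  Pairs dating to
the inclusive window [50, 70] Ma are ancient WGD duplicates; a recent
window (default [2, 20] Ma) captures lineage-specific neopolyploidy.
Ks > 3 is treated as saturated.

Ks distributions are modelled as mixtures of log-normals: Gaussian EM on
ln Ks with k-means initialisation, 10 seeded restarts, tolerance 1e-6 on
the log-likelihood, at most 500 iterations and a variance floor of 1e-6
(sd 1e-3), selecting k by BIC = -2 logLik + (3k - 1) ln n.  The EM
implementation is deliberately in-package rather than delegated so that
the per-iteration monotonicity of the log-likelihood can be asserted, and
because the BIC parameter count is part of the contract.

## Synteny chaining and ancestral compartments

Anchors (accepted ortholog/paralog pairs with midpoint coordinates) are
chained per chromosome pair by dynamic programming: longest strictly
collinear subsequence per orientation, with the classical cleaning
parameters - at least 6 anchors per block ("more than 5" read strictly), a
maximum gap of 100 kb between consecutive anchors measured independently
on each side (a break on either side splits the chain), and a minimum
block span of 100 kb (a block is kept when either side reaches the span).
Blocks are extracted greedily by anchor count (ties by span, then leftmost
start) so no anchor belongs to two blocks.  Tandem-proximal paralog pairs
(same chromosome, within the gap distance) are excluded from paralogy
anchors: they are copy-number variants, not WGD relics.

Blocks are stitched into ancestral compartments: block sides overlapping
on a chromosome merge into one node, each block links its two sides, and
connected components define ancestral labels.  Components whose paralogy
edges span two or more genomes are ancestral duplications (duplicated
blocks found at orthologous positions descend from one ancestral region);
paralogy confined to one genome is lineage specific.

## Retained vs shuffled duplicates

An ancient pair is *retained* when its two genes fall inside the two sides
of a recognized paralogon and *shuffled* otherwise.  The paralogon is
taken at chromosome scale: per chromosome pair and ancestral component,
the convex hull of all kept paralogous blocks.  Strict block-anchor
membership would misclassify retained pairs that sit in sub-threshold
chain fragments inside an otherwise continuous duplicated region; the
hull reading matches the notion of "known paralogous blocks".
Partition percentages are rounded half away from zero, matching printed
summary tables.

Deletion chronology is small parsimony on the four-leaf species tree
((rice, brachypodium),(sorghum, maize)): a copy absent everywhere was lost
before speciation (ancestral); absence confined to one clade is a lineage
loss; absence in one species is species specific; other patterns resolve
to the minimum number of lineage/species events, with cross-clade pairs
counted as two independent species losses.

## Subgenome dominance

Equal retention between sister compartments is tested with a Pearson
chi-square against an equal split of the observed retained total
(E = (n_a + n_b)/2, df = 1, no continuity correction - counts are large
where the test matters).  The larger count is labelled dominant (D) and
the smaller sensitive (S) when p < 0.05; no multiple-testing correction is
applied by default, matching the per-pair decision rule, with a Bonferroni
option exposed.  Composite compartments (fused chromosomes) are split into
ancestry segments before counting.

## Ancestral gene order (CARs)

Each genome's chromosome order, restricted to orthogroup members
(single-genome orthogroups and copies displaced relative to their group's
compartment are dropped; intervening non-ancestral genes are skipped),
yields adjacency observations; a genome supports an adjacency at most
once, and orientation-mismatched support counts 0.5.  An adjacency is an
ancestral candidate only with root-spanning support (>= 1 genome in each
clade).  Candidates are linearized into contiguous ancestral regions
(CARs): maximum-weight edge selection under degree <= 2 and acyclicity,
exact (branch and bound) within conflict components of <= 15 edges and
greedy beyond, followed by a repair pass (endpoint joins plus bounded
splice moves accepted when they lower (path count, -weight)
lexicographically).  The repair matters: greedy selection maximises
weight, not contiguity, and can strand a segment when a segment-skipping
adjacency outweighs the segment's boundary edges (which happens around
subgenome-specific inversion breakpoints).  This is a deliberate
simplification of consecutive-ones/PQ-tree ancestral-genome machinery:
adjacency voting plus path-constrained selection is fully specifiable and
oracle-checkable at small scale.

The pre-duplication order uses *retained* duplicate pairs only - shuffled
pairs sit at nonsyntenic positions and would bridge unrelated CARs (this
is visible in simulation: pre-speciation transpositions are shared by all
genomes and look root-spanning).  Duplicate pairs are folded onto a
canonical ancestral gene; adjacency votes come from every genome and both
subgenome copies, so a deletion break on one side is bridged by its
sister; votes below weight 2 are discarded, which removes single-genome
junctions created by lineage-specific chromosome fusions.  Merged paths
with >= 2 genes are reported as pre-WGD CARs, the deeper (depth 2) repair
being enabled here because breakpoint conflicts of ancestral inversions
need two coordinated splices.

## Karyotype scenarios

The scenario engine replays candidate ancestors through WGD, centromeric
fusion (CCF), telomeric fusion (TCF), fission and translocation events
with two invariants: fusions leave exactly one functional centromere
(functional monocentric neochromosomes; TCF is treated the same way, a
choice this package makes explicit), and dominance follows the algebra
D + D = D (supradominant), D + S = D, S + S = S, with no path back from
sensitive to dominant.  Centromeric fission leaves both products with
nonfunctional (partially deleted) centromeres; an arm fission keeps the
parent centromere and yields an acentric fragment that must be rejoined by
translocation.  Violations collected against the observed post-WGD
karyotype: R-a terminal chromosome without a functional centromere,
R-b broken fusion algebra or a WGD pair not labelled one D / one S,
R-c an ancestrally sensitive chromosome observed dominant,
R-d terminal dominance or segment composition contradicting observation.
Scenarios are ranked by (violations, fissions + fusions, ancestor
chromosome count descending).

Five candidate scenarios (n = 5, 5, 7, 6, 6) ship as packaged fixtures.
In the n = 7 fixture the ancestral A3-A12 translocation is encoded as an
arm fission of A12 plus a translocation join of the fragment onto A3; the
narrative does not tie its single fission to a named chromosome, so this
placement is interpretive (flagged in the fixture), and it is what makes
the bookkeeping (one fission, two fusions, final count 12, all functional
centromeres) consistent.  The n = 5 fission-and-fusion fixture uses five
fissions and three fusions, the counting under which the published 5/3
totals are consistent.

## The simulator and what it does (not) emulate

The generator builds an ancestor of 7 protochromosomes x 200 protogenes on
a uniform 10 kb grid (gene length gamma-distributed around 3 kb, exon
counts 1 + Poisson(7.6), one functional centromere per chromosome),
applies a shared WGD at 60 Ma assigning one dominant and one sensitive
copy per chromosome pair, and descends the dated tree
((rice:40, brachypodium:40):10, (sorghum:40, maize:40):10) with a
maize-specific WGD at 5 Ma.  Per-branch events, applied in time order:

* gene deletion, per gene per Myr: 8e-4 (D copies) and 1.6e-3 (S copies) -
  the bias ratio 2 encodes dominance;
* transposition, 8e-4 per gene per Myr; cluster sizes drawn from
  {1: 0.996, 2-4: 0.00134 each}, so about 12 per mil of moved genes travel
  in clusters of two to four; an `ssd_mode` variant duplicates then
  deletes the source copy instead of moving it;
* inversions 0.08, tandem duplications 0.05 and segmental deletions
  (2-6 genes) 0.03 per genome per Myr;
* planned chromosome fusions: two CCFs on the brachypodium branch, two
  CCFs and one TCF on the maize branch after its WGD.

Absolute erosion rates are scaled down relative to real grass genomes
(where roughly 60% of duplicates are deleted over 60 Myr): at realistic
erosion the adjacency signal among four genomes becomes too sparse for
order reconstruction at this genome size, which is also why real studies
order only a minority of protogenes.  The scaled rates preserve every
phenomenon (biased fractionation, shuffling, fusions, neopolyploidy) at
magnitudes where recovery can be demanded of the method, so passing tests
demonstrate correctness of the inference chain, not that real genomes are
this easy.  Randomness flows from one root seed; per-lineage child streams
are derived by hashing the lineage name, so outputs are byte-identical for
a fixed configuration and seed.

Dating inputs are emitted either as a Ks table (Ks = 2 r T with
multiplicative log-normal noise, sd 0.08 on the ln scale, which produces
unimodal per-WGD peaks) plus BLAST-style identities decreasing linearly
with age, or as codon FASTA whose third positions evolve under a
Jukes-Cantor clock at rate r along the true genealogy.  Simulated codons
use fourfold-degenerate families without first-position synonymy, so every
codon carries exactly one synonymous site and realized NG86 Ks equals
2 r T in expectation.  Not modelled: transposable elements, non-coding
sequence, gene conversion, selection, codon usage bias, and WGDs on
internal branches other than the root stem.

After a second (maize) WGD an ancient pair has up to four surviving
copies, so "the pair" is ill-defined; truth-recovery therefore pools
shared-WGD pairs of the three single-WGD genomes with maize's recent
pairs.

## Problem sizes and runtime

The default end-to-end analysis uses 4 genomes x 1,400 protogenes
(roughly 2,500-5,200 genes per genome), about 110,000 HSP rows and
11,000 paralog pairs, and completes in well under a minute on one core.
Statistical calibrations use 2,000 replicates (type-I error), 200
replicates (label recovery) and 100 seeded mixture fits of n = 1,000.
Oracle comparisons run on 100 instances of <= 15 anchors (chaining), 50
random 100-codon pairs (NG86) and 40 small path-cover instances
(linearization).

## Known limitations

* The chi-square dominance test at the default simulation's scaled-down
  erosion has little power per compartment pair; dominance calibration is
  therefore demonstrated on purpose-built replicates, not on the default
  end-to-end run.
* Mixture fits on whole-genome paralog sets include tandem/background
  duplications, which can add a low-Ks component beyond the WGD peaks.
* The CAR linearizer is a heuristic; the repair pass removes the common
  selection artefacts but global optimality is only guaranteed for small
  conflict components.
* Orthogroups come from reciprocal best hits; lineage-specific duplicates
  that outcompete the true ortholog can displace a group member, which the
  compartment-consistency filter only partially corrects.
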