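# Methods

`chlorocomp` re-implements a comparative-genomics workflow for chloroviruses
(genus *Chlorovirus*, family *Phycodnaviridae*): large dsDNA viruses whose
isolates fall into three host groups named after the chlorella-like algal
strains they infect (NC64A, Pbi, SAG).  The pipeline builds ortholog protein
families across a set of annotated genomes, classifies families by their
presence/absence pattern, reconstructs the gene repertoire of the last
common ancestor by a two-clade parsimony rule, screens every ORF for
compositional evidence of recent horizontal acquisition, and quantifies
gene-order colinearity.  A synthetic-genome generator supplies ground truth
for every stage, so the whole pipeline is testable without downloads.

## Ortholog families

Putative ortholog pairs are cross-genome **reciprocal best hits** (RBH):
protein *a* in genome A and *b* in genome B form a pair when each is the
other's best-scoring match in the partner genome.  Pairs are assembled into
clusters by **single linkage**, i.e. clusters are the connected components
of the RBH graph.  Within-genome duplicates (**in-paralogs**) join an
existing cluster when their alignment score with some member *m* exceeds
every score between *m* and the other cluster members; with several
qualifying clusters the largest margin wins.  Remaining proteins are
singletons.  Together clusters and singletons partition the proteome.

Numerical choices:

* The best-hit metric is the local alignment score (bit score for imported
  hits).  The internal engine is Smith–Waterman (BLOSUM62, gap open −11,
  extend −1) via Biopython's `PairwiseAligner`, with a Karlin–Altschul-style
  e-value (λ = 0.267, K = 0.041, the standard gapped BLOSUM62 constants);
  hits with e ≥ 1e−5 are discarded.  The same threshold filters imported
  12-column tabular hits (BLAST `outfmt 6` dialect), where multiple HSPs
  per pair collapse to the best-scoring one.
* Best-hit ties break by higher score, lower e-value, longer alignment,
  then lexicographic subject id, making results input-order invariant.
* The in-paralog rule is evaluated for every candidate against the
  *original* cluster memberships; a sequential variant (assigned candidates
  enlarging clusters seen by later candidates) is order-dependent and was
  rejected for that reason.
* Genomes can be marked as outgroup: their proteins participate in
  clustering (to polarise downstream analyses) but never appear as focal
  singletons.

## Family classification and ancestral repertoire

With families counted per genome (`FamilyMatrix`), each family receives
exactly one label: **core** (present in every genome), **host-specific:g**
(present in all genomes of group *g*, absent elsewhere), **opposite:g**
(absent from all of *g*, present in all others), **singleton** (one member
overall), or **scattered** (everything else).  Labels are pattern-based, so
a family designed as "scattered" in a simulation can legitimately classify
as opposite if its random presence set happens to complement one group.

A family is flagged **ancestral** when it has at least one member in an
NC64A genome and at least one member in a Pbi or SAG genome — the deepest
split of the virus phylogeny, so presence on both sides is parsimony
evidence for presence in the last common ancestor.  Families supported by
external phylogenetic evidence (e.g. sister groups to homologs in other
nucleocytoplasmic large DNA viruses) can be added through an explicit input
list; reading such trees is manual work and out of scope.  Consequences
asserted as properties: core ⊆ ancestral, and the flag is monotone (adding
members never clears it).

**ORFan status** (no detectable homolog outside the genus) requires
external database searches and is consumed as a boolean input column, never
computed.

### ORFan chance null

The null asks how many ORFs longer than a floor (default 300 bp) arise by
chance in a genome's unconstrained sequence.  Per replicate, the sequence
lying *between* the non-ORFan genes (intergenic DNA plus the spans of
ORFan-flagged genes) is shuffled as a single mononucleotide pool and
written back into the same spans; the six frames of the rebuilt genome are
scanned and ATG-initiated, stop-terminated ORFs above the floor that fall
entirely outside the non-ORFan gene spans are counted.  The published
procedure admits several readings; this one is adopted because shuffling
the coding sequence itself while counting only outside gene spans would
make the shuffle irrelevant, and because gene-dense genomes then yield the
small chance counts (≪ number of observed long ORFans) that make the null
informative.  Surfaced assumptions: mononucleotide shuffle unit, ATG starts
required, nested ORFs each counted, both strands scanned.  The counter's
expectation on i.i.d. sequence has the closed form
n<sub>codons</sub> · p<sub>ATG</sub> · (1 − p<sub>stop</sub>)^(L/3) per
frame-strand, which the tests verify by simulation.

## Compositional deviation index (CDI)

Each genome's vertically inherited coding sequence is summarised by a
non-homogeneous Markov chain of order k (default 5): an initial
distribution P⁰ over the first k-tuple of an ORF and three transition
matrices P¹, P², P³ giving P(next nucleotide | preceding k-tuple), the
matrix chosen by the codon position (1, 2, 3) of the tuple's first
nucleotide.  Conditioning on reading-frame phase captures the periodic
structure of coding DNA.  Training counts k-tuples and (k+1)-tuples per
frame over all ancestral ORFs of one genome; transitions are
(N(j,i,f) + α) / (N(j,f) + 4α).

An ORF scores log P(ORF | model) = log P⁰(first k-tuple) + Σ log
P^f(next | context), the ORF assumed to start at codon position 1.  The
CDI standardises that likelihood against n_rand (default 100) random
coding sequences *emitted from the model* at the ORF's exact length:

    CDI = (log P(ORF) − mean log P(random)) / SD(log P(random))

Native-composition ORFs centre on 0; compositionally deviant ORFs — the
signature of recent horizontal transfer from a donor with different
nucleotide bias — fall in the tails, the left tail being the HGT-like
direction on synthetic evidence.  Reporting is two-sided.

Numerical and design choices:

* **All arithmetic in log space.**  The raw product of per-nucleotide
  probabilities underflows for any realistic ORF; standardising
  log-likelihoods preserves the expected-zero calibration and is the only
  numerically viable formulation.
* **Pseudocount α = 0.5** per (tuple, nucleotide) cell.  At k = 5 there are
  3 × 4⁵ contexts; a genome's ancestral ORFs (~10⁵ training tuples) leave
  unseen contexts whose zero probability would send alien ORFs to −∞.
* **Frame convention**: the initial k-tuple starts at codon position 1; f
  is the codon position of the context's first nucleotide, cycling 1→2→3.
* **One model per genome**, trained only on that genome's ancestral ORFs;
  each ORF is scored with its own genome's model.
* ORFs shorter than k+1 usable nucleotides yield an explicit null result
  (`too_short`); windows containing ambiguity codes contribute 0 to the
  log-sum; a degenerate null (SD numerically 0) is flagged, not divided by.
* Training sets far below ~10·4^(k+1) nucleotides trigger a warning: with
  sparse training the model memorises its own training k-mers and real
  genes then score systematically *above* model-emitted sequences (the
  smoothed model spreads mass over unseen contexts).  The index stays
  useful for ranking, but absolute calibration (mean ≈ 0) requires
  adequate training, as in a full ~300-gene viral genome.
* Group contrasts use a Kruskal–Wallis omnibus plus all pairwise two-sided
  Mann–Whitney tests with Holm family-wise correction (the
  Steel–Dwass–Critchlow–Fligner procedure is not available in the
  supported stack; Holm-corrected pairwise rank tests are the standard
  conservative substitute), and a named long (>300 bp) vs short ORFan
  contrast.

## Colinearity

Dot-plots use **gene rank** (order index), not nucleotide coordinates, so
a block length is a gene count.  Matches carry orientation (product of the
two genes' strands) and a mutual-best flag.  **Colinear blocks** are
maximal monotone chains of matches — rank strictly increasing on both axes
(same-direction) or increasing on one and decreasing on the other
(inverted) — with consecutive rank gaps of at most `max_gap` intervening
genes (default 3; the published block statistic states no gap tolerance,
so the parameter is exposed).  Blocks are extracted greedily, longest
first, by an O(n²) longest-chain dynamic programme.

**Contig ordering** anchors each assembly contig by its genes' mutual best
hits in a reference: placement is the median reference rank of the
anchors, orientation the majority strand agreement, ties broken by contig
length then id; unanchored contigs are appended last and flagged, and an
assembly with no anchors at all is returned unchanged with a warning.  The
operation is idempotent.

## Synthetic data generator

The generator emulates the structure the analysis is designed to detect:

* **Host groups** with group-specific GC (defaults 40/45/49 %GC mirroring
  NC64A/Pbi/SAG) — each group's genomes share a codon-composition model.
* **Families** with designed categories (core, group-specific, opposite,
  scattered, singleton) and optional copy number (in-paralogs, derived
  with extra substitutions).  Each family has one ancestor protein
  (uniform-random residues, initial Met fixed); members derive from it by
  per-site substitution (default 0.10 per genome), keeping within-family
  identity high enough for RBH recovery while between-family identity
  stays at random background.
* **Back-translation** through a codon table parameterised only by a
  nucleotide GC bias θ, calibrated by root-finding so the *expected coding*
  GC equals the group target (achievable coding GC under uniform amino-acid
  usage spans roughly 0.30–0.63 — the genetic code bounds it).  The
  downstream signal is nucleotide composition, not codon optimality, so no
  organismal codon table is imposed.  Intergenic spacers (20–200 bp) are
  i.i.d. at the genomic GC target.
* **Alien genes**: a designed fraction of each genome's genes is
  back-translated through a compositionally offset model (default +10 GC
  points) — they keep their family membership, as HGT-acquired orthologs
  would, and are flagged in the truth tables as the detection ground truth.
* **Gene order**: one family permutation per group (shuffled between
  groups), each genome optionally applying segment inversions; per-(group,
  family) strands are conserved within a group.  Gene lengths are
  log-normal, truncated to 60–2000 codons (the 60-codon floor matches the
  ORF-calling convention for these genomes).
* **Determinism**: all randomness flows from the single design seed through
  named `numpy` SeedSequence substreams (plan / ancestors / order / one per
  genome); identical designs give byte-identical output files.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: realistic phylogenetic branch lengths or
rate heterogeneity (substitutions are i.i.d. per site), amino-acid
composition bias, codon usage beyond GC, repeats and assembly gaps,
tRNA genes, and donor compositions more exotic than a GC shift.  Exact
family recovery on synthetic designs bounds implementation correctness,
not the biological error rate of RBH clustering on diverged proteomes.

## Problem sizes in the shipped tests

The default suite runs the full pipeline on small designs (≤ 6 genomes ×
~24 families), CDI calibration on 500 model-emitted ORFs of 999 nt with
100 randomisations each, alien-recovery runs of 200 genes per offset, and
brute-force oracle comparisons on 200 random instances per operation —
sizes chosen so each stage's statistical check is well-powered while the
suite stays interactive.  Full-scale statistics for the 41-genome
collection (531 multi-member clusters, 155 core, 290 ancestral families,
64% DNA-polymerase identity between the most divergent pair) need the
deposited accessions and an external aligner; they are tracked in
`chlorocomp.benchmarks` with a ±5% relative tolerance and a local runner,
not asserted in unit tests.

## Known limitations

* The Karlin–Altschul e-value uses fixed gapped-BLOSUM62 constants and a
  per-pair m×n search space; it approximates, but does not reproduce,
  BLAST's composition-adjusted statistics.
* Ancestral reconstruction is the two-clade presence rule only — no
  Dollo/ML gain–loss model over a tree.
* The CDI detects *recent* acquisitions from compositionally distinct
  donors; transfers from similar donors or ancient, ameliorated transfers
  are invisible by construction.
* Greedy longest-first block extraction does not guarantee a globally
  optimal block partition (the longest single block, which is the reported
  statistic, is exact).
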