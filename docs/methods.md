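# Methods

This note documents the models and procedures implemented in `mitokit`, the
parameters that matter, what the synthetic data generator does and does not
emulate, and the design choices made where the design was genuinely open.  No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Read baiting (recruitment)

The recruitment stage models how organelle reads are fished out of a
whole-genome long-read pool.

*Candidate selection.* A read qualifies if it shares an alignment block
strictly longer than 50 bp with any core-gene bait sequence.  Blocks are found
by (k=11, w=5) minimizer matching, diagonal clustering (band 200 bp, ≥ 3
shared minimizers), exact base-wise extension of the chain bounds, and a
global edlib alignment for identity.  An identity floor of 0.70 on candidate
blocks suppresses chance minimizer chains; a genuine core-gene fragment on a
10 %-error read aligns near 0.90.

*Seed ranking.* Candidates are ordered lexicographically by (distinct genes
hit, mean covered fraction of each hit gene), ties broken by read length then
id, and the top `n_seeds` (default 10; the upstream procedure does not state a
count) become the initial recruited set.

*Iteration.* Each round, every unrecruited read with a dovetail overlap of at
least `min_overlap` = 1000 bp at `min_identity` = 0.70 against any recruited
read is added; additions are batched per round, so the final set is
independent of read order; the loop stops at the first round adding nothing
(the reported round count includes that empty round).  Read-vs-read overlaps
use (k=15, w=10) minimizers; the best diagonal is extended to the sequence
ends (dovetail semantics — the overlap contract of assembly), and identity is
edlib distance over the aligned block.  "70 % similarity" is interpreted as
alignment identity over the overlap block; the definition is a documented
choice, not a claim about any external mapper's gap-compressed identity.

Costs: recruitment maintains one global minimizer index over unrecruited
reads, so each round touches only reads sharing minimizers with the newest
recruits; the default 4,000-read pool completes in well under a minute.

## C→U editing classification

Edit sites are inputs (gene, 1-based CDS position); site prediction is a
separate problem and out of scope.  Applying sites validates that every
reference base is C and flips it to T.  Codon changes are classified by the
hydropathy transition of the encoded residue under the standard genetic code:

* hydrophobic: A V L I P F M W
* hydrophilic: R N D C Q E H K S T Y G
* stop: its own class

C and T sit in the hydrophilic class because organelle editing tables
classify R→C transitions as hydrophilic→hydrophilic and T→I/M as
hydrophilic→hydrophobic; G never occurs as a source or target in the bundled
census and is assigned hydrophilic by the sign of its Kyte–Doolittle index
(`set_glycine_class` reassigns it).  A codon edited at positions 1 and 2
simultaneously counts as one site with `positions_edited = {1, 2}`.  The
bundled table `data/forsythia_mt_edit_types.tsv` carries the observed
edit-type counts of the *Forsythia suspensa* mitochondrial genome (460 sites,
30 codon-change types); the summarizer reproduces its printed class counts,
percentages, codon-position split and target-residue spectrum exactly, which
the acceptance suite asserts.

Stop gains (an edited codon becoming TAA/TAG/TGA before the terminal codon)
and start creation (codon 1 ACG→ATG) are reported separately, since both
readings of "premature termination" circulate: stop-gain edits and
already-annotated edited stops.

## RSCU

RSCU_c = n_c·k/Σ n_{c'} within each synonym family.  Families default to the
standard code with methionine and tryptophan as singletons and stop codons
excluded (both configurable).  Counting uses unique CDS — exact-sequence
deduplication, mirroring the "choose one copy of multi-copy CDS" convention —
and drops the terminal stop.  A `met_family` mode groups ATG/CTG/TTG into one
three-codon family, a convention some organelle reports use for start codons;
it is not the default.  Within any family with nonzero usage the values
average to exactly 1 (asserted as a property).

## Repeat mining

*SSRs.*  Maximal perfect runs with unit length 1–6 and MISA's canonical
minimum copy numbers {1:10, 2:5, 3:4, 4:3, 5:3, 6:3}.  A run is reported at
its primitive (non-self-periodic) motif only, canonicalized to the
lexicographically minimal rotation; composite/interrupted SSRs are not merged
(each perfect run stands alone).  Detection is vectorized (positions equal to
the base one period earlier); on circular genomes a short tail prefix makes
backward-maximality circular and a pad lets runs cross the origin.  The
detector is asserted equal to a naive maximal-run enumerator on random 5 kb
instances.

*Tandem repeats.*  The probabilistic matching model of the classical tandem
finder is replaced by a deterministic equivalent with the same weights:
candidate periods d ∈ [2, 2000] come from stretches matching the sequence d
earlier (true-runs merged across gaps ≤ max(2, d/5), density ≥ 0.8, length ≥
2d); each region is scored column-wise against its majority-rule consensus at
match +2 / mismatch −7 with minimum score 50, after a max-score trim of region
ends (boundary bases that cost more than they contribute are dropped, so exact
planted repeats come back with percent_match = 100).  Candidate detection is
substitution-level; the indel weight of the classical parameter set is kept in
the signature for report parity but no gapped consensus alignment is
attempted — the planted-repeat contract of the generator is substitution
divergence.

*Dispersed repeats.*  Exact 7-mer seeds extended ungapped with X-drop 12 at
match +1 / mismatch −3 (blastn-like; crossing a repeat boundary needs three
chance matches per mismatch, so planted bounds are recovered within a few
bases, while homology down to ~25 % divergence still has positive expected
score).  Four comparisons give the four orientation classes: genome vs itself
(forward), vs reverse complement (palindromic), vs reverse (reverse), vs
complement (complement).  Pairs whose copies overlap each other are
tandem-like and dropped; pairs where either copy overlaps an SSR/tandem
interval by more than half its length are removed; symmetric duplicates are
canonicalized away.  E-values are replaced by the (length ≥ 30, identity ≥
0.80) filter — e-values depend on database-size conventions that are not
pinned down here.

## Plastid transfer (MTPT)

The same seed-and-extend engine with word size 11 runs between two genomes on
both strands; accepted fragments (≥ 30 bp, ≥ 70 % identity) are re-aligned
globally with edlib to count mismatches and gap openings, and carry an
`evalue_proxy` (Karlin–Altschul shape with blastn-like constants) used only
for ordering parity, not as a calibrated e-value.  Donor-side coordinates are
1-based inclusive with start > end encoding the minus strand, the convention
of tabular homology reports.  Gene coverage merges fragment intervals first so
inverted-repeat duplicates do not double count.  The transferred fraction
defaults to the plain sum of fragment lengths over the genome length — the
arithmetic printed homology tables use — with the union-based figure reported
alongside.

## Ka/Ks and Pi

*NG86.*  Synonymous sites per codon are the synonymous fraction of the nine
single-base changes (changes to stop codons count as nonsynonymous), averaged
over the two sequences; sites_n + sites_s = 3·codons exactly.  Multi-hit
codons average over all orderings of the differing positions, excluding
pathways through stop codons unless every pathway is blocked.  Proportions are
Jukes–Cantor corrected; p ≥ 3/4 or Ks = 0 yield missing values, mapped to the
"undetermined" selection class.

*MLWL.*  Positions are classed nondegenerate / two-fold / four-fold by their
synonymous-change count (0 / 1–2 / 3); transitions and transversions are
tallied per class (half-weight to each sequence's class when they disagree)
and corrected per class with Kimura's two-parameter formula (A_i transitional,
B_i transversional).  Two-fold sites are apportioned κ/(κ+2) synonymous and
2/(κ+2) nonsynonymous with κ = 2·A4/B4 estimated from four-fold sites
(κ = 1 recovers the original LWL85 1/3 : 2/3 weighting; the argument is
exposed).  The arginine-codon special-casing of the published calculator is
not reproduced; nothing numeric in this package depends on it, and NG86 is
retained as the oracle-friendly reference.

*Pi.*  Mean pairwise differences per site over C(n,2) pairs with complete
deletion of gap/N columns (the convention of the standard diversity tool;
pairwise deletion available by flag).  Note this estimator is not invariant
under duplicating the whole sequence set — it rescales by 4·C(n,2)/C(2n,2) —
and the tests assert that exact factor.

*Alignment.*  Sequences must arrive aligned; a codon-aware gap-strip utility
is provided instead of re-implementing multiple alignment.

## Synthetic data generator

The generator emulates the study conditions at desk scale: a circular 60 kb
mitogenome at GC 0.449, a 20 kb circular plastid donor (GC 0.38), and a 200 kb
linear nuclear genome (GC 0.36) — about a tenth of real plant organelle
sizes, preserving every threshold relationship (50 bp candidate blocks, 1 kb
overlaps, 30 bp fragments).  Defaults plant:

* 15 single-copy coding genes (12.8 kb coding; realistic plant-mt lengths,
  one minus-strand subset, multi-exon genes with 120 bp introns, one gene
  spanning the origin, one ACG start, one TTG start) — these double as the
  core-gene bait set, since the published bait collection is an external
  resource and the baits only need to be the genome's own conserved genes;
* 14 SSRs across unit lengths 1–6, all at or above MISA thresholds;
* 2 tandem repeats (20 bp × 4 exact; 12 bp × 5 with one substitution);
* 13 dispersed repeats, 7 palindromic / 6 forward, 40–250 bp — the two
  classes the study system shows; reverse/complement classes are exercised by
  tests through explicit configs;
* 16 verbatim plastid insertions of 30–370 bp totalling 2,350 bp (3.92 % of
  the genome), the MTPT ground truth — sub-kilobase fragments, the size
  regime such insertions occupy at this scale;
* 3 numt-like segments: 2 kb of mitochondrial backbone copied into the
  nuclear genome at 80 % identity (substitutions only).  These are the
  realistic false-positive source for recruitment: at the 70 % identity
  threshold, numt reads (pairwise read identity ≈ 0.8 × 0.81 ≈ 0.65) stay
  out; relaxing the threshold lets them flood in, which is exactly the
  precision-degradation trend the tests assert;
* 3 edit sites per gene at codon positions 1–2 of C bases, plus 2
  dual-position (CC→TT) codons.

Reads: 4,000 per pool (≈10× mitochondrial coverage at the 5 % mixture —
enough that the 1 kb-overlap read graph is connected, as a quality-filtered
long-read run would be), mixture 5 / 15 / 80 % mito/plastid/nuclear, lengths
1,500 + Gamma(shape 3) around a 3,000 bp mean (the floor models long-read
length filtering; reads shorter than the 1 kb overlap threshold could never
be recruited and would only measure the generator, not the method), uniform
errors at 10 % in a 3:1 substitution:indel ratio, strands flipped at random,
circular genomes sampled across the origin.

*Sanitization.*  A random 60 kb backbone contains a couple of chance
microsatellite runs at MISA thresholds; the generator breaks them (and any
run created at a planting junction) with single-base edits, places guard
bases so planted runs cannot extend into the backbone, and re-draws gene/
repeat content that happens to contain runs.  Manifest tallies are therefore
exact by construction, and `TruthManifest.validate` re-reads every feature
from the emitted sequence.  All randomness flows through one seeded
generator; the same seed gives byte-identical output.

*What is not emulated:*  homopolymer-biased nanopore error profiles (errors
are uniform; the recruitment criteria depend only on block length and
identity), gene expression/annotation signal (baits are known sequences, not
predictions), indel divergence in planted homologs, multi-copy genes in the
default genome (they would be their own dispersed repeats and are covered by
unit tests instead), and rearrangement/recombination structure.  Passing
tests therefore demonstrate threshold-level correctness of the detectors and
the recruitment loop, not robustness to every real-data pathology.

*Divergent CDS pairs.*  `make_divergent_pair` plants at most one substitution
per codon, rejecting stop-creating changes, until reaching a synonymous
budget of `ks_target` per NG86 synonymous site (uncorrected proportion) and a
nonsynonymous budget of `omega_target × ks_target` per nonsynonymous site;
realized counts are returned for oracle checks.  Unattainable budgets raise.

## Numerical and reporting conventions

Intervals are 0-based half-open internally and 1-based inclusive in all
user-facing tables; circular coordinates wrap modulo the genome length.  GC
excludes N from the denominator; all report percentages round to 2 decimals.
Gene-table amino-acid columns follow the convention that a stop-terminated
CDS of n bases encodes n/3 − 1 residues, while a coding length printed
without its stop encodes n/3; `protein_length` detects the terminal stop and
handles both.  Selection classes use a 1e-9 tolerance around ω = 1.
Pseudogenes carry no coding contract and are skipped with a warning.

## Problem sizes

The shipped analyses and acceptance script run the full pipeline at the
desk-scale defaults above (60/20/200 kb genomes, 4,000 reads, 500-codon Ka/Ks
pairs, 20 replicates per planted ω); the whole acceptance computation takes
about half a minute on one CPU, and the test suite about two minutes.

## Known limitations

The overlapper is a minimizer chainer, not a full aligner: overlaps below
~200 bp of anchored homology at high error rates can be missed, and identity
is computed on the dovetail-extended block, which dilutes contained homology
with flanking sequence (a property the recruitment thresholds exploit).  The
tandem finder does not model indel'd copies.  The dispersed-repeat and
homology detectors are ungapped at the extension stage; diverged homology
with indels fragments into multiple collinear pieces (visible with the numt
segments).  MLWL omits the arginine special cases.  E-value semantics are
deliberately replaced by explicit length/identity thresholds.
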