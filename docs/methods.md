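# Methods

## Problem and data model

The package delimits species from pre-aligned multi-locus barcode data:
one gapped FASTA alignment per locus (here an ITS1-5.8S-ITS2 nuclear
fragment and a COI mitochondrial fragment), a specimen-to-species
partition, and an optional map of alignment coordinates to gene regions.
All coordinates a user sees are 1-based inclusive.  The residue alphabet
is `A C G T`, the gap `-`, and the IUPAC ambiguity codes (incl. `N`);
ambiguity codes are treated as missing data everywhere — they never match
a state, never fix a species, and never exclude a non-member.  This is a
deliberately conservative choice: an ambiguous read must not manufacture
a diagnostic character, and must block one it cannot confirm.

## Statistics

*Haplotype collapsing* runs in two modes: indel-aware (rows compared as
full strings, so an insertion haplotype is distinct) and
substitutions-only (columns containing any gap dropped first).
*Haplotype diversity* is Nei's unbiased estimator h = n/(n−1)(1 − Σ pᵢ²).
*Nucleotide diversity* π is the mean over unordered pairs of
(differences / comparable sites); with the default `indels=exclude`, a
site with a gap in either sequence of a pair is skipped, so indel-only
variation yields π = 0 exactly.  *Site classification* calls a column
variable (segregating) when ≥ 2 determinate states are observed and
parsimony-informative when ≥ 2 states each occur in ≥ 2 sequences.  The
default gap policy excludes any gap-bearing column from these counts
(such columns carry alignment rather than substitution signal, and the
motivating data's intraspecific variation is entirely indel-borne);
`fifth-state` is available as an explicit flag for sensitivity analysis.

## Divergence

The uncorrected p-distance uses pairwise deletion by default (a site
counts only when both residues are determinate); complete deletion masks
every column containing a gap or ambiguity first.  Which convention a
published table used is often unstated, so both are exposed and the
comparable-site count per pair is kept in the matrix metadata.  JC69 and
K2P corrections are closed-form on the mismatch (and
transition/transversion) proportions and raise a named error when the
logarithm argument is non-positive.  Percent tables round half away from
zero to three decimals, the convention of published divergence tables;
composite-likelihood distances are intentionally not implemented — at the
sub-2% divergences this pipeline targets, tree topology is insensitive to
the distance model, and p/JC69/K2P cover the standard choices.

## Character-based diagnosis

A pure diagnostic character for species S is a position whose state is
fixed (strictly: shared by every member, determinate) in S and carried by
no specimen outside S.  A composite diagnostic combination is a set of
positions, each fixed in S but not individually diagnostic, whose joint
states occur in no single outside specimen.  The finder enumerates
candidate subsets by increasing cardinality and stops at the first
cardinality with a hit, which guarantees minimality: a working proper
subset would have been found earlier, and a working singleton would be a
pure diagnostic, which is excluded from the candidate pool.  Candidates
are further restricted to columns that at least one non-member fails to
match; a column matched by every non-member can never appear in a minimal
set, which keeps the combinatorial search small on realistic alignments.
Missing residues in non-members are treated as possible matches, so they
block exclusivity (the conservative direction).  Species represented by a
single specimen satisfy fixation trivially; the text report flags them as
provisionally diagnostic.  Loci are diagnosed independently and merged in
the report; composite sets never span loci.

## Phylogenetics

Neighbor-joining follows Saitou–Nei with the standard Q criterion.  Two
determinism contracts are imposed: ties on Q are broken by the
lexicographically smallest pair of cluster representatives (a cluster's
representative is its smallest member label), and Q is minimised over the
upper triangle only, because floating-point summation order can make
Q[i,j] and Q[j,i] differ by one ulp.  Negative branch-length estimates
are clamped to zero with the deficit moved to the sister edge — standard
practice that changes printed lengths, never topology.  The bootstrap
resamples columns with replacement under a caller-supplied seed
(`numpy.random.default_rng`; no hidden global state), recomputes the
distance matrix and NJ tree per pseudo-replicate, and reports each
bipartition's support as the percentage of successful replicates
containing it, mapped onto the full-data NJ tree (a majority-rule
consensus presentation is not implemented).  Replicates in which some
pair has zero comparable sites are discarded and counted, with a warning
above 1%.

Parsimony length is Fitch's count of state-set intersections failing on a
postorder pass; gaps default to missing data (union of all states at the
leaf, zero cost), matching common maximum-parsimony practice, with
`fifth-state` optional.  The exact search is branch and bound over the
standard taxon-insertion enumeration (taxa added in input order, each
insertion point visited in a fixed order, so every unrooted binary
topology is generated exactly once and the result ordering is
reproducible).  The bound is the best complete-tree length found so far;
partial trees are pruned only when they *exceed* it, so all co-optimal
topologies are retained.  A guard rail refuses more than 15 taxa —
heuristic search is out of scope.  Columns are compressed to weighted
site patterns before either computation.

Trees are `dendropy.Tree` objects; newick I/O goes through dendropy with
bootstrap supports as internal-node labels, underscores preserved and
spaced labels quoted.  A taxon set is monophyletic on an unrooted tree
iff it (or its complement) is one side of an internal-edge bipartition;
singletons and complements of singletons are trivially monophyletic.

## Synthetic data generator

The generator emulates the structure of the motivating data set and is
the package's primary validation instrument.  Per locus: a uniform random
root sequence; species haplotypes derived by planting substitutions;
specimens copy their species haplotype; intraspecific variation enters
only through indel insertions (a run of columns gapped in every specimen
except a carrier subset of one species).  Substitution positions are
sampled without replacement, so pairwise substitution counts — and hence
expected p-distances k/L — are exact integers, not expectations.  The
per-pair substitution budget is star-decomposed into per-species private
counts (k_ab = x_a + x_b; infeasible maps raise before any file is
written).  Planted composite-only combinations share each member state
with another species (at least two distinct partners per set) so that no
member is accidentally pure and no single non-member matches the whole
set.  Truth files are recomputed from the realized haplotypes by an
independent brute scan, and the whole generator is deterministic under
(spec, seed), with per-locus streams derived by CRC32 hashing of the
locus name.

The packaged three-species spec mirrors the motivating study's shape:
6/4/5 specimens; a 705 bp ITS-like locus with pair counts {2, 5, 5} over
the 695 columns comparable after a 10 bp insertion polymorphism in one
species (0.288% / 0.719% exactly), four planted pure diagnostics for one
species and one each for the others; and a 523 bp COI-like locus
invariant except for one site diagnostic for one species.  What the
generator does *not* emulate: substitution-model realism (no ts/tv bias,
no rate heterogeneity, no multiple hits), intragenomic rDNA
polymorphism, alignment error, or sequencing noise.  Passing tests
therefore demonstrate the correctness of the statistics and searches on
clean planted signal, not robustness to alignment-protocol choices —
on real data, site counts and distances shift with the aligner and
end-clipping rule used upstream.

On haplotype diversity: the insertion-carrier subset is drawn at random,
so h depends on the realized counts; under the default seed the insertion
is carried by 2 of 5 specimens, giving h = (5/4)(1 − (9+4)/25) = 0.60.  Published
two-haplotype values such as h = 0.67 correspond to counts 2:1 over n = 3
(4:1 over n = 5 gives 0.40); since the sample behind such a printed value
is often ambiguous, the package computes h from realized counts and does
not force any particular figure.

## Numerical and design choices

- Percent formatting: decimal half-away-from-zero, three digits.
- NJ final three-taxon star is solved by the closed three-point formulas,
  clamped at zero.
- Bootstrap support denominators use successful replicates.
- The integrative report is structure only: per species pair, four
  independent evidence lines (distance divergence above intraspecific
  variation, pure diagnostics, composite diagnostics, joint monophyly)
  each flagged supported / not supported.  No numeric score aggregates
  them — no defensible formula for that integration exists, so none is
  invented.
- Every pipeline output is hashed into `manifest.json`; a rerun of the
  same config and seed reproduces the bundle byte for byte.

## Known limitations

- The diagnosis finders assume strict fixation; population-style
  frequency thresholds (CAOS-like "private at ≥ x%") are not offered.
- Composite search cost grows combinatorially with the number of
  candidate columns; the `max_size` cap (default 6) and the
  informative-column filter keep realistic cases fast, but adversarial
  alignments with hundreds of species-fixed, partially shared columns
  can still be slow.
- Exact parsimony is limited to ≤ 15 taxa; no heuristic (SPR/TBR),
  likelihood or Bayesian methods are included.
- Bootstrap supports are Monte-Carlo estimates; only their seeded
  reproducibility, not their exact values, is guaranteed.
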