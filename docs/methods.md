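# Methods

This package implements a synteny-and-parsimony procedure for deciding
whether two paralogous genomic regions (paralogons) descend from a single
large-scale duplication in a common ancestor or from independent
lineage-specific duplications, together with the supporting supermatrix
phylogenetics and a sliding-window dN/dS screen. The worked example
throughout is the rhodopsin (*rho*) region of teleost fish: a deep-sea-type
and a freshwater-type copy in eel, two corresponding scaffolds in Asian
arowana, and a single ancestral-state region in spotted gar.

## Microsynteny matrices

The unit of evidence is a presence/order matrix over a reference gene panel
(here 11 genes, *lrig1*..*thoc7*, in spotted gar order). Each row is one
(species, synteny copy) region; each cell is present / absent / unknown,
with present genes carrying a rank (position along the region) and an
orientation relative to the reference. Rows are built by anchoring each
region's proteins to the reference panel by reciprocal best hits (RBH)
under local Smith–Waterman alignment with BLOSUM62 (gap open −11, extend
−1; identity = matches / aligned columns). At panel scale, where each
region carries at most one copy of each gene, RBH recovers the same anchors
a graph-clustering orthology method would; a panel gene anchored twice in
one region is rejected as a candidate tandem array, which is outside the
model. The default identity floor for anchors is 40%.

Order conservation of a row is the longest common subsequence (LCS) between
its present-gene order and the panel order; it equals the present-gene
count exactly when the observed order is a subsequence of the reference
order. Orientation does not enter the LCS — inversions change strand
agreement, not rank.

"Unknown" states handle assembly edges: a panel gene missing from a row is
recorded as unknown rather than absent when it lies beyond the outermost
present gene and its extrapolated position (terminal present gene plus one
median observed inter-gene gap per missing rank) falls off the region end.
This is off by default in extraction and on in the worked-example matrix,
where the panel-terminal gene *thoc7* is unknown on the eel copy-#2
scaffold because *atxn7* sits at the scaffold end.

## Dollo-parsimony scenario scoring

A candidate duplication scenario places one or more duplication events on
branches of a rooted species tree. Each placement doubles a contiguous
template interval of the panel into copy lineages #1/#2 within the clade
below the placement. The template defaults to the minimal duplicated
segment: the smallest contiguous panel interval containing every gene
observed on any copy-#2 row (8 genes, *magi1*..*atxn7*, in the worked
example). Genes outside the template were never doubled and contribute no
events; genes inside it but absent from all #2 rows are implied losses.

Scoring is Dollo: a gene copy arises once and can only be lost, and a
single loss event removes it from an entire descendant subtree. For each
(placement, copy lineage, template gene) the minimal number of clade-wide
losses consistent with the tip states is found by a post-order dynamic
program — each maximal subtree containing at least one observed absence and
no observed presence costs one event; unknown tips are unconstrained, which
automatically resolves them in the event-minimizing direction. The DP is
checked in the test suite against exhaustive minimization over all subsets
of loss branches. A scenario's total cost is its number of duplication
placements plus all losses; candidates are ranked ascending, ties broken by
fewer duplications (a genome duplication is a rarer event than a gene
loss), then input order.

On the worked-example matrix the single stem-duplication scenario costs 1
duplication + 5 losses = 6 events (shared ancestral losses of *pphln1* on
copy #1 and of *adamts9*, *slc2a9l1*, *psmd6* on copy #2, plus *rho* on the
arowana copy #2), while independent duplications in the two lineages cost
2 + 9 = 11. These totals are derived quantities, confirmed in the tests by
the exhaustive oracle rather than asserted from outside.

Two modelling notes. First, the shared-loss statistic (genes whose
two-copy pattern is identical in both species with exactly one absence) is
restricted to the duplicated template; genes outside it are single-copy by
inference and their copy-#2 "absence" is not a loss. Second, under this
template convention a single ancestral duplication can never score worse
than independent duplications for a two-species comparison — the parsimony
argument is exactly that the independent-duplication history pays a second
duplication while saving no losses. The Dollo-violation check covers the
one pattern losses cannot explain: a copy observed in a species outside
every placement's clade, which would require a regain.

## Supermatrix likelihood, tree search and RELL support

Alignments arrive pre-aligned (alignment inference is an input, not an
operation). Supermatrix preparation follows three steps: columns with gaps
in strictly more than half the OTUs are pruned; third codon positions are
included, RY-recoded (A,G→R; C,T→Y, discarding transition information), or
excluded; gene alignments are concatenated by OTU label with a per-column
partition map. These operations commute with concatenation, which the
property tests exercise.

Likelihood uses Felsenstein pruning with reversible models specified by
exchangeabilities and stationary frequencies (JC69, K2P, HKY, TN93, GTR; a
two-state model for RY columns; Poisson or file-supplied empirical
exchangeabilities for amino acids). Rate matrices are normalized to one
expected substitution per unit branch length; transition probabilities come
from the symmetric eigendecomposition. Among-site rate variation is a
discrete gamma with four equal-probability categories and mean-per-category
rates. Gaps and ambiguity codes are missing data (all-ones partials).
RY-recoded columns of a mixed supermatrix are scored under the binary model
with the same branch lengths, so transition-only differences at third
positions contribute nothing. Site patterns are compressed before
computation; no per-site scaling is applied, which is adequate at the
tens-of-taxa scale this package targets.

Branch lengths are optimized coordinate-wise (bounded Brent per branch,
sweeps to a 1e-6 lnL tolerance, 50-sweep cap with a warning on
non-convergence; the total lnL is non-decreasing across sweeps). Topology
search is hill climbing over nearest-neighbor interchanges (NNI) with
branch-length re-optimization of every candidate, accepting the best
strictly improving neighbor until a local optimum; polytomies in the start
tree are resolved randomly under the seed. Tests confirm that on five-taxon
data the search recovers the exhaustive best of all 15 topologies.

Branch support is RELL: per internal branch, the ML tree is compared
against its two NNI alternatives (alternative branch lengths re-optimized
once, then fixed); site log-likelihood vectors are bootstrap-resampled
(multinomial site weights) and support is the percent of replicates in
which the ML tree's resampled total is highest. Exact ties are broken
uniformly at random from the seeded stream, so trees with identical
site-likelihood vectors share support evenly (three identical vectors give
~33% each); a tree that dominates at every site gets 100%. Clade support
looks up the bipartition a taxon set induces; a set that is not a
bipartition of the tree reports "not present".

## Sliding-window dN/dS

The selection screen is Nei–Gojobori (1986) counting on a focal pair of
in-frame coding sequences: synonymous/nonsynonymous site counts per codon
(fraction of the three possible changes at each position that preserve the
amino acid, averaged over the two sequences), substitution counts averaged
over all shortest mutational pathways between differing codons, and
Jukes–Cantor correction d = −3/4 ln(1 − 4p/3), undefined at p ≥ 3/4.
Conventions: changes creating a stop codon count as nonsynonymous in site
counting, which keeps N + S = 3 × codon count exactly; pathways through
stop codons are excluded unless every pathway is blocked; codons with a gap
or ambiguity in either sequence are skipped. The scan slides a 25-codon
window in 5-codon steps; a trailing partial window is kept when it covers
at least half a window. Masking removes every codon column covered by any
window whose dN/dS exceeds a user-chosen threshold (no default threshold is
claimed); windows with undefined ratios can be flagged by a dN quantile
instead.

## Synthetic data

The generator emulates the assumed history: an ancestral segment of
`panel_size` genes (default 11) evolves down a species tree; at the
duplication branch (default: the eel+arowana stem, emulating the
teleost-specific genome duplication) the segment doubles; on every branch
at or below a duplication each surviving (gene, copy) is lost independently
with `loss_prob` (irreversibly, matching the Dollo assumption); with
`inversion_prob` per branch and copy a contiguous gene run is reversed and
strand-flipped; sequences evolve by a Goldman–Yang-style codon process
(kappa 2.0, uniform codon frequencies, per-gene rate multipliers uniform in
[0.5, 1.5]) with dN/dS `omega` defaulting to 0.2 — purifying selection
typical of conserved single-copy genes, which keeps outgroup–ingroup
protein identities in the ~75–90% range seen for this panel and makes RBH
anchoring behave as it does on real proteins. Setting `omega=None` falls
back to a plain HKY nucleotide process. Default branch lengths are 0.15
(eel), 0.15 (arowana), 0.08 (stem) and 0.2 (gar) neutral
substitutions/site; default `loss_prob` 0.2 per gene per branch
(the worked-example matrix realizes losses at roughly that rate) and
`inversion_prob` 0.1. Gene length defaults to 100 codons and intergenic
spacing is uniform in [500, 5000] bp — only midpoints and order matter
downstream. One seeded generator stream drives every draw, so outputs are
byte-reproducible.

What the generator does not emulate: assembly fragmentation (regions are
complete), tandem arrays, introns, unequal codon usage, rate variation
within genes, and gene conversion between copies. Passing recovery tests
therefore show that the inference chain is correct under its own model
assumptions, not that those assumptions hold for any particular genome.

The recovery experiment (100 seeded replicates at loss probability 0.3)
builds each replicate's presence matrix from the simulation truth and asks
whether scenario ranking puts the generating single-duplication scenario
strictly first; the pipeline-closure test separately verifies that RBH
anchoring plus matrix extraction reproduces the true presence/absence
pattern from the simulated sequences themselves.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to exercise every code
path with exhaustive oracles: 4–6-taxon trees for likelihood and Dollo
oracle equivalence, 15-topology exhaustive scans at five taxa, 500–800-site
alignments for search and support, 30–200-codon pairs for the dN/dS oracle
and neutral calibration, and 100-replicate simulation experiments. Brent
uses an absolute x-tolerance of 1e-8 within (1e-9, 10) substitutions/site;
zero or negative branch lengths give the identity transition matrix;
degenerate inputs (empty stores, missing rows, frame violations,
zero-length references) raise explicit errors rather than propagating
silently.
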