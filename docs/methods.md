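# Methods

This note documents the models behind `xenocomp`, the defaults that matter,
and the choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Compositional profiles

A k-mer profile counts every k-window over {A,C,G,T}; any window containing
an ambiguity code (N, R, Y, ...) is skipped entirely rather than
fractionally attributed. The *reverse-complement extension* counts the
sequence and its reverse complement as two independent sequences (no
junction windows across an artificial concatenation point), which makes the
profile exactly strand symmetric — the point of the extension. k is limited
to 2–8; tetranucleotides (k=4, 256 categories) are the default signature.

Codon profiles are counted in frame 0 within each CDS independently, never
across gene boundaries; a trailing partial codon is dropped with a warning.
Frequencies are count/total-codons, the standard normalization that yields
a probability distribution over the 64 codons.

## The divergence statistic

For a region profile *p* and genome profile *q* over the same alphabet,

    D_KL(region ‖ genome) = Σ_i p_i ln(p_i / q_i)   (nats).

Both profiles receive a Laplace pseudocount (default 1 count per category)
before normalization. This keeps the divergence finite when a ~2.7-kb
operon misses tetranucleotides that the genome contains, at the cost of
shrinking the statistic slightly toward zero for short regions; since
operons are compared against each other at a fixed length scale, the
shrinkage is shared and rankings are unaffected. The genome profile always
includes the region itself (no leave-one-out): for a 2.7-kb operon in a
multi-megabase (here 200-kb) genome the self-contribution is negligible,
and it matches how whole-genome signatures are computed in practice.

KL is unbounded above, so a bounded companion score is reported:
`score01 = 1 − exp(−D_KL)`. It is monotone in the divergence, zero exactly
when the smoothed profiles coincide, and strictly below 1. Raw nats are
always reported alongside; score01 saturates numerically above ~36 nats,
far beyond anything a smoothed profile pair can produce.

## Windowed alien-region scan

Windows of 2500 bp (step 500 bp = window/5) slide along the genome; for
each window and each k in 2..8 the KL of the window profile against the
whole-genome profile is computed, and the per-k values are combined with
weights w_k ∝ 4^−(k−2), normalized to sum to 1. Higher orders carry some
independent signal but are dominated by sampling noise (and by the
pseudocount) in a few-kb window over 4^k categories, hence the geometric
down-weighting; most of the combined statistic comes from k = 2–4.

Calling is deterministic: an exact 1-D 2-means split (optimal sorted split
by within-cluster sum of squares) of the combined scores defines the
threshold, accepted only if the upper cluster's mean exceeds the overall
mean by two overall standard deviations. This effect-size guard keeps a
homogeneous genome — where 2-means happily splits pure noise — from
producing calls. Flagged windows that touch or overlap are merged; each
call records its peak score and any operon loci it intersects. At least 10
windows are required; shorter inputs should use the direct
operon-vs-genome table instead.

## Distance phylogenies

Pairwise amino-acid distances use the Poisson correction d = −ln(1 − p)
with p the proportion of differing sites under pairwise gap deletion
(columns where either row is gapped are excluded for that pair only, so no
taxon is lost to a single ragged row). Pairs with p ≥ 0.95 raise an error
naming the pair — at that level the correction is meaningless and the right
remedy is excluding the sequence, not silently clamping.

Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion. Ties on Q break to the lowest index pair; negative
branch-length estimates are clamped to zero (logged at debug level). On
additive matrices NJ provably recovers the generating tree; the test suite
checks this on random 5–8 taxon trees and cross-checks topology against an
independent implementation (dendropy).

Robinson–Foulds distances are computed after pruning both trees to their
shared leaf set, as the size of the symmetric difference of non-trivial
splits, normalized by its maximum 2(n−3). Trees are handled as unrooted
throughout (a degree-2 root is transparent to the split set).

## Lineage rate acceleration

Branch-specific rate estimation needs a clock model; this package instead
uses a deliberately simple proxy adequate for *detecting* an accelerated
lineage: the tree is rooted where the user-named outgroup attaches to the
ingroup, and the ratio of mean root-to-tip path length over a focal clade
to the mean over the remaining background leaves is reported. On a
clock-like tree the ratio is 1; if the focal clade's branches (stem
included) are scaled by m and the clade attaches at the ingroup root, the
true-tree ratio is exactly m. The root is placed at the ingroup-side node
of the outgroup edge (not mid-edge) so the outgroup stem does not dilute
the contrast. If an estimated tree fails to recover the outgroup as a
clade, the edge with maximal Jaccard overlap to the outgroup is used with a
warning rather than aborting — important in multi-replicate studies.

This proxy detects which lineage is accelerated and by roughly how much; it
is not a posterior branch-rate estimate, and on real data its numeric value
will differ from relaxed-clock machinery.

## Primer screening

IUPAC primers are scanned ungapped over every placement on both target
strands; a reverse-role primer is matched via its reverse complement
against the sense strand. The mismatch count at a placement is the number
of positions whose target base is outside the IUPAC code's expansion, so
the reported minimum equals a brute-force minimum over all degenerate
expansions (property-tested against exactly that oracle). Pair coverage
additionally requires amplifiable geometry — the forward site upstream of
the reverse primer's annealing site on the same orientation — and reports
the outer amplicon length. No 3′-end weighting, no thermodynamics, no
indels: this is probe-match-style screening, and mismatch counts near the
3′ end are not penalized differently. The mismatch budget is a required
user parameter with no claimed default.

## Synthetic data: what it emulates and what it does not

*Genomes.* Hosts are sampled from Markov models (order 0–k; the default
study uses order-0 models at GC 40% for hosts and GC 60% for donors —
separations of this size occur between real donor/recipient pairs). Host
genomes are ~85% coding, alternating codon-usage-driven genes (600–1200 nt,
random strand) with Markov intergenic spacers (100–200 nt), so the codon
method has a genome-wide usage signal to compare against. Codon-usage
tables are GC-parameterized: sense-codon weights gc^g(1−gc)^(3−g) with g
the codon's G+C count, stops excluded.

*Operon inserts.* Three same-strand genes (xmoC, xmoA, xmoB in CAB order;
an ABC mode mirrors the pxm arrangement) with two ~30-nt intergenic gaps;
spanning length is N(2730, 300) truncated at 1500 nt — 2730 nt being the
average xmoCAB operon span. CDS lengths are multiples of 3, drawn as i.i.d.
codons plus one terminal stop. Implantation places inserts uniformly at
random, ≥5 kb apart, never inside an existing host gene, and records exact
truth coordinates. The default detection study uses 200-kb hosts with two
foreign and two matched native (host-composition) operons.

*Gene families.* Amino-acid sequences evolve by a Poisson equal-rates
process: per site, replacement events arrive as Poisson(branch length) and
each replaces the residue with one of the other 19 uniformly, so branch
lengths are expected substitutions/site and the simulator is matched to the
Poisson distance estimator (the match is first-order: with 20 states the
observed proportion saturates as (19/20)(1 − e^(−20t/19)), so −ln(1−p)
under-corrects long paths; see "numerical behavior" below). Alignments are
ungapped by construction — alignment inference is out of scope.

The default base tree is a 12-taxon rooted binary tree, ultrametric over
the ingroup at depth 0.4 substitutions/site with internal branches of 0.1:
a 3-leaf focal clade (V1–V3, the "third operon" analog) attached at the
ingroup root, seven background taxa, and a 2-leaf outgroup. The depth is a
compromise fixed at design time: internal branches of 0.1 give NJ enough
signal at 500 sites, while deeper trees would push focal-to-background
path lengths into the saturating regime of the Poisson correction.

Perturbations: a *topology swap* regrafts a named clade (stem length
preserved) onto the midpoint of the edge above another named clade — the
default study moves the focal clade next to the B5–B7 clade for gene 2
only, reproducing the one-gene-transferred incongruence pattern. A *rate
multiplier* scales all branch lengths within a named clade, stem included,
for one gene; including the stem is what makes the root-to-tip ratio equal
the multiplier on the default tree geometry. The default study applies
×3.46 to the focal clade of gene 3.

All generators draw from `numpy.random.Generator` streams spawned from one
`SeedSequence(seed)`, one child per stage; fixed seeds give byte-identical
FASTA/TSV outputs.

What passing these studies does *not* show about real data: real genomes
have higher-order compositional structure, amelioration gradients, mobile
elements and rearrangements; real operons are not cleanly inserted into
intergenic positions; real proteins evolve under exchangeability and rate
heterogeneity that the equal-rates model ignores; and real alignments have
gaps. The studies validate the statistics and their implementations, not
field performance.

## Numerical behavior and problem sizes

* The KL implementation equals an explicit per-category summation to
  1e−12 (tested); Gibbs' inequality (KL ≥ 0, zero iff identical smoothed
  profiles) is property-tested, with a zero-clamp guarding float round-off
  on identical inputs.
* Root-to-tip rate recovery carries a known downward bias from the finite
  state space: at the default tree scale the recovered mean over 50
  replicates sits roughly 10% below the true multiplier, within the ±15%
  band the recovery study checks. Shrinking the tree reduces this bias but
  starves NJ of topology signal; the default is the documented compromise.
* Study sizes used by the test suite and acceptance script — 20 replicates
  of 200-kb genome scans, 50 replicates of three-gene simulations at 500
  sites, 100 random additive matrices, 1000 random profile pairs, 200
  primer oracle pairs — were chosen so each study estimates its rate or
  mean stably; the full suite runs in well under a minute of compute
  per study.
* Degenerate inputs are rejected loudly: empty FASTA records, non-IUPAC
  characters (with position), out-of-bounds features, saturated distance
  pairs, zero-overlap pairs, fewer than 10 scan windows, stop-codon mass in
  usage tables, unsatisfiable insert spacing.

## Open design choices resolved here

* Operon extraction for k-mer work uses the *spanning* locus (one
  contiguous region, as a whole-locus upload would be); codon work uses
  *concatenated CDS* (codon counting requires coding sequence). Both modes
  are public.
* The "combined 2–8-mer" weighting, the scan threshold rule and the scan
  step are not published for the reference island-detection tools at this
  level of detail; the geometric weights, exact 2-means + 2·SD guard and
  window/5 step used here are deterministic, documented and tested, but are
  not claimed to reproduce any external tool's calls.
* Internal coordinates are 0-based half-open everywhere; GenBank, loci TSV
  and CDS TSV convert at the I/O boundary (files are 1-based inclusive).
* Newick serialization is implemented in-package (the tree type is core to
  the package); dendropy is used in the tests as an independent oracle for
  RF distances, NJ topologies and newick parsing, never as the
  implementation.
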