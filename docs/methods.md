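# Methods

This note documents the models implemented in `aylacostoma`, the parameter
choices that matter, what the fixture generators emulate, and the
numerical decisions taken where the design was genuinely open.

## Data model

The central object is a `MultipleAlignment`: equal-length gapped sequences
over `ACGT-` with unique IDs, stored as an immutable byte matrix.
Ambiguity codes are rejected at read time rather than silently skipped —
on a 234 bp fragment a single mis-scored residue materially changes every
distance, so partial data should be cleaned explicitly.  All coordinates
are 1-based alignment columns so that reports line up with published
polymorphic-site tables.

Pairwise comparisons distinguish three site categories: transitions
(A↔G, C↔T), transversions (all other base mismatches), and indel events.
A column gapped in exactly one of the two sequences is never a nucleotide
difference; maximal runs of such columns count as one indel event.
Columns gapped in either sequence are excluded from the comparison
denominator (`compared_sites`).

## Distances

* p-distance: (transitions + transversions) / compared_sites.
* K2P: `d = -½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` with P, Q the transition
  and transversion proportions.  When an argument of a logarithm is
  non-positive the distance is saturated: the scalar function returns NaN
  with that diagnosis, and matrix construction turns it into a hard
  error naming the pair — a silent NaN in a matrix would propagate into
  trees and delimitation.
* Deletion modes: *pairwise* (default) drops gapped columns per pair;
  *complete* removes every column containing any gap first.  Pairwise is
  the default because the study data's printed p-distances are 9/233,
  10/233 and 5/233 — a 233-site denominator, which both modes happen to
  produce there.
* Values are kept at full precision internally and rounded to 6 decimals
  only when written to reports.

Group summaries compute mean within-group (dX), mean between-group (dXY)
and net divergence `Da = dXY − (dX + dY)/2`.  A singleton group has no
within-group pairs; its within-mean is recorded as undefined, not 0.  For
Da some convention is unavoidable: the default `singleton_zero` treats the
undefined term as 0 (the natural choice when each population is a single
haplotype), and `borrow_sister` substitutes the partner group's
within-mean as a more conservative alternative.  Every report states the
policy used.

Standard errors come from the nonparametric column bootstrap: alignment
columns are resampled with replacement (same count), the statistic is
recomputed, and the SE is the sample standard deviation across replicates
(default 1000; a seed is mandatory).  On the fixture this agrees with the
binomial delta-method SE to within a few percent.

## Neighbour joining

Saitou–Nei agglomeration on the distance matrix, joining the pair that
minimises `Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`.  Numerical
decisions:

* Ties in Q are broken by the lexicographically smallest pair of cluster
  keys (a cluster's key is its smallest member ID).  Ties are routine
  here because within-species distances are exactly zero.
* Q is evaluated in floating point and its two orientations can differ in
  the last ulp, so minimisers are canonicalised to unordered pairs before
  tie-breaking.
* Negative branch lengths are clamped to zero with the deficit moved to
  the partner branch of the join; raw values are logged at debug level.

Split support is the percentage of column-bootstrap replicate NJ trees
containing the split (bipartition), not a statement about node identity.
Supports are attached to internal nodes and serialised as integer Newick
labels; branch lengths round-trip at 10 significant digits.

## Secondary-structure classification

Variable columns are mapped onto a dot-bracket annotation.  At a paired
column, a sequence "preserves" the stem if its (base, partner-base)
combination is in {AU, UA, GC, CG, GU, UG} (T read as U); GU wobble is
included because it is a legitimate rRNA pairing and excluding it would
misclassify ordinary compensating changes as disruptions.  A gap at a
paired column is classified stem-breaking with an `indel-in-stem` note.
The published structural model for this fragment is only available as a
figure, so tests validate the classifier against a synthetic surrogate
structure that reproduces the reported pattern (ten loop changes, three
pairing-preserving stem changes); the classifier itself accepts any
user-supplied Vienna-format string.

## Clock test and dating

Tajima's relative rate test counts, over sites with no gap in any of the
three sequences, the sites where each ingroup taxon alone differs while
the other agrees with the outgroup (m1, m2).  The statistic
`(m1 − m2)²/(m1 + m2)` is referred to the 1-df chi-square upper tail with
no continuity correction, following the test's original formulation.
Under clock-like simulation (5000 sites) the empirical type-I error at
α = 0.05 is 0.048 over 500 runs.  The likelihood-ratio clock test on ML
trees used alongside it in the original study is out of scope here;
reports state that the relative rate test is what was run.

Dating uses `T = Da/2μ` with 2μ = 0.006 substitutions/site/Myr by default
(a rate commonly applied to gastropod mitochondrial rRNA) and
`CI = (Da ± 1.96·SE)/2μ` with SE from the column bootstrap of Da.  These
identities are exact by construction and tested as such.  On simulated
clock data (true split 3.0 Myr, 5000 sites, 100 replicate datasets, 100
bootstrap replicates each) the estimator shows −2.1% bias and 94% CI
coverage.

The study's printed divergence times (6.57 and 3.75 Myr) are *not*
reproduced: arithmetic on its own printed K2P distances gives 6.39 and
3.66 Myr under any singleton policy, so the published values must rest on
a slightly different distance variant (possibly gamma-corrected) that the
text does not specify.  The package reports its own reproducible values
and leaves the discrepancy documented rather than tuning toward the
printed numbers.

## Species delimitation

**Barcode-gap partitioning.**  The published ABGD algorithm's recursive
local-slope gap heuristic is not fully specified by its description, so
this package implements a deliberately simplified, fully documented
variant: sort the distinct pairwise distances; among those at or above
the prior P, the first consecutive pair `(d_i, d_{i+1})` with
`d_{i+1} − d_i > X·d_i` (default X = 1.5) marks the barcode gap and `d_i`
becomes the clustering threshold, falling back to P when no gap
qualifies; groups are connected components of the ≤-threshold graph,
refined recursively within groups until stable.  The prior is scanned
over a geometric ladder (default 0.001 → 0.1 in 10 steps, matching the
original method's defaults).  On the fixture this reproduces the study's
partition table exactly: three groups for the seven priors ≤ 0.021544.
Outgroups are excluded before delimitation.  The group count is monotone
non-increasing in the prior (property-tested on random matrices; this
follows from the threshold being non-decreasing in P).

**K/θ.**  K is the mean between-clade pairwise distance; the decision
rule is distinct species when K/θ ≥ 4.  θ policies: `supplied` (explicit
value, e.g. taken from another locus), `max_within` (the larger
within-clade mean), and `watterson_upper` (the upper bound `3/(a_n·L)`,
`a_n = Σ_{i<n} 1/i`, for clades with zero observed variation).  The
study's θ values (0.0043165, 0.0014333) cannot arise from this fragment —
every species shows a single haplotype, so within-clade means are zero —
and their provenance is unstated; they are honoured verbatim through the
`supplied` policy, and no policy here claims to regenerate them.  θ must
resolve strictly positive, otherwise the test errors (`theta unresolved`)
rather than dividing by zero or silently passing.

## Fixture generators

**Table-derived alignment.**  The 11 × 234 ingroup alignment is rebuilt
from the printed tables: 13 polymorphic columns with per-species states
(including the single gap column), sample sizes 1/3/7, and per-species
base totals.  Invariant column *content* is not printed anywhere, but
every in-scope statistic depends only on the invariant base counts, which
are uniquely determined by subtracting each species' polymorphic states
from its composition totals (A=78, C=28, G=36, T=79 over 221 columns).
The builder verifies this consistency for every species (an inconsistent
spec fails naming the species) and lays the background down in a
seed-shuffled order; two seeds give alignments differing only by a
permutation of invariant columns, with identical distances, trees,
partitions and dates.  What the fixture does *not* emulate: the real
GenBank sequences' actual invariant residues, outgroup sequence content,
and any intra-species variation (none was observed).  Tests passing on
the fixture therefore validate the arithmetic of the pipeline against the
published tables, not the biological sequences themselves.

**Clock simulator.**  Three taxa on ((A,B):inner, C):outer evolve under
K2P with per-lineage rate μ = 2μ/2, using the closed-form branch
transition probabilities (no per-site event loops), so the expected K2P
distance between tips split t Myr ago is exactly `2μ·t`.  The root
sequence is uniform over ACGT (the K2P stationary distribution).  The
default transition/transversion ratio is 10, reflecting the strongly
transition-biased fragment (all 13 observed variable sites are
transitions); calibration results are insensitive to this choice.  Tips
may carry multiple identical copies to mimic single-haplotype
populations.  The simulator omits rate heterogeneity across sites,
indels, and selection.

## Problem sizes used in the test suite

Simulation-based checks use sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances: 30 × 50 kb alignments for simulator
unbiasedness (MC error ≈ 0.5%), 500 × 5 kb for relative-rate-test
calibration, 100 datasets × 5 kb × 100 bootstrap replicates for dating
recovery, 100 random trees (≤ 8 leaves) for NJ consistency, and 50 random
matrices for partition monotonicity.

## Known limitations

* Only p and K2P distances; no gamma correction or other substitution
  models, which is why the published divergence times are documented as
  non-reproducible rather than matched.
* The barcode-gap partitioner is a simplified variant, validated against
  the study's table, not a reimplementation of the original program's
  full heuristic.
* Maximum parsimony, maximum likelihood and Bayesian tree inference and
  Bayesian dating are out of scope; the NJ tree is the only topology
  produced.
* The pipeline assumes an aligned input; it performs no alignment.
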