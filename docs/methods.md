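# Methods

## Model and definitions

All computations take a rooted cladogram and a table of per-taxon first
occurrences (FOs). Ages increase into the past (Recent = 0). Two age scales
are supported: unit stratigraphic intervals (default; the classic 77
series-and-stages coding, 0–76) and millions of years. Every index is
invariant to the choice up to the units tag on reported gap sums (MIG on
unit intervals is conventionally written MIGu).

A clade's implied origin is the oldest FO among its members. On a binary
tree each branch's ghost range is age(parent) − age(child), so an internal
node with child clades of ages a and b contributes |a − b|; the sum over
the tree is the minimum implied gap (MIG). Branches at and below the root's
children contribute; the root itself has no subtending branch. For a fixed
FO multiset the topology-free bounds are Gmin = FOoldest − FOyoungest
(a perfectly laddered tree telescopes the consecutive gaps) and
Gmax = Σ(FOoldest − FO_i) (every taxon hung directly against the oldest).
Both identities are verified exhaustively over all rooted binary topologies
for up to six taxa in the test suite.

The five indices follow the standard definitions (see README). Assumptions
inherited from the ghost-range framework: bifurcating cladogenesis, no
sampled ancestors, and monophyletic terminals. The SCI tie rule treats
equal sister ages as consistent for both nodes ("no older than" is `<=`),
which is what inflates the SCI when few distinct FO dates are spread over
many terminals.

### Irreversible Sankoff cross-check

MSM* is defined through the optimal length of an irreversible age character:
FO ages are ordered states; a parent in state s may subtend a child in state
t only if s is no younger, at cost s − t. We implement this as an
independent dynamic program (per-node cost vectors over distinct states,
with the prefix-minimum trick for the irreversible step matrix) and require
its optimum to equal the ghost-range sum — a dual-route equality tested on
500 random tree/date pairs. The worked five-taxon example (minimum length
Lm = 5, optimized length Lo = 9, Gmax = 14, hence MSM* = GER = 0.556) is
reconstructed by brute force from those constraints rather than hard-coded;
note that the conventional labels enter MSM* as Lm = Gmin and Lo = MIG.

### Permutation null (GERt, GER*)

Gtmin/Gtmax are estimated by shuffling the observed FO multiset across the
tips (permutation without replacement) and recomputing MIG on the fixed
topology. Design choices:

* The observed MIG is pooled into the min/max, so GERt is always defined on
  [0, 1] regardless of replicate count.
* GER* ties: permuted values equal to the observed MIG receive half weight
  (midpoint rule, default) or zero weight (`ties="strict"`). Equality is
  tested with a small relative tolerance (rtol 1e-12, atol 1e-9) because
  sums of the same age multiset taken in different orders can differ in the
  final ulps.
* Default 1000 replicates, seeded; the seed and replicate count are echoed
  in every report. An exhaustive mode (all n! assignments, n ≤ 8) backs the
  small-fixture oracles in the tests.

### Polytomy resolution

Polytomies are resolved into ladders ranked by clade-oldest FO. `soft`
places the oldest child as the earliest divergence, so the polytomy
contributes only the telescoped consecutive gaps (the most congruent
resolution); `hard` nests the oldest child deepest, maximizing the implied
gap, so a completely unresolved tree scores at the indices' theoretical
minima — the view that lack of resolution is lack of information. `hard` is
the CLI default. Exhaustive enumeration over all resolutions of star trees
with up to five children confirms soft/hard attain the exact min/max MIG.
Ties in clade-oldest FO preserve input child order and are logged; this
tie rule is a documented package choice, as is the root-exclusion convention
in percent resolution r/(n − 2)·100 (only with the root excluded does a
fully bifurcating rooted tree score 100).

### Covariates

Center of gravity CG = ΣN_i t_i / ΣN_i (occurrence-weighted mean FO age),
rescaled as CGscaled = (FOoldest − CG)/(FOoldest − FOyoungest); > 0.5 is
top-heavy (FOs crowded toward the youngest terminal). Gap variability is
sd(successive FO gaps)/range(gaps) — scale-free regularity of spacing; the
sd flavour is configurable (sample, ddof = 1, by default; the population
flavour is offered because the convention is not fixed in the literature).
All-equal gaps return 0 by definition (flagged degenerate rather than NaN),
with a relative tolerance so arithmetically spaced floating-point ages count
as equal. Taxa with no fossil record carry an FO placeholder at the Recent
(age 0), so they subtend maximal ghost ranges ("pull of the Recent"); they
are included in CG and gap variability by default with an exclusion switch,
since either convention is defensible. Mixed-rank datasets record the
median ordinal rank, rounded half-up. Undefined quantities (CGscaled with
zero FO range; Colless on a polytomous tree) are reported as nulls with
reason flags, never sentinel numbers.

## Simulation study

The simulator asks what each index does on stratigraphically *random* data.
Defaults are the study conditions: 64 taxa; 4, 8, 16, 32 or 64 distinct FO
dates spanning 128 unit intervals; regular, top-heavy or bottom-heavy date
spacing; maximally balanced or maximally pectinate topology (the Colless
extremes, Ic = 0 and 1); 5000 outer shuffles of the FO multiset per
condition; GERt and GER* from a fresh 1000-replicate inner null per shuffle.
That is a 2 × 3 × 5 = 30-condition grid. Equal block allocation assigns
n_taxa/n_dates taxa per date (divisibility is enforced; unequal allocation
is not part of the design). Four dates for 64 taxa emulates a record
dominated by a few Lagerstätten; 64 distinct dates emulates continuous
sampling with exact stratigraphy.

Skewed date spacing uses a geometric gap progression pinned to both
endpoints (so every condition spans the identical 128-interval range),
parameterized by `gap_fold` — the ratio of the largest to the smallest gap —
rather than by a fixed successive-gap ratio: a constant fold keeps the
distribution *shape* (CGscaled) the same whatever the date count, and stays
numerically non-degenerate at 64 dates, where a fixed per-step ratio of 2
would shrink the smallest gap below float resolution and collapse adjacent
dates. Default fold 64 gives CGscaled ≈ 0.77 for the top-heavy case (a
latent radiation); bottom-heavy is its mirror (early burst). The fold is a
config knob for exploring other skews.

MIG and SCI are evaluated by a vectorized postorder kernel (one |a − b|
accumulation per internal node across all assignment rows at once), which is
what makes 5000 × 1000 nested permutations tractable in seconds per
condition. Reruns with the same seed are byte-identical; per-condition
seeds are spawned from the study seed.

What the generator does *not* emulate: birth–death clade growth, lineage-
specific preservation rates, tree inference error, or real geological
timescale structure. Passing null-behaviour tests therefore shows how the
indices respond to tree shape and FO-date geometry, not how well any
empirical record fits its phylogeny.

## Problem sizes used in the checks

The bundled acceptance run uses the full 5000 outer shuffles for the median
MSM*/SCI sweeps (where no inner null is consumed by the reported statistic)
and 500 outer × 250 inner for the GER* medians — the package's own
stability test shows GER* medians move by < 0.02 between 250 and 1000 inner
replicates, so the scaled run measures the same quantity. The five-taxon
worked example search and the exhaustive topology/permutation oracles run
in well under a minute.

## Known limitations

* Unrooted trees are out of scope; all indices presuppose a root.
* No branch-length-aware dating, tree search, or fossilized birth–death
  modelling; the simulator permutes dates over fixed topologies only.
* Ancestor-aware index variants (ignoring terminal sister ghost ranges) are
  not implemented.
* Stage-name reconciliation against published geological charts is
  editorial curation, not an algorithm, and is not attempted; interval codes
  or Ma values are taken as given.
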