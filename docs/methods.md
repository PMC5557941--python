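# Methods

## Scope and data model

The pipeline delimits putative species among DNA-barcoded individuals using
four coordinated criteria — distance-based molecular partitioning,
geographic thresholds, tree-based monophyly and discrete-character
diagnosability — and a congruence rule that combines them. Its common
currency is the `Partition`: a total, disjoint assignment of specimen ids to
group labels, whatever the method that produced it (gap partitioner,
geographic clustering, morphospecies hypothesis, or an imported table from
an external delimitation program such as PTP). Trees may be built internally
(neighbour joining) or imported as newick from likelihood/Bayesian software;
tree inference beyond NJ, alignment construction, and model selection are
deliberately out of scope.

## K2P distances

Distances use the Kimura two-parameter correction with pairwise deletion:
for each pair, only sites where both sequences carry A/C/G/T are compared
(gaps and N, plus any other IUPAC code, are missing data; other ambiguity
codes are collapsed to N on input with a logged warning). With transition
proportion `p` and transversion proportion `q` over the m comparable sites,

    d = -1/2 ln(1 - 2p - q) - 1/4 ln(1 - 2q).

The estimator diverges when `1 - 2p - q <= 0` or `1 - 2q <= 0`
(saturation). Such pairs never become silent infinities: the whole-matrix
computation collects them and raises a structured error listing every
failing pair, or — on explicit opt-in (`on_saturation="cap"`) — replaces
them by the largest finite observed distance. Pairs with no comparable site
always raise. The distance histogram used to eyeball the barcode gap has 40
equal-width bins over [0, max].

Intra/inter summaries conditioned on a partition are **pooled over pairs**
(all within-group pairs together, all between-group pairs together), not
averaged per group: pooled statistics are what single printed
mean (min–max) ranges correspond to. Per-group maxima are also reported so
per-group views can be reconstructed.

## Barcode-gap partitioning

Given a prior intraspecific divergence `P`, the sorted distance list
`d_(1..m)` is scanned above the last rank with `d <= P`. The rank gap
`g_i = d_(i+1) - d_(i)` is *significant* when it is positive and strictly
exceeds `X * r_i`, where `r_i` is the mean of up to `w` preceding rank gaps
(defaults `X = 1`, `w = 10`); a rank with no preceding gap cannot be
assessed and is skipped, and the strict comparison carries a small relative
epsilon so gaps equal up to floating-point noise never count. Among the
significant gaps the **largest** is chosen and the threshold is its
midpoint. We also provide a "first significant gap" rule as an option, but
it is not the default for a concrete reason: K2P distances from aligned
barcodes are quantized near multiples of 1/L, so the sorted intraspecific
region is a staircase of ties whose first positive step always dominates
the local mean gap — the first-gap rule then triggers essentially at the
prior itself and over-splits at small priors (on the default simulated
dataset it selects a ~140-group plateau where the largest-gap rule selects
the 22 planted species exactly). The largest-gap rule also matches the
qualitative behaviour expected of barcode-gap scans: a primary partition
stable across the whole prior range below the interspecific band.

Groups are connected components of the `d <= t` graph (single-linkage
connectivity), labelled `G1..Gk` by first-member input order for
determinism. When no significant gap exists the primary partition falls
back to `t = P` (recorded per prior), keeping the scan total. The
*recursive* partition re-runs the gap search inside every group of size
>= 3 on the group's own distances (no fallback inside groups) until nothing
splits or 20 rounds pass; it always refines the primary partition. The
prior scan uses a log-spaced grid (default 20 priors over 0.001–0.14),
detects plateaus (maximal runs of equal primary k) and selects the primary
partition at the start of the widest plateau, ties going to larger priors —
primary partitions stable over a wide prior range are the canonical pick.

## Geographic delimitation

Sites within a 5 km single-linkage radius form a population; a population
inherits the morphospecies of its members (mixtures are reported).
Inter-population distance is the minimum over member-site great-circle
distances (spherical earth, R = 6371.0088 km; ellipsoidal corrections are
irrelevant at 5–500 km scales); centroid distance is available as an
option. Within each morphospecies, populations are clustered at a km
threshold — single linkage by default, so two distant populations still
merge through an intermediate one within threshold of both; complete
linkage is available for the stricter pairwise reading, since the verbal
rule ("populations separated by more than the threshold are distinct")
does not decide between the two. Geographic delimitation only refines the
morphospecies partition, and under single linkage the species count is
non-increasing in the threshold (asserted at run time).

## Trees and monophyly

NJ is the classical Q-matrix agglomeration with two determinism rules:
ties in Q are broken by the lexicographically smallest joined pair (each
internal node carries the smallest leaf label of its subtree), and negative
branch lengths are clamped to zero with the deficit moved to the sister
edge. Duplicates are kept (identical sequences appear as zero-length
leaves). Bootstrap resamples alignment columns with replacement, recomputes
K2P + NJ, and scores each bipartition of the reference tree by the fraction
of replicates containing it; a replicate whose distance matrix fails (e.g.
saturation) scores nothing. All resampling is driven by one seed.

Monophyly of a cluster means: on a rooted tree, a node whose descendant
leaf set equals the cluster; on an unrooted tree with an outgroup, the
cluster is one side of a bipartition disjoint from the outgroup (equivalent
to rooting on the outgroup edge); with `rooting="unrooted"`, any
bipartition side counts — the natural criterion for unrooted NJ/ML trees,
used by the end-to-end pipeline since the simulator plants no outgroup.
Size-1 clusters are `trivial` (and count as monophyletic for validation);
clusters with leaves missing from the tree are `unresolvable` and listed.

## Congruence and validation

Congruence is cluster-wise: a reference cluster is congruent iff its exact
specimen set is a cluster of every compared partition. Whole-partition
equality would be the wrong reading — a 22-cluster molecular partition can
coexist with a 26-cluster geographic one while agreeing on almost every
cluster — so the report names, per cluster, exactly which methods disagree.
Adjusted Rand indices and the meet (common refinement) summarize overall
agreement. Character analysis excludes deformed specimens (bilateral
asymmetry in diagnostic structures) from every statistic; values are opaque
categorical strings (no partial credit for similar formulae). Stability of
a character in a cluster is the modal-value fraction among non-missing
values; two clusters are diagnosable on a character iff both have values
and the value sets are disjoint.

The validation rule per cluster: monophyly (i), congruence (ii), and
morphology (iii) — at least one character with stability >= the floor
(default 1.0, i.e. no intraspecific variation; lower it to tolerate rare
aberrant individuals) *and* diagnosability against every other cluster on
at least one character. All three ⇒ `validated_species`; (i) and (ii)
without (iii) ⇒ `cryptic_species`; otherwise `unresolved`.

## Synthetic data

The generator emulates the structure these analyses assume rather than a
demographic process. Sequences: a uniform random root of length L = 658
(the standard COI barcode length); each species ancestor evolves along an
independent branch of length drawn uniformly from half the interspecific
band (default 0.09–0.20 expected substitutions/site), so ancestor pairs
land inside the band; individuals radiate from their ancestor on a star
genealogy with Poisson(L·intra/2) K80 jump events each (transition:
transversion ratio kappa = 4), giving expected within-species pairwise K2P
near the intraspecific target (default 0.02). Star genealogies are the
simplest process matching pooled divergence targets; a deep-split option
and a random gap-masking option exist for stress tests. Geography: species
range centres are rejection-placed at least twice the range radius apart in
a box spanning roughly northeast-Asian extents (lat 40–52, lon 120–136);
populations scatter within the range radius; widespread species get a
second centre > 150 km away. Characters: one categorical value per
character per species (three pseudocelli-style characters); cryptic pairs
copy all values; morphospecies labels come from a lumping map; deformity is
i.i.d. Bernoulli (default 5%).

Every dataset is checked for its planted gap (max pooled intra < min
inter) and regenerated from a seed-derived stream with a logged attempt
count if violated; defaults essentially never need regeneration. What
passing tests on such data show: the machinery recovers planted structure
exactly when a clean barcode gap exists. What they cannot show: behaviour
under coalescent variance, rate heterogeneity, indel-rich alignments,
introgression or uneven geographic sampling — real data may present gaps
far murkier than the simulator's.

The `emulate_study` preset mirrors a realistic integrative study: 22
species in 144 specimens, 10 morphospecies (4 of them cryptic pairs, one a
lone widespread species, the rest lumping 2–3 diagnosable species), centre
spacing 120 km and range radius 10 km so a 50 km threshold separates every
lumped species pair while the widespread species' two ranges split. One
structural simplification: species do not co-occur at shared sites, so the
preset assembles 23 populations — co-occurrence would require either
overlapping ranges (breaking the spacing guarantee) or shared sites within
a morphospecies (collapsing the geographic signal).

## Problem sizes and numerical choices

Default analyses run at n = 144 specimens × 658 bp (≈10,000 pairs), where
the full pipeline — distances, 20-prior scan with recursion, geographic
scan, NJ and validation — completes in a couple of seconds; bootstrap
examples use 100–200 replicates on small alignments. Distance computation
is vectorized row-against-block; connectivity uses sparse connected
components. Tolerances: distance oracle agreement to 1e-12; the gap
significance epsilon is 1e-15 absolute plus 1e-9 relative; simulator
calibration is judged at ±30% of configured targets over seeds, reflecting
Poisson sampling variance at ~400 intra pairs per dataset.

## Known limitations

- The gap partitioner is a self-contained reimplementation of the
  barcode-gap idea, not a line-for-line port of any published program;
  provenance tags on partitions record its parameters.
- Recursive partitions at very small priors can over-split (as expected:
  the prior asserts almost no intraspecific variation); selection therefore
  relies on primary-partition plateaus.
- Geographic delimitation needs every specimen to carry coordinates and a
  morphospecies; specimens lacking either are excluded with warnings or
  rejected, never silently guessed.
- Monophyly on unrooted trees treats any bipartition side as a clade; with
  a genuine outgroup, pass it explicitly for the rooted semantics.
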