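# Methods

## Known PD and marginal contributions

Phylogenetic diversity (PD) is used in the strict sense: the sum of branch
lengths, in Myr, of a phylogenetic tree or of the subtree spanned by a
species set.  *Known PD* at a date is the PD of the subtree spanned by the
species formally described by that date, where the spanning subtree always
includes the path to the root: the tree's root is the clade's origin, and
the first-described species is credited its full root-to-tip depth.  This
convention makes conservation exact — for any discovery order the
per-species marginal contributions sum to the full tree's PD — and it is
the only choice under which "remove the most recently described species and
recompute" yields a telescoping sum.  The root itself has no edge; a stem
edge on an extracted clade is never counted in PD.

The reference definition of a species's contribution is the backward one:
delete the most recently described tip (removing its pendant edge and
suppressing the resulting degree-2 node by summing its two incident edges),
recompute total PD, take the difference, repeat.  The implementation uses
the equivalent forward view: walk from the tip toward the root and sum edge
lengths until reaching a node already visited by an earlier-described
species.  This is O(total tree size) per discovery order instead of
O(n²), and the test suite checks it against a brute-force
remove-and-recompute oracle on hundreds of random trees and on every
permutation of trees up to six tips.

Species described in the same year have no defined relative order.  The
within-year order is randomized (default 100 permutations, one RNG stream
per tree × permutation replicate so any replicate is reproducible in
isolation) and per-species contributions are averaged across replicates.
95% intervals are empirical 2.5/97.5% quantiles pooled over trees and
permutations, not normal approximations — contribution distributions are
strongly skewed.  When several merged tree samples are supplied, replicates
enumerate trees × permutations and the bands pool over both; pooling is the
default because the two sources of variation are not separable in the
curves being summarized.

Accumulation curves cumulate per-replicate contributions either by
description year or along each replicate's own discovery order (count
axis), then summarize across replicates.  Milestone years are the earliest
grid point at which the cumulative mean reaches the requested fraction of
its final value.

## Counterfactual discovery orders

The null model permutes the observed multiset of description years
uniformly across species and recomputes everything.  Permuting year labels
— rather than drawing new years — preserves the historical tempo of
descriptions, so null and observed curves share the same time axis and the
same final total.  The reversed model inverts discovery ranks (within-year
ties still randomized).  Difference curves are pointwise observed − 
reference means on the observed grid (the reference is carried forward
stepwise-constantly if grids differ), with bands from paired replicate
differences when both curves carry replicates.

Under a discovery process biased toward evolutionarily distinct species,
the observed cumulative curve runs ahead of its null early and the gap
decays back to zero — both curves end at total PD, so the cumulative
difference cannot change sign late; what turns negative late is the
per-discovery *increment* difference.  The empirical avian record differs
in one respect: its first-year burst of descriptions was phylogenetically
clustered (a regional avifauna), which put the observed curve briefly
*below* the null at the very start.  The synthetic generator does not
emulate that clustering (see below), so passing calibration tests here show
correct behaviour for an exchangeable or distinctness-biased process, not
for every feature of the historical record.

## Trend regression

The decline of contributions is fit by OLS of log(mean contribution) on
description year or on discovery count — one point per species, species
sharing a year sharing an x, no jitter.  Fitting in log space keeps
predicted contributions positive and linearizes a proportional decline.
The slope *b* per unit x is reported as a percent decline
100·(1 − e^*b*), i.e. "percent relative to the previous value", with
delta-method SE 100·e^*b*·SE(*b*).  A second fit drops species described
before a cutoff year (default 1780) to remove the leverage of the initial
burst.  On noiseless log-linear input the fit recovers the generating rate
to ≥ 10 significant digits; percent decline is invariant to rescaling all
contributions by a positive constant.

A species's whole marginal contribution is attributed to its own order in
the per-order summaries, even where part of the added path lies on shared
backbone edges: the marginal contribution is indivisible, and re-computing
PD within order subtrees would double-count shared edges across orders.
Decade matrices use calendar decades from 1750; a trailing partial decade
is kept as is.  Decade-distinctiveness ties break by earlier year, then
lexicographic name.  The recent per-discovery increment is the mean of mean
contributions over the trailing 50 years of the record.

## Supertree assembly

Merging takes a backbone tree (inter-group relationships) and donor trees
(within-group relationships), all ultrametric time trees:

1. **Extract** the donor clade spanning a group's species, with its stem
   edge.  Non-monophyly is an error naming the intruding tips, except for
   species declared misplaced, which are silently excluded here and
   re-attached later.
2. **Rescale** every edge (stem included) by a single factor so the clade's
   stem-to-tip depth equals the depth of the group's representative in the
   backbone.  Depth (stem age) rather than summed branch length is matched:
   grafting time trees must preserve tip contemporaneity, and matching a
   branch-length *sum* would destroy ultrametricity.  Edge-length ratios
   are preserved exactly.
3. **Graft** the rescaled clade in place of the backbone representative.
   Because depths match, an ultrametric backbone stays ultrametric.

Groups absent from the backbone are inserted before grafting: the sister
group is read from a reference topology, and the new group's stem length is
set to (stem ratio in a reference tree) × (sister's backbone stem), clamped
into the open interval between the sister's crown age and its stem-parent
age so the insertion is geometrically valid; the group enters as a
placeholder tip at the present and is expanded by its species-level graft.
Which reference donates the topology and which the ratio is configurable —
the published procedure this follows is ambiguous on that point.

Misplaced species are re-attached at the crown node of their true family as
an additional child (creating or extending a polytomy) with pendant length
equal to the family's crown age — the maximum value that keeps the species
inside the family crown with its tip at the present.  This deliberately
overstates such a species's distinctness in exchange for leaving every
other branch length in the family untouched.  For a monotypic target family
(no crown) the species is attached as a sister at half the single tip's
pendant depth.  Finally, tips not recognized as full species are pruned
with degree-2 suppression (incident edge lengths summed), which preserves
pairwise path lengths among retained tips exactly; if pruning leaves the
root with a single child, that child becomes the root and the dangling stem
is dropped.

Polytomies are accepted everywhere and never arbitrarily resolved.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

- **Tree**: constant-rate birth–death (defaults: birth 1.0/Myr, death 0)
  run forward and stopped at the first passage to `n_species` extant
  lineages, plus one final exponential waiting-time stretch so pendant
  edges are strictly positive; extinct lineages pruned; the whole tree
  rescaled to a root depth of `root_age` (default 100 Myr).  First-passage
  conditioning is simpler than uniform sampling of conditioned histories
  and slightly biases node ages, which is irrelevant here: downstream code
  needs an ultrametric tree with realistic shape, not an unbiased sample of
  the birth–death posterior.
- **Taxonomy**: orders are the clades obtained by cutting at the
  `n_orders − 1` deepest internal nodes (guaranteeing monophyly), families
  by cutting each order the same way into ≈ √(order size) pieces.
- **Discovery years** (defaults 1758–2013): the discovery order is an
  exponential-weight draw without replacement, weight exp(bias × 
  standardized fair-proportion distinctness), implemented exactly via the
  Gumbel-max trick; bias 0 gives an exchangeable random order.  The first
  5% of the order (Linnaeus described roughly 550 of the ~10 000 birds in
  1758) is dated to the first year; remaining species get years drawn
  uniformly over the rest of the range and sorted, so draw order and
  calendar order agree.  The exponential-weight sampler is a modelling
  stand-in, not an inference claim about how taxonomists actually chose;
  and the burst is *distinctness-biased*, not regionally clustered as the
  real 1758 burst was.
- **Merge fixtures**: a truth tree plus an order-level backbone missing one
  order (the smallest order not attached at the root — a root-attached
  order has no sister stem to receive a transferred ratio), a family-level
  reference at 0.7× depth, and a species-level donor at 1.6× depth with one
  species (from a ≥ 3-species family) moved into a foreign order.  Merging
  this set must recover the truth topology on unperturbed tips (checked by
  Robinson–Foulds distance 0 via an independent implementation), restore
  the omitted order next to its true sister, repair the planted
  non-monophyly, and stay ultrametric.
- **Direct contribution series**: log c = log c₀ − r·(t − t₀) + ε,
  ε ~ N(0, noise_sd), for exercising the trend regression against a known
  rate (defaults r = 0.0077/yr, noise_sd 0.5).

All generator randomness derives from the config seed through named
per-function streams; a fixed config reproduces byte-identical output.

## Numerical choices and problem sizes

- Ultrametricity is asserted at 1e-9 relative tip-depth spread for
  simulated trees and 1e-6 for merged trees (grafting accumulates a few
  rescaling roundings).
- Conservation is asserted at 1e-9 relative error; fast-vs-brute-force
  agreement at rtol 1e-9 with an atol floor of 1e-9 × total PD, because the
  brute-force oracle computes small contributions as differences of large
  sums.
- The acceptance script runs the discovery study at 2000 species in 40
  orders with 100 permutations and 100 null randomizations, the merge
  fixture at 200 species in 12 orders, decline recovery over 100 seeds, and
  null-envelope calibration over 5 seeds — sizes chosen so the whole
  reproduction finishes in seconds while keeping Monte-Carlo error well
  below the effects being measured.
- Name matching between tree tips and tables normalizes whitespace,
  underscores and case; mismatches are hard errors before any computation.

## Known limitations

- The generator's discovery process captures distinctness bias and the
  initial burst but not spatial/regional clustering, body-size effects, or
  time-varying taxonomic effort; conclusions from synthetic calibration
  transfer to real records only insofar as those features do not dominate.
- Missing-group placement transfers a single stem-length ratio; if the
  reference trees disagree strongly about depths near the insertion point
  the clamped stem is only a coarse estimate (topology is still correct).
- The misplaced-species repair intentionally inflates those species'
  pendant lengths; their individual contributions are upper bounds.
- First-passage birth–death conditioning biases internal node ages relative
  to the uniformly conditioned process; use a dedicated simulator if
  unbiased node-age distributions matter.
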