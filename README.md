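# knownpd

**Accumulation of known phylogenetic diversity over the history of species
descriptions.**

How complete is our knowledge of a clade's evolutionary history?  Counting
described species tells only part of the story: two newly described species
may add very different amounts of *phylogenetic diversity* (PD), the sum of
branch lengths of a phylogenetic tree.  `knownpd` reconstructs how *known PD*
— the PD of the subtree spanned by all species formally described up to a
given date — has grown since the start of modern taxonomy in 1758, and asks
whether it has plateaued even while species descriptions continue.  It is
aimed at systematists and macroevolution/conservation researchers with a
time-calibrated, near-complete species-level phylogeny and a table of formal
description years (the motivating case is birds, where both exist).

## What it computes

For a rooted ultrametric tree with branch lengths in Myr and a discovery
record, the marginal contribution of species *i* described at step *k* is

&nbsp;&nbsp;&nbsp;&nbsp;ΔPD*ᵢ* = PD(S*ₖ*) − PD(S*ₖ*₋₁),

where S*ₖ* is the set of the first *k* described species and PD(S) is the
branch-length sum of the subtree spanning S and the root.  Computed forward,
ΔPD*ᵢ* is the path length from tip *i* to its attachment point on the
already-known subtree, so contributions conserve exactly:
Σᵢ ΔPD*ᵢ* = PD(full tree).  Species sharing a description year have no
defined relative order, so within-year order is randomized (100 permutations
by default) and contributions averaged, with 95% bands from empirical
quantiles.  On top of this the package provides:

- **Supertree assembly** (`tree_merge`): graft donor clades into a backbone
  by extract → rescale (stem-to-tip depth matched, edge ratios preserved) →
  replace; insert orders missing from the backbone next to their sister with
  a stem-length ratio transferred from a reference tree; re-attach
  known-misplaced species at their true family's crown as a basal polytomy;
  prune tips not recognized as full species.
- **Counterfactual discovery orders** (`discovery_models`): a null model
  that permutes description years uniformly across species (preserving the
  historical tempo of descriptions), a reversed discovery order, and
  observed − reference difference curves.
- **Trend analysis** (`trend_analysis`): OLS of log mean contribution on
  year or discovery count; the slope *b* is reported as a percent decline
  per unit x of 100·(1 − e^*b*) with a delta-method SE; per-order curves,
  decade × order contribution fractions, the most distinctive species of
  each decade, and the recent mean per-discovery PD increment.
- **Synthetic data** (`synthetic_data`): birth–death time trees partitioned
  into monophyletic orders/families, discovery years with a Linnaean initial
  burst and an optional bias toward evolutionarily distinct species (fair
  proportion), merge fixtures with a planted misplaced species and a
  backbone-omitted order, and a direct log-linear contribution series —
  so every stage runs without external data.

## Worked example

```python
import knownpd as k

cfg = k.SimConfig(n_species=500, n_orders=12, seed=42)
tree = k.simulate_tree(cfg)                     # ultrametric, 100 Myr deep
table = k.assign_discovery_years(tree, cfg)     # species, order, family, year

contribs = k.mean_contributions(tree, table, n_perm=100, seed=42)
year_curve = k.accumulation_curve(contribs, axis="year")
print("total known PD (Myr):", round(contribs.mean.sum(), 1))
print("50% of PD described by:", k.milestone_year(year_curve, 0.5))

fit = k.fit_decline(contribs, x="year")
print(f"decline: {fit.percent_decline:.2f}% per year (SE {fit.percent_decline_se:.2f}%)")

null = k.null_model(tree, table, n_rand=100, seed=42)
diff = k.difference_curve(k.accumulation_curve(contribs, axis="count"), null.count_curve)
q = len(diff.x) // 4
print(f"observed - null PD over the first quarter of discoveries: {diff.mean[:q].mean():.0f} Myr")
print("recent per-discovery PD increment (Myr):", round(k.recent_increment(contribs), 2))
```

prints

```
total known PD (Myr): 8373.0
50% of PD described by: 1797
decline: 1.22% per year (SE 0.05%)
observed - null PD over the first quarter of discoveries: 421 Myr
recent per-discovery PD increment (Myr): 3.58
```

Half of this synthetic clade's PD was already known four decades into the
record, the average contribution of a new description shrinks by about 1.2%
per year, early discoveries run well ahead of a randomized discovery order
(the generator biases early discovery toward distinct species), and recent
descriptions add ~3.6 Myr each — the asymptotic increment a new species
contributes once the tree is essentially known.

A command-line interface mirrors the library:

```sh
knownpd simulate --n-species 500 --seed 42 --out-dir data/
knownpd accumulate --trees data/tree.nwk --species data/species.csv --n-perm 100 --seed 42
knownpd merge --plan plan.yaml --species data/species.csv --out merged.nwk
```

Real data enter as Newick tree files (one tree per line, branch lengths in
Myr) and a CSV with header `species,order,family,year`.

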