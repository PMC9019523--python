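"""Synthetic phylogenies, taxonomies and discovery histories.

The generator emulates the inputs of the historical-PD analysis: a
time-calibrated ultrametric tree whose tips are partitioned into monophyletic
named orders and families, description years spanning the era of modern
taxonomy (default 1758-2013) with a large initial burst of descriptions, and
a discovery process optionally biased toward evolutionarily distinct species.
It also produces fixture sets for the supertree merge (a backbone missing one
order, a family-level reference, a depth-perturbed species-level donor with a
deliberately misplaced species) and a direct log-linear contribution series
for exercising the trend regression.

Tree process: constant-rate birth-death run forward and stopped at the first
passage to ``n_species`` extant lineages (plus a final exponential stretch so
pendant edges are strictly positive), extinct lineages pruned, and the whole
tree rescaled so the root depth equals ``root_age``.  Orders are obtained by
cutting the tree at the deepest internal nodes, which guarantees their
monophyly; families are cut the same way within each order.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .trees import clone, fair_proportion, find_mrca, node_depths, prune_tips, tree_height
from .tree_merge import GraftInstruction, MergePlan, TaxonomyMap

__all__ = [
    "SimConfig",
    "SimulationError",
    "SourceTreeSet",
    "simulate_tree",
    "partition_taxonomy",
    "assign_discovery_years",
    "simulate_decline_series",
    "simulate_source_trees",
]


class SimulationError(Exception):
    """Birth-death conditioning failed after bounded retries."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the avian discovery record the analysis was designed for:
    description years 1758-2013, roughly 5% of species described in the first
    year of modern taxonomy (Linnaeus described ~550 of the ~10 000 birds in
    1758), and a moderate bias of early discovery toward evolutionarily
    distinct species.
    """

    n_species: int = 100
    birth_rate: float = 1.0  # per Myr
    death_rate: float = 0.0  # per Myr
    n_orders: int = 10
    root_age: float = 100.0  # Myr
    year_range: tuple[int, int] = (1758, 2013)
    initial_burst_fraction: float = 0.05
    distinctness_bias: float = 1.0
    decline_rate: float = 0.0077  # per year, for the direct contribution series
    noise_sd: float = 0.5  # log-scale noise of the direct contribution series
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        if not (0 < self.birth_rate < math.inf):
            raise ValueError("birth_rate must be a positive finite rate")
        if not (0 <= self.death_rate < math.inf):
            raise ValueError("death_rate must be a nonnegative finite rate")
        if not (1 <= self.n_orders <= self.n_species):
            raise ValueError("n_orders must be in [1, n_species]")
        if self.root_age <= 0:
            raise ValueError("root_age must be positive")
        if self.year_range[0] >= self.year_range[1]:
            raise ValueError("year_range start must precede end")
        if not (0 <= self.initial_burst_fraction < 1):
            raise ValueError("initial_burst_fraction must be in [0, 1)")
        if self.distinctness_bias < 0:
            raise ValueError("distinctness_bias must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _species_label(i: int) -> str:
    return f"sp{i + 1:04d}"


def simulate_tree(config: SimConfig, max_retries: int = 1000) -> dendropy.Tree:
    """Rooted bifurcating ultrametric tree with ``n_species`` extant tips.

    Deterministic for a fixed config (seed included); tips are labelled
    ``sp0001`` ... in preorder.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_species
    tn = dendropy.TaxonNamespace()

    if n == 1:
        # a pendant edge below the root, so PD equals the species's depth
        tree = dendropy.Tree(taxon_namespace=tn)
        tip = tree.seed_node.new_child(edge_length=config.root_age)
        tip.taxon = tn.require_taxon(label=_species_label(0))
        return tree

    b, d = config.birth_rate, config.death_rate
    for _attempt in range(max_retries):
        root = dendropy.Node()
        alive: list[tuple[dendropy.Node, float]] = []
        extinct: list[dendropy.Node] = []
        t = 0.0
        for _ in range(2):
            child = root.new_child()
            alive.append((child, 0.0))
        failed = False
        while len(alive) < n:
            rate = len(alive) * (b + d)
            t += rng.exponential(1.0 / rate)
            k = int(rng.integers(len(alive)))
            node, t0 = alive.pop(k)
            node.edge.length = t - t0
            if rng.random() < b / (b + d):
                for _ in range(2):
                    alive.append((node.new_child(), t))
            else:
                extinct.append(node)
                if not alive:
                    failed = True
                    break
        if failed:
            continue
        # stretch past the last event so pendant edges are strictly positive
        t_end = t + rng.exponential(1.0 / (len(alive) * (b + d)))
        for node, t0 in alive:
            node.edge.length = t_end - t0

        tree = dendropy.Tree(taxon_namespace=tn)
        tree.seed_node = root
        extinct_leaves = [nd for nd in extinct if nd.is_leaf()]
        for i, nd in enumerate(extinct_leaves):
            nd.taxon = tn.require_taxon(label=f"extinct{i:05d}")
        if extinct_leaves:
            prune_tips(tree, [nd.taxon.label for nd in extinct_leaves])
        leaves = [lf for lf in tree.leaf_node_iter()]
        if len(leaves) != n:
            continue  # pruning collapsed below target (root child died etc.)
        for i, lf in enumerate(tree.leaf_node_iter()):
            lf.taxon = tn.require_taxon(label=_species_label(i))
        height = tree_height(tree)
        factor = config.root_age / height
        for nd in tree.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length = float(nd.edge.length) * factor
        tree.seed_node.edge.length = None
        return tree
    raise SimulationError(
        f"could not condition a birth-death tree on {n} tips after "
        f"{max_retries} attempts (birth_rate={b}, death_rate={d})"
    )


def _cut_into_groups(
    tree: dendropy.Tree,
    root: dendropy.Node,
    k: int,
    depths: dict[dendropy.Node, float],
) -> list[dendropy.Node]:
    """Split the clade under ``root`` into ``k`` subclades by repeatedly
    splitting the clade whose crown is deepest (closest to the root)."""
    counter = 0
    heap: list[tuple[float, int, dendropy.Node]] = [(depths[root], counter, root)]
    final: list[dendropy.Node] = []
    while heap and len(heap) + len(final) < k:
        _, _, node = heapq.heappop(heap)
        if node.is_leaf():
            final.append(node)
            continue
        for child in node.child_nodes():
            counter += 1
            heapq.heappush(heap, (depths[child], counter, child))
    return final + [node for _, _, node in heap]


def partition_taxonomy(tree: dendropy.Tree, n_orders: int) -> pd.DataFrame:
    """Partition tips into monophyletic orders and families.

    Orders come from cutting the tree at the ``n_orders - 1`` deepest
    internal nodes; each order is subdivided into roughly sqrt(size)
    families the same way.  Deterministic for a given tree.
    """
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if not (1 <= n_orders <= n_tips):
        raise ValueError("n_orders must be in [1, n_tips]")
    depths = node_depths(tree)
    preorder_pos = {nd: i for i, nd in enumerate(tree.preorder_node_iter())}
    order_roots = _cut_into_groups(tree, tree.seed_node, n_orders, depths)
    order_roots.sort(key=lambda nd: preorder_pos[nd])
    rows = []
    for oi, oroot in enumerate(order_roots):
        order_name = f"Order{oi + 1:02d}"
        tips = [oroot] if oroot.is_leaf() else list(oroot.leaf_iter())
        k_fam = max(1, int(round(math.sqrt(len(tips)))))
        fam_roots = _cut_into_groups(tree, oroot, k_fam, depths)
        fam_roots.sort(key=lambda nd: preorder_pos[nd])
        for fi, froot in enumerate(fam_roots):
            fam_name = f"Family{oi + 1:02d}_{fi + 1:02d}"
            ftips = [froot] if froot.is_leaf() else list(froot.leaf_iter())
            for lf in ftips:
                rows.append(
                    {
                        "species": lf.taxon.label,
                        "order": order_name,
                        "family": fam_name,
                    }
                )
    frame = pd.DataFrame(rows)
    return frame.sort_values("species", kind="stable").reset_index(drop=True)


def assign_discovery_years(tree: dendropy.Tree, config: SimConfig) -> pd.DataFrame:
    """Assign a formal-description year to every tip.

    Discovery order is a weighted draw without replacement with weight
    proportional to exp(distinctness_bias x standardized fair-proportion
    distinctness); the first ``initial_burst_fraction`` of the order is dated
    to the first year (the Linnaean burst) and the remainder to years drawn
    uniformly over the rest of the range, sorted so earlier draws get earlier
    years.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 202])
    taxonomy = partition_taxonomy(tree, config.n_orders)
    species = taxonomy["species"].to_numpy()
    n = len(species)

    ed = fair_proportion(tree)
    ed_vals = np.array([ed[s] for s in species], dtype=float)
    sd = ed_vals.std()
    z = (ed_vals - ed_vals.mean()) / sd if sd > 0 else np.zeros(n)

    # Gumbel-max trick: exact exponential-weight sampling without replacement
    keys = config.distinctness_bias * z + rng.gumbel(size=n)
    discovery_order = np.argsort(-keys, kind="stable")

    y0, y1 = config.year_range
    k_burst = int(round(config.initial_burst_fraction * n))
    years_in_order = np.empty(n, dtype=int)
    years_in_order[:k_burst] = y0
    n_rest = n - k_burst
    if n_rest > 0:
        rest = np.sort(rng.integers(y0 + 1, y1 + 1, size=n_rest))
        years_in_order[k_burst:] = rest
    years = np.empty(n, dtype=int)
    years[discovery_order] = years_in_order

    out = taxonomy.copy()
    out["year"] = years
    return out


def simulate_decline_series(
    config: SimConfig, initial_contribution: float = 100.0
) -> pd.DataFrame:
    """Direct log-linear contribution series (no tree).

    log c(t) = log c0 - decline_rate * (t - t0) + Normal(0, noise_sd), with
    years uniform over the configured range.  Used to exercise the trend
    regression with a known generating decline rate.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 303])
    y0, y1 = config.year_range
    years = rng.integers(y0, y1 + 1, size=config.n_species)
    logc = (
        math.log(initial_contribution)
        - config.decline_rate * (years - y0)
        + rng.normal(0.0, config.noise_sd, size=config.n_species)
    )
    return pd.DataFrame(
        {
            "species": [_species_label(i) for i in range(config.n_species)],
            "year": years,
            "contribution": np.exp(logc),
        }
    )


@dataclass
class SourceTreeSet:
    """Fixture set for the supertree merge.

    ``backbone`` is an order-level placeholder tree missing ``omitted_order``;
    ``family_tree`` is a family-level reference containing every order (depths
    scaled by 0.7); ``species_donor`` is the full species tree with depths
    scaled by 1.6 and one species moved outside its family.  Merging with
    ``plan`` should recover ``truth``'s topology on the unperturbed tips.
    """

    truth: dendropy.Tree
    taxonomy: pd.DataFrame
    backbone: dendropy.Tree
    family_tree: dendropy.Tree
    species_donor: dendropy.Tree
    misplaced: pd.DataFrame
    omitted_order: str
    plan: MergePlan = field(default=None)

    @property
    def trees(self) -> dict:
        return {
            "backbone": self.backbone,
            "family": self.family_tree,
            "species": self.species_donor,
        }


def _collapse_groups(tree: dendropy.Tree, groups: dict[str, list[str]]) -> dendropy.Tree:
    """Replace each group's clade by a placeholder tip at the present whose
    pendant length is the group's stem-to-tip depth."""
    work = clone(tree)
    height = tree_height(work)
    for name, taxa in groups.items():
        depths = node_depths(work)
        crown = find_mrca(work, taxa)
        crown_age = height - depths[crown]
        if not crown.is_leaf():
            for child in list(crown.child_nodes()):
                crown.remove_child(child)
        crown.taxon = work.taxon_namespace.require_taxon(label=name)
        crown.edge.length = float(crown.edge.length or 0.0) + crown_age
    return work


def _scale_edges(tree: dendropy.Tree, factor: float) -> dendropy.Tree:
    out = clone(tree)
    for nd in out.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length = float(nd.edge.length) * factor
    return out


def simulate_source_trees(config: SimConfig) -> SourceTreeSet:
    """Backbone + donor trees whose merge should recover the truth tree.

    The backbone omits one order (exercising missing-group placement from
    the reference trees, the way unrepresented orders are inserted next to
    their sister with a transferred stem ratio), and the species-level donor
    carries one deliberately misplaced species (exercising non-monophyly
    repair).  Donor depths are deliberately perturbed by global factors to
    exercise rescaling.
    """
    config.validate()
    if config.n_orders < 2:
        raise ValueError("simulate_source_trees requires n_orders >= 2")
    truth = simulate_tree(config)
    taxonomy = partition_taxonomy(truth, config.n_orders)
    taxmap = TaxonomyMap(taxonomy)

    order_groups = {
        o: taxmap.species_in(o, "order") for o in taxmap.orders
    }
    family_groups = {
        f: taxmap.species_in(f, "family") for f in taxmap.families
    }

    backbone = _collapse_groups(truth, order_groups)
    # omit the smallest order whose placeholder is not attached at the root
    # (an order at the root has no sister stem to transfer a ratio onto)
    order_sizes = taxonomy.groupby("order")["species"].count()
    eligible = [
        lf.taxon.label
        for lf in backbone.leaf_node_iter()
        if lf.parent_node is not backbone.seed_node
    ]
    if not eligible:
        raise SimulationError(
            "no order can be omitted: all orders attach at the backbone root"
        )
    omitted = min(eligible, key=lambda o: (order_sizes[o], o))
    prune_tips(backbone, [omitted])
    family_tree = _scale_edges(_collapse_groups(truth, family_groups), 0.7)

    # misplaced species: first family (by name) with >= 3 species, not in the
    # omitted order; host tip from a different order
    fam_sizes = taxonomy.groupby("family")["species"].count()
    candidates = [
        f
        for f in sorted(fam_sizes.index)
        if fam_sizes[f] >= 3 and taxmap.family_to_order[f] != omitted
    ]
    misplaced_frame = pd.DataFrame(columns=["species", "true_family"])
    donor = _scale_edges(truth, 1.6)
    if candidates:
        fam = candidates[0]
        species = sorted(family_groups[fam])[0]
        home_order = taxmap.family_to_order[fam]
        host_orders = [
            o for o in taxmap.orders if o not in (home_order, omitted)
        ]
        if host_orders:
            host = sorted(order_groups[host_orders[0]])[0]
            prune_tips(donor, [species])
            host_node = next(
                lf for lf in donor.leaf_node_iter() if lf.taxon.label == host
            )
            pendant = float(host_node.edge.length)
            parent = host_node.parent_node
            parent.remove_child(host_node)
            joint = parent.new_child(edge_length=pendant / 2.0)
            joint.add_child(host_node)
            host_node.edge.length = pendant / 2.0
            taxon = donor.taxon_namespace.require_taxon(label=species)
            joint.new_child(taxon=taxon, edge_length=pendant / 2.0)
            misplaced_frame = pd.DataFrame(
                [{"species": species, "true_family": fam}]
            )

    plan = MergePlan(
        backbone="backbone",
        grafts=[GraftInstruction(donor="species", group=o, level="order") for o in taxmap.orders],
        missing_policy={
            "reference_topology": "family",
            "reference_lengths": "species",
        },
    )
    return SourceTreeSet(
        truth=truth,
        taxonomy=taxonomy,
        backbone=backbone,
        family_tree=family_tree,
        species_donor=donor,
        misplaced=misplaced_frame,
        omitted_order=omitted,
        plan=plan,
    )
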