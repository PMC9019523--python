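"""Supertree assembly by clade extraction, rescaling and grafting.

A species-level time tree is assembled from a backbone tree (which fixes the
relationships *between* higher groups such as orders) and one or more donor
trees (which supply the relationships *within* those groups).  For each group
the donor clade is extracted together with its stem edge, linearly rescaled so
its stem-to-tip depth matches the depth of the group's representative in the
backbone, and grafted in place of that representative.  Because grafting is
depth-preserving, merging ultrametric inputs yields an ultrametric supertree.

Two repair steps handle the usual imperfections of real donor trees: groups
absent from the backbone are inserted next to their sister group with a stem
length transferred as a ratio from a reference tree, and species known to be
misplaced in a donor are excluded from extraction and re-attached at the crown
of their correct family as a basal polytomy, with a pendant edge equal to the
family's crown age (the maximum length that keeps the species inside the
family crown while remaining at the present).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .trees import (
    clone,
    find_mrca,
    leaf_names,
    node_depths,
    prune_tips,
    tree_height,
)

__all__ = [
    "TreeMergeError",
    "MonophylyError",
    "DegenerateCladeError",
    "PlacementError",
    "RepairError",
    "EmptyTreeError",
    "MergeError",
    "TaxonomyMap",
    "MisplacedList",
    "GraftInstruction",
    "MergePlan",
    "extract_clade",
    "rescale_clade",
    "graft_clade",
    "place_missing_groups",
    "repair_nonmonophyly",
    "reconcile_taxonomy",
    "run_merge",
]


class TreeMergeError(Exception):
    """Base class for merge failures."""


class MonophylyError(TreeMergeError):
    def __init__(self, taxa: Iterable[str], intruders: Iterable[str]):
        self.intruders = sorted(intruders)
        super().__init__(
            "requested taxa are not monophyletic; intruding tips: "
            + ", ".join(self.intruders)
        )


class DegenerateCladeError(TreeMergeError):
    pass


class PlacementError(TreeMergeError):
    pass


class RepairError(TreeMergeError):
    pass


class EmptyTreeError(TreeMergeError):
    pass


class MergeError(TreeMergeError):
    """A component operation failed; the message names the graft step."""


class TaxonomyMap:
    """Species -> (family, order) lookup plus the recognized-species set."""

    def __init__(self, frame: pd.DataFrame):
        required = {"species", "order", "family"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
        if frame["species"].duplicated().any():
            dups = frame.loc[frame["species"].duplicated(), "species"].tolist()
            raise ValueError(f"duplicate species in taxonomy: {dups}")
        self.frame = frame.reset_index(drop=True)
        self.species_to_family = dict(zip(frame["species"], frame["family"]))
        self.species_to_order = dict(zip(frame["species"], frame["order"]))
        self.family_to_order = dict(zip(frame["family"], frame["order"]))
        self.recognized = set(frame["species"])
        self.orders = list(dict.fromkeys(frame["order"]))
        self.families = list(dict.fromkeys(frame["family"]))

    def species_in(self, group: str, level: str) -> list[str]:
        if level == "order":
            return [s for s, o in self.species_to_order.items() if o == group]
        if level == "family":
            return [s for s, f in self.species_to_family.items() if f == group]
        raise ValueError(f"unknown level {level!r}")

    def group_of_tip(self, label: str, level: str) -> str | None:
        """Group a tip label belongs to: a species, a family placeholder, or
        the group's own placeholder name."""
        if label in self.recognized:
            if level == "order":
                return self.species_to_order[label]
            return self.species_to_family[label]
        if level == "order" and label in self.family_to_order:
            return self.family_to_order[label]
        if level == "order" and label in self.orders:
            return label
        if level == "family" and label in self.families:
            return label
        return None


@dataclass
class MisplacedList:
    """Species known to sit outside their true family in a donor tree."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MisplacedList":
        return cls(list(zip(frame["species"], frame["true_family"])))

    @property
    def species(self) -> set[str]:
        return {s for s, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class GraftInstruction:
    donor: str
    group: str
    level: str = "order"


@dataclass
class MergePlan:
    backbone: str
    grafts: list[GraftInstruction] = field(default_factory=list)
    missing_policy: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping) -> "MergePlan":
        grafts = [GraftInstruction(**g) for g in d.get("grafts", [])]
        return cls(
            backbone=d["backbone"],
            grafts=grafts,
            missing_policy=dict(d.get("missing_policy", {})),
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def extract_clade(
    tree: dendropy.Tree,
    taxa: Iterable[str],
    prune_intruders: Iterable[str] = (),
) -> dendropy.Tree:
    """Extract the subtree spanning ``taxa`` together with its stem edge.

    ``taxa`` must be monophyletic in ``tree``, except for tips listed in
    ``prune_intruders`` (known-misplaced species), which are silently removed
    from the extracted clade.  The input tree is not modified.  The returned
    tree's seed edge carries the stem length (0 when the clade is the whole
    tree).
    """
    taxa = set(taxa)
    if not taxa:
        raise ValueError("taxa set is empty")
    mrca = find_mrca(tree, taxa)
    under = {lf.taxon.label for lf in mrca.leaf_iter()} if not mrca.is_leaf() else {
        mrca.taxon.label
    }
    intruders = under - taxa
    unforgiven = intruders - set(prune_intruders)
    if unforgiven:
        raise MonophylyError(taxa, unforgiven)

    work = clone(tree)
    mrca_c = find_mrca(work, taxa)
    stem = mrca_c.edge.length if mrca_c.edge.length is not None else 0.0
    parent = mrca_c.parent_node
    if parent is not None:
        parent.remove_child(mrca_c)
    sub = dendropy.Tree(taxon_namespace=work.taxon_namespace)
    sub.seed_node = mrca_c
    sub.seed_node.edge.length = float(stem)
    if intruders:
        prune_tips(sub, intruders)
    return sub


def clade_depth(clade: dendropy.Tree) -> float:
    """Stem-to-tip depth: stem edge plus the deepest root-to-tip path."""
    return tree_height(clade, include_stem=True)


def rescale_clade(clade: dendropy.Tree, target_depth: float) -> dendropy.Tree:
    """Multiply every edge (stem included) so the stem-to-tip depth becomes
    ``target_depth``; edge-length ratios are preserved exactly."""
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    depth = clade_depth(clade)
    if depth <= 0:
        raise DegenerateCladeError("clade has zero stem-to-tip depth")
    factor = target_depth / depth
    out = clone(clade)
    for node in out.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length = float(node.edge.length) * factor
    if out.seed_node.edge.length is None:
        out.seed_node.edge.length = 0.0
    return out


def _resolve_attach_node(tree: dendropy.Tree, attach) -> dendropy.Node:
    if isinstance(attach, str):
        for lf in tree.leaf_node_iter():
            if lf.taxon.label == attach:
                return lf
        raise LookupError(f"attach tip {attach!r} not found in backbone")
    # an iterable of tip labels -> the MRCA of those tips
    try:
        return find_mrca(tree, attach)
    except KeyError as exc:
        raise LookupError(str(exc)) from exc


def graft_clade(backbone: dendropy.Tree, attach, clade: dendropy.Tree) -> dendropy.Tree:
    """Replace the backbone subtree identified by ``attach`` with ``clade``.

    ``attach`` is a tip label (placeholder) or an iterable of tip labels
    (replaced by their MRCA's subtree).  The clade's stem edge becomes the
    new connecting edge.  Returns a new tree; inputs are unmodified.
    """
    work = clone(backbone)
    node = _resolve_attach_node(work, attach)
    parent = node.parent_node
    if parent is None:
        raise LookupError("cannot replace the backbone root")
    incoming = clone(clade)
    child = incoming.seed_node
    stem = child.edge.length if child.edge.length is not None else 0.0
    parent.remove_child(node)
    parent.add_child(child)
    child.edge.length = float(stem)
    # unify taxa into the backbone's namespace
    work.migrate_taxon_namespace(work.taxon_namespace)
    return work


def place_missing_groups(
    backbone: dendropy.Tree,
    reference_a: dendropy.Tree,
    reference_b: dendropy.Tree,
    missing: Iterable[str],
    taxonomy: TaxonomyMap,
    level: str = "order",
    exclude: Iterable[str] = (),
) -> dendropy.Tree:
    """Insert groups absent from the backbone next to their sister group.

    ``reference_a`` donates the topology (which clade is the missing group's
    sister); ``reference_b`` donates relative stem lengths: the inserted
    group's stem is set so that (missing stem)/(sister stem measured on the
    backbone before insertion) equals the same stem-length ratio in
    ``reference_b``.  The group enters as a single placeholder tip reaching
    the present; grafting its species-level clade afterwards expands it.
    Tips named in ``exclude`` (known-misplaced species) are ignored when
    locating groups in the reference trees.
    """
    excluded = set(exclude)
    work = clone(backbone)
    for group in missing:

        def tips_of(tree: dendropy.Tree, g: str) -> list[str]:
            return [
                nm
                for nm in leaf_names(tree)
                if nm not in excluded and taxonomy.group_of_tip(nm, level) == g
            ]

        ga = tips_of(reference_a, group)
        gb = tips_of(reference_b, group)
        if not ga or not gb:
            raise PlacementError(
                f"missing group {group!r} absent from a reference tree"
            )
        mrca_a = find_mrca(reference_a, ga)
        parent_a = mrca_a.parent_node
        if parent_a is None:
            raise PlacementError(f"group {group!r} spans reference_a entirely")
        sister_tips_a = [
            lf.taxon.label
            for ch in parent_a.child_nodes()
            if ch is not mrca_a
            for lf in (ch.leaf_iter() if not ch.is_leaf() else [ch])
        ]
        sister_groups = {
            taxonomy.group_of_tip(nm, level)
            for nm in sister_tips_a
            if nm not in excluded
        } - {None, group}
        if not sister_groups:
            raise PlacementError(f"no resolvable sister group for {group!r}")

        sister_tips_backbone = [
            nm
            for nm in leaf_names(work)
            if nm not in excluded
            and taxonomy.group_of_tip(nm, level) in sister_groups
        ]
        if not sister_tips_backbone:
            raise PlacementError(
                f"sister group of {group!r} not present in backbone"
            )
        sister_node = find_mrca(work, sister_tips_backbone)
        if sister_node.parent_node is None:
            raise PlacementError(
                f"sister group of {group!r} is the whole backbone"
            )
        sister_stem_backbone = float(sister_node.edge.length or 0.0)
        if sister_stem_backbone <= 0:
            raise PlacementError(f"sister of {group!r} has no stem in backbone")

        sister_tips_b = [
            nm
            for nm in leaf_names(reference_b)
            if nm not in excluded
            and taxonomy.group_of_tip(nm, level) in sister_groups
        ]
        if not sister_tips_b:
            raise PlacementError(
                f"sister group of {group!r} not present in reference_b"
            )
        mrca_gb = find_mrca(reference_b, gb)
        mrca_sb = find_mrca(reference_b, sister_tips_b)
        stem_g = float(mrca_gb.edge.length or 0.0)
        stem_s = float(mrca_sb.edge.length or 0.0)
        if stem_s <= 0:
            raise PlacementError(
                f"sister of {group!r} has no stem in reference_b"
            )
        ratio = stem_g / stem_s

        # insert a node on the sister's stem at age (= missing stem length)
        # ratio * sister stem, clamped to the open interval between the
        # sister's crown age and its stem parent's age
        height = tree_height(work)
        depths = node_depths(work)
        sister_crown_age = height - depths[sister_node]
        parent_age = height - depths[sister_node.parent_node]
        eps = 1e-9 * height
        attach_age = ratio * sister_stem_backbone
        attach_age = min(max(attach_age, sister_crown_age + eps), parent_age - eps)
        if not (sister_crown_age < attach_age < parent_age):
            raise PlacementError(
                f"cannot place {group!r}: degenerate stem interval"
            )

        parent = sister_node.parent_node
        parent.remove_child(sister_node)
        joint = parent.new_child(edge_length=parent_age - attach_age)
        joint.add_child(sister_node)
        sister_node.edge.length = attach_age - sister_crown_age
        taxon = work.taxon_namespace.require_taxon(label=group)
        joint.new_child(taxon=taxon, edge_length=attach_age)
    return work


def repair_nonmonophyly(
    tree: dendropy.Tree,
    taxonomy: TaxonomyMap,
    misplaced: MisplacedList,
) -> dendropy.Tree:
    """Re-attach known-misplaced species at their true family's crown.

    Each misplaced species is detached (if present) and re-attached as an
    additional child of its target family's crown node — extending it into a
    polytomy — with pendant length equal to the family's crown age, so the
    tip stays at the present.  For a monotypic target family the species is
    attached as the sister of the family's single tip at half its pendant
    depth.
    """
    if not misplaced.pairs:
        return clone(tree)
    work = clone(tree)
    present = set(leaf_names(work))
    to_detach = [s for s, _ in misplaced.pairs if s in present]
    if to_detach:
        prune_tips(work, to_detach)
    height = tree_height(work)
    for species, family in misplaced.pairs:
        members = [
            nm
            for nm in leaf_names(work)
            if taxonomy.species_to_family.get(nm) == family
        ]
        if not members:
            raise RepairError(
                f"target family {family!r} absent from tree; cannot re-attach "
                f"{species!r}"
            )
        depths = node_depths(work)
        crown = find_mrca(work, members)
        taxon = work.taxon_namespace.require_taxon(label=species)
        if crown.is_leaf():
            # monotypic family: make a cherry at half the pendant depth
            pendant = float(crown.edge.length or 0.0)
            parent = crown.parent_node
            if parent is None or pendant <= 0:
                raise RepairError(
                    f"cannot attach {species!r} to monotypic family {family!r}"
                )
            parent.remove_child(crown)
            joint = parent.new_child(edge_length=pendant / 2.0)
            joint.add_child(crown)
            crown.edge.length = pendant / 2.0
            joint.new_child(taxon=taxon, edge_length=pendant / 2.0)
        else:
            crown_age = height - depths[crown]
            crown.new_child(taxon=taxon, edge_length=crown_age)
    return work


def reconcile_taxonomy(
    tree: dendropy.Tree, taxonomy: TaxonomyMap
) -> tuple[dendropy.Tree, dict[str, list[str]]]:
    """Drop tips not recognized as full species; report what changed.

    Returns the pruned tree (degree-2 nodes suppressed, edge lengths summed)
    and a report with ``dropped`` (tips removed) and ``missing`` (recognized
    species absent from the tree).
    """
    tips = leaf_names(tree)
    dropped = [t for t in tips if t not in taxonomy.recognized]
    missing = sorted(taxonomy.recognized - set(tips))
    if len(dropped) == len(tips):
        raise EmptyTreeError("reconciliation would drop every tip")
    out = clone(tree)
    if dropped:
        prune_tips(out, dropped)
    return out, {"dropped": sorted(dropped), "missing": missing}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _donor_sample(trees, name: str, sample: int):
    entry = trees[name]
    if isinstance(entry, (list, tuple)):
        return entry[sample % len(entry)]
    return entry


def run_merge(
    plan: MergePlan,
    trees: Mapping[str, dendropy.Tree | Sequence[dendropy.Tree]],
    taxonomy: TaxonomyMap,
    misplaced: MisplacedList | None = None,
) -> list[dendropy.Tree]:
    """Execute a merge plan; one merged tree per species-level donor sample.

    ``trees`` maps tree ids to a tree or, for sampled donors, a list of
    trees; the output list length is the longest donor list (1 when all
    donors are single trees).  All outputs share the backbone-determined
    structure between groups and differ only within groups.
    """
    if misplaced is None:
        misplaced = MisplacedList()
    backbone = trees[plan.backbone]
    if isinstance(backbone, (list, tuple)):
        raise ValueError("the backbone must be a single tree")
    n_samples = 1
    for g in plan.grafts:
        entry = trees[g.donor]
        if isinstance(entry, (list, tuple)):
            n_samples = max(n_samples, len(entry))

    misnames = misplaced.species
    merged: list[dendropy.Tree] = []
    for sample in range(n_samples):
        work = clone(backbone)

        # groups in the plan but absent from the backbone get placed first
        present_groups = set()
        for g in plan.grafts:
            for nm in leaf_names(work):
                if taxonomy.group_of_tip(nm, g.level) == g.group:
                    present_groups.add(g.group)
                    break
        absent = [g for g in plan.grafts if g.group not in present_groups]
        if absent:
            policy = plan.missing_policy
            try:
                ref_a = _donor_sample(trees, policy["reference_topology"], sample)
                ref_b = _donor_sample(trees, policy["reference_lengths"], sample)
            except KeyError as exc:
                raise MergeError(
                    f"groups {[g.group for g in absent]} absent from backbone "
                    f"and no missing-group policy given"
                ) from exc
            work = place_missing_groups(
                work,
                ref_a,
                ref_b,
                [g.group for g in absent],
                taxonomy,
                level=absent[0].level,
                exclude=misnames,
            )

        for g in plan.grafts:
            try:
                donor = _donor_sample(trees, g.donor, sample)
                taxa = [
                    nm
                    for nm in leaf_names(donor)
                    if taxonomy.group_of_tip(nm, g.level) == g.group
                    and nm not in misnames
                ]
                if not taxa:
                    raise MergeError(
                        f"donor {g.donor!r} has no usable tips for {g.group!r}"
                    )
                # attach point: the group's placeholder tip if still present,
                # else the MRCA of its tips in the working tree
                work_tips = set(leaf_names(work))
                if g.group in work_tips:
                    attach = g.group
                    target_node = _resolve_attach_node(work, g.group)
                else:
                    members = [
                        nm
                        for nm in work_tips
                        if taxonomy.group_of_tip(nm, g.level) == g.group
                    ]
                    attach = members
                    target_node = find_mrca(work, members)
                stem = float(target_node.edge.length or 0.0)
                if target_node.is_leaf():
                    target_depth = stem
                else:
                    sub_h = max(
                        node_depths(work)[lf] for lf in target_node.leaf_iter()
                    ) - node_depths(work)[target_node]
                    target_depth = stem + sub_h
                extracted = extract_clade(donor, taxa, prune_intruders=misnames)
                rescaled = rescale_clade(extracted, target_depth)
                work = graft_clade(work, attach, rescaled)
            except TreeMergeError as exc:
                raise MergeError(f"graft step {g.group!r}: {exc}") from exc

        if misplaced.pairs:
            work = repair_nonmonophyly(work, taxonomy, misplaced)
        work, _report = reconcile_taxonomy(work, taxonomy)
        merged.append(work)
    return merged
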