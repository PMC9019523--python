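import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.calculate import treecompare

from knownpd import (
    MergePlan,
    MisplacedList,
    SimConfig,
    TaxonomyMap,
    extract_clade,
    graft_clade,
    place_missing_groups,
    reconcile_taxonomy,
    repair_nonmonophyly,
    rescale_clade,
    run_merge,
    simulate_source_trees,
)
from knownpd.tree_merge import (
    EmptyTreeError,
    MonophylyError,
    clade_depth,
)
from knownpd.trees import (
    find_mrca,
    is_ultrametric,
    leaf_names,
    node_depths,
    parse_newick,
    to_newick,
    tree_height,
)


def rf_distance(newick_a: str, newick_b: str, restrict_to=None) -> int:
    """Independent Robinson-Foulds via dendropy's treecompare."""
    tn = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(
        data=newick_a, schema="newick", preserve_underscores=True, taxon_namespace=tn
    )
    tb = dendropy.Tree.get(
        data=newick_b, schema="newick", preserve_underscores=True, taxon_namespace=tn
    )
    if restrict_to is not None:
        ta.retain_taxa_with_labels(list(restrict_to))
        tb.retain_taxa_with_labels(list(restrict_to))
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)


class TestExtractClade:
    def test_subtree_with_stem(self, worked_tree):
        sub = extract_clade(worked_tree, {"A", "B"})
        assert set(leaf_names(sub)) == {"A", "B"}
        assert sub.seed_node.edge.length == pytest.approx(2.0)
        assert clade_depth(sub) == pytest.approx(3.0)
        # original untouched
        assert len(leaf_names(worked_tree)) == 3

    def test_extract_all_tips_has_zero_stem(self, worked_tree):
        sub = extract_clade(worked_tree, {"A", "B", "C"})
        assert set(leaf_names(sub)) == {"A", "B", "C"}
        assert sub.seed_node.edge.length == 0.0

    def test_nonmonophyletic_names_intruder(self):
        tree = parse_newick("((A:1,C:1):2,B:3);")
        with pytest.raises(MonophylyError) as exc:
            extract_clade(tree, {"A", "B"})
        assert "C" in str(exc.value)

    def test_known_intruders_are_pruned(self):
        tree = parse_newick("(((A:1,X:1):1,B:2):2,C:4);")
        sub = extract_clade(tree, {"A", "B"}, prune_intruders={"X"})
        assert set(leaf_names(sub)) == {"A", "B"}


class TestRescaleClade:
    def test_halving(self, worked_tree):
        sub = extract_clade(worked_tree, {"A", "B"})  # depth 3
        out = rescale_clade(sub, 1.5)
        assert clade_depth(out) == pytest.approx(1.5)
        assert out.seed_node.edge.length == pytest.approx(1.0)

    def test_identity_when_target_equals_depth(self, worked_tree):
        sub = extract_clade(worked_tree, {"A", "B"})
        out = rescale_clade(sub, clade_depth(sub))
        assert to_newick(out) == to_newick(sub)

    def test_worked_doubling(self):
        clade = parse_newick("(A:1,B:1):2;")
        clade.seed_node.edge.length = 2.0
        out = rescale_clade(clade, 6.0)
        depths = node_depths(out, include_stem=True)
        tips = {lf.taxon.label: depths[lf] for lf in out.leaf_node_iter()}
        assert tips == {"A": pytest.approx(6.0), "B": pytest.approx(6.0)}
        assert out.seed_node.edge.length == pytest.approx(4.0)

    def test_edge_ratios_preserved(self):
        rng = np.random.default_rng(0)
        tree = parse_newick("((A:1.3,B:0.7):2.1,(C:0.4,D:3.3):0.9):0.5;")
        before = [
            nd.edge.length
            for nd in tree.preorder_node_iter()
            if nd.edge.length is not None
        ]
        for target in rng.uniform(0.1, 50, size=5):
            out = rescale_clade(tree, target)
            after = [
                nd.edge.length
                for nd in out.preorder_node_iter()
                if nd.edge.length is not None
            ]
            ratios = np.array(after) / np.array(before)
            np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)


class TestGraftClade:
    def test_replacing_placeholder_keeps_ultrametricity(self):
        backbone = parse_newick("((X:5,B:5):5,C:10);")
        clade = parse_newick("(P:2,Q:2):3;")
        clade.seed_node.edge.length = 3.0  # stem-to-tip depth 5
        out = graft_clade(backbone, "X", clade)
        assert set(leaf_names(out)) == {"P", "Q", "B", "C"}
        assert is_ultrametric(out, 1e-9)

    def test_graft_then_extract_round_trip(self):
        backbone = parse_newick("((X:5,B:5):5,C:10);")
        clade = parse_newick("(P:2,Q:2):3;")
        clade.seed_node.edge.length = 3.0
        out = graft_clade(backbone, "X", clade)
        back = extract_clade(out, {"P", "Q"})
        assert to_newick(back) == to_newick(clade)

    def test_one_tip_clade_is_a_renaming(self):
        backbone = parse_newick("((X:5,B:5):5,C:10);")
        single = extract_clade(parse_newick("(P:5,Q:5);"), {"P"})
        assert single.seed_node.edge.length == pytest.approx(5.0)
        out = graft_clade(backbone, "X", single)
        assert set(leaf_names(out)) == {"P", "B", "C"}
        assert rf_distance(to_newick(out), "((P:5,B:5):5,C:10);") == 0

    def test_unknown_attach_tip_errors(self):
        backbone = parse_newick("((X:5,B:5):5,C:10);")
        with pytest.raises(LookupError):
            graft_clade(backbone, "nope", parse_newick("(P:1,Q:1):1;"))


def three_order_taxonomy():
    return TaxonomyMap(
        pd.DataFrame(
            {
                "species": ["x1", "s1", "o1"],
                "order": ["X", "S", "O"],
                "family": ["FX", "FS", "FO"],
            }
        )
    )


class TestPlaceMissingGroups:
    def test_direct_ratio(self):
        taxonomy = three_order_taxonomy()
        backbone = parse_newick("(S:4,O:4);")
        ref_a = parse_newick("((X:1,S:1):1,O:2);")
        ref_b = parse_newick("((X:2,S:4):1,O:5);")  # stem ratio X/S = 0.5
        out = place_missing_groups(backbone, ref_a, ref_b, ["X"], taxonomy)
        tips = {lf.taxon.label: lf for lf in out.leaf_node_iter()}
        assert tips["X"].edge.length == pytest.approx(2.0)  # 0.5 * 4
        assert is_ultrametric(out, 1e-9)
        # X sits as sister to S
        parent = tips["X"].parent_node
        assert {c.taxon.label for c in parent.child_nodes()} == {"X", "S"}

    def test_empty_missing_set_is_identity(self):
        taxonomy = three_order_taxonomy()
        backbone = parse_newick("(S:4,O:4);")
        out = place_missing_groups(
            backbone, backbone, backbone, [], taxonomy
        )
        assert to_newick(out) == to_newick(backbone)


class TestRepairNonmonophyly:
    def test_pendant_equals_family_crown_age(self):
        # family F = {A,B} with crown age 8; M belongs to F but sits outside
        tree = parse_newick("(((A:8,B:8):4,M:12):3,C:15);")
        taxonomy = TaxonomyMap(
            pd.DataFrame(
                {
                    "species": ["A", "B", "M", "C"],
                    "order": ["O1", "O1", "O1", "O2"],
                    "family": ["F", "F", "F", "G"],
                }
            )
        )
        out = repair_nonmonophyly(tree, taxonomy, MisplacedList([("M", "F")]))
        tips = {lf.taxon.label: lf for lf in out.leaf_node_iter()}
        assert tips["M"].edge.length == pytest.approx(8.0)
        depths = node_depths(out)
        assert depths[tips["M"]] == pytest.approx(15.0)  # still at the present
        crown = find_mrca(out, {"A", "B", "M"})
        assert {lf.taxon.label for lf in crown.leaf_iter()} == {"A", "B", "M"}

    def test_empty_list_is_identity(self, worked_tree):
        taxonomy = TaxonomyMap(
            pd.DataFrame(
                {
                    "species": ["A", "B", "C"],
                    "order": ["O", "O", "O"],
                    "family": ["F", "F", "F"],
                }
            )
        )
        out = repair_nonmonophyly(worked_tree, taxonomy, MisplacedList())
        assert to_newick(out) == to_newick(worked_tree)

    def test_fixture_repair_restores_monophyly_of_every_family(self):
        src = simulate_source_trees(SimConfig(n_species=90, n_orders=6, seed=12))
        taxmap = TaxonomyMap(src.taxonomy)
        mis = MisplacedList.from_frame(src.misplaced)
        repaired = repair_nonmonophyly(src.species_donor, taxmap, mis)
        for fam, grp in src.taxonomy.groupby("family"):
            taxa = set(grp["species"])
            mrca = find_mrca(repaired, taxa)
            under = (
                {mrca.taxon.label}
                if mrca.is_leaf()
                else {lf.taxon.label for lf in mrca.leaf_iter()}
            )
            assert under == taxa, f"family {fam} not monophyletic after repair"


class TestReconcileTaxonomy:
    def taxonomy(self, species):
        return TaxonomyMap(
            pd.DataFrame(
                {
                    "species": species,
                    "order": ["O"] * len(species),
                    "family": ["F"] * len(species),
                }
            )
        )

    def test_no_unrecognized_tips_is_identity(self, worked_tree):
        out, report = reconcile_taxonomy(worked_tree, self.taxonomy(["A", "B", "C"]))
        assert to_newick(out) == to_newick(worked_tree)
        assert report == {"dropped": [], "missing": []}

    def test_drop_merges_path_lengths(self, worked_tree):
        out, report = reconcile_taxonomy(worked_tree, self.taxonomy(["A", "C"]))
        assert report["dropped"] == ["B"]
        depths = node_depths(out)
        tips = {lf.taxon.label: depths[lf] for lf in out.leaf_node_iter()}
        assert tips == {"A": pytest.approx(3.0), "C": pytest.approx(3.0)}
        # A's pendant 1 and the internal edge 2 were summed
        a = next(lf for lf in out.leaf_node_iter() if lf.taxon.label == "A")
        assert a.edge.length == pytest.approx(3.0)

    def test_missing_species_reported(self, worked_tree):
        out, report = reconcile_taxonomy(
            worked_tree, self.taxonomy(["A", "B", "C", "D"])
        )
        assert report["missing"] == ["D"]

    def test_all_tips_dropped_errors(self, worked_tree):
        with pytest.raises(EmptyTreeError):
            reconcile_taxonomy(worked_tree, self.taxonomy(["Z"]))

    def test_pairwise_path_lengths_preserved(self):
        tree = parse_newick("(((A:1,B:2):3,(C:4,D:1):2):1,(E:5,F:2):3);")

        def path(t, a, b):
            d = node_depths(t)
            tips = {lf.taxon.label: lf for lf in t.leaf_node_iter()}
            m = find_mrca(t, {a, b})
            return d[tips[a]] + d[tips[b]] - 2 * d[m]

        keep = ["A", "C", "E"]
        before = {
            (a, b): path(tree, a, b)
            for a in keep
            for b in keep
            if a < b
        }
        out, _ = reconcile_taxonomy(tree, self.taxonomy(keep))
        for (a, b), v in before.items():
            assert path(out, a, b) == pytest.approx(v, rel=1e-12)


@pytest.fixture(scope="module")
def src():
    return simulate_source_trees(SimConfig(n_species=110, n_orders=7, seed=3))


@pytest.fixture(scope="module")
def merged(src):
    taxmap = TaxonomyMap(src.taxonomy)
    mis = MisplacedList.from_frame(src.misplaced)
    return run_merge(src.plan, src.trees, taxmap, mis)


class TestRunMerge:
    def test_single_donor_sample_gives_one_tree(self, merged):
        assert len(merged) == 1

    def test_recovers_truth_topology_on_unperturbed_tips(self, src, merged):
        shared = (
            set(leaf_names(merged[0])) & set(leaf_names(src.truth))
        ) - set(src.misplaced["species"])
        assert (
            rf_distance(
                to_newick(src.truth), to_newick(merged[0]), restrict_to=shared
            )
            == 0
        )

    def test_restores_omitted_order_as_sister_of_true_sister(self, src, merged):
        # the omitted order's species are present and monophyletic
        taxa = set(
            src.taxonomy.loc[
                src.taxonomy["order"] == src.omitted_order, "species"
            ]
        )
        assert taxa <= set(leaf_names(merged[0]))
        mrca = find_mrca(merged[0], taxa)
        under = (
            {mrca.taxon.label}
            if mrca.is_leaf()
            else {lf.taxon.label for lf in mrca.leaf_iter()}
        )
        assert under == taxa

    def test_merged_tree_is_ultrametric(self, merged):
        from knownpd.trees import node_depths as nd

        depths = nd(merged[0])
        tips = [depths[lf] for lf in merged[0].leaf_node_iter()]
        assert (max(tips) - min(tips)) / max(tips) < 1e-6

    def test_multiple_donor_samples(self, src):
        taxmap = TaxonomyMap(src.taxonomy)
        mis = MisplacedList.from_frame(src.misplaced)
        trees = dict(src.trees)
        trees["species"] = [trees["species"], trees["species"]]
        out = run_merge(src.plan, trees, taxmap, mis)
        assert len(out) == 2
        assert to_newick(out[0]) == to_newick(out[1])

    def test_zero_graft_plan_returns_reconciled_backbone(self, worked_tree):
        taxonomy = TaxonomyMap(
            pd.DataFrame(
                {
                    "species": ["A", "B", "C"],
                    "order": ["O", "O", "O"],
                    "family": ["F", "F", "F"],
                }
            )
        )
        plan = MergePlan(backbone="bb", grafts=[])
        out = run_merge(plan, {"bb": worked_tree}, taxonomy)
        assert len(out) == 1
        assert to_newick(out[0]) == to_newick(worked_tree)
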