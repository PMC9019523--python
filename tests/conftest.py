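import dendropy
import numpy as np
import pandas as pd
import pytest

from knownpd.trees import parse_newick

WORKED_NEWICK = "((A:1,B:1):2,C:3);"


@pytest.fixture
def worked_tree():
    """The 3-tip worked example: total PD 7, depths A=B=3 (via a shared stem
    of 2), C=3."""
    return parse_newick(WORKED_NEWICK)


@pytest.fixture
def worked_table():
    return pd.DataFrame(
        {
            "species": ["A", "B", "C"],
            "order": ["O1", "O1", "O2"],
            "family": ["F1", "F1", "F2"],
            "year": [1760, 1800, 1850],
        }
    )


def oracle_pd(tree: dendropy.Tree, tips) -> float:
    """Independent brute-force known PD of a species set: sum of edge
    lengths on the union of root-to-tip paths, computed by naive node
    walking on the dendropy tree (no package code)."""
    wanted = set(tips)
    edges = set()
    total = 0.0
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in wanted:
            continue
        node = leaf
        while node.parent_node is not None:
            if id(node) not in edges:
                edges.add(id(node))
                total += node.edge.length or 0.0
            node = node.parent_node
    return total


def oracle_contributions(tree: dendropy.Tree, order) -> np.ndarray:
    """Brute-force remove-and-recompute marginal contributions: the species
    added at step k contributes PD(first k) - PD(first k-1)."""
    out = np.zeros(len(order))
    for k in range(len(order)):
        out[k] = oracle_pd(tree, order[: k + 1]) - oracle_pd(tree, order[:k])
    return out


@pytest.fixture
def oracle():
    return oracle_pd


@pytest.fixture
def oracle_seq():
    return oracle_contributions
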