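import numpy as np
import pandas as pd
import pytest

from coreclades.asv_table import AsvCountTable
from coreclades.phylo import parse_newick


@pytest.fixture
def four_tip_tree():
    """Balanced rooted binary tree on 4 tips."""
    return parse_newick("((A:1,B:2):0.5,(C:1,D:1):0.25);")


@pytest.fixture
def caterpillar_tree():
    """Fully pectinate rooted tree on 5 tips."""
    return parse_newick("((((A:1,B:1):1,C:1):1,D:1):1,E:1);")


@pytest.fixture
def small_table():
    """4 samples x 4 ASVs with sequences, matching the 4-tip tree."""
    counts = pd.DataFrame(
        [[5, 0, 2, 1], [0, 3, 0, 0], [1, 1, 1, 1], [0, 0, 4, 0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["A", "B", "C", "D"],
    )
    seqs = {"A": "ACGTACGTAC", "B": "TTTTGGGGCC", "C": "GGGCCCAAAT", "D": "ACACACACAC"}
    return AsvCountTable(counts=counts, sequences=seqs)


@pytest.fixture
def metadata_two_studies():
    rows = []
    for i in range(4):
        rows.append(
            {
                "sample_id": f"s{i + 1}",
                "study": "study1" if i < 2 else "study2",
                "facility": "f1",
                "age_dpf": 90,
                "exposure": "control",
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def leaf_depths(phy):
    """Root-to-tip path length per tip label (simple upward walk)."""
    out = {}
    for leaf in phy.tree.leaf_node_iter():
        d, n = 0.0, leaf
        while n.parent_node is not None:
            d += n.edge.length or 0.0
            n = n.parent_node
        out[leaf.taxon.label] = d
    return out


def pairwise_tip_distances(phy):
    """All-pairs tip path lengths via dendropy's distance matrix (oracle)."""
    pdm = phy.tree.phylogenetic_distance_matrix()
    taxa = list(phy.tree.taxon_namespace)
    out = {}
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
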