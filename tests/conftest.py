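import sys
from pathlib import Path

import dendropy
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from morphoconflict.matrix_io import CharacterMatrix, build_partitions
from morphoconflict.synthetic_data import SimulationConfig, simulate_matrix


@pytest.fixture
def toy_matrix() -> CharacterMatrix:
    """5 taxa x 6 characters with missing, inapplicable, polymorphic and
    ordered codings."""
    return CharacterMatrix.from_rows(
        ["A", "B", "C", "D", "E"],
        [
            "010{01}20",
            "01-1?1",
            "110110",
            "0?0221",
            "10-000",
        ],
        ordered=[5],
    )


@pytest.fixture(scope="session")
def pure_signal_sim():
    """Small clean matrix generated entirely on the S resolution."""
    cfg = SimulationConfig(
        n_taxa=12,
        n_chars=300,
        conflict_weights=(1.0, 0.0, 0.0),
        state_count_weights=(1.0, 0.0, 0.0, 0.0),
        ordered_fraction=0.0,
        alpha=None,
        missing_fraction=0.0,
        polymorphic_fraction=0.0,
        focal_branch_length=0.2,
        branch_length_mean=0.15,
        seed=7,
    )
    matrix, truth = simulate_matrix(cfg)
    return matrix, truth, build_partitions(matrix)


def random_unrooted_tree(n_leaves: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random topology by stepwise addition with unit branch lengths."""
    labels = [f"t{i}" for i in range(n_leaves)]
    newick = f"({labels[0]}:1,{labels[1]}:1,{labels[2]}:1);"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)
    for lab in labels[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None]
        edge = edges[int(rng.integers(len(edges)))]
        old_head = edge.head_node
        parent = old_head.parent_node
        parent.remove_child(old_head)
        mid = parent.new_child(edge_length=1.0)
        mid.add_child(old_head)
        old_head.edge.length = 1.0
        leaf = mid.new_child(edge_length=1.0)
        leaf.taxon = tree.taxon_namespace.new_taxon(label=lab)
    return tree
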