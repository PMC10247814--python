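"""Tree handling: Newick I/O, bipartitions, normalized RF distance, and
operational clade (hypothesis) detection.

Trees are dendropy ``Tree`` objects throughout.  Functions here treat them
as unrooted: splits are computed as leaf-label bitmask bipartitions, and
"clades" are defined relative to a named outgroup (the side of a split that
contains no outgroup taxon).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "HypothesisLabel",
    "DEFAULT_REFERENCE_TAXA",
    "DEFAULT_OUTGROUP",
    "read_tree",
    "read_trees",
    "write_trees",
    "tree_from_newick",
    "to_newick",
    "leaf_labels",
    "split_set",
    "rf_distance",
    "rf_distance_normalized",
    "pairwise_rf_matrix",
    "clades_with_support",
    "detect_hypothesis",
    "is_monophyletic",
    "canonical_newick",
]

#: Operational reference taxa for the three resolutions of the focal branch:
#: a theropod, a sauropodomorph, and an ornithischian.
DEFAULT_REFERENCE_TAXA: tuple[str, str, str] = (
    "Dilophosaurus",
    "Plateosaurus",
    "Scelidosaurus",
)
#: Default outgroup used to root clade queries.
DEFAULT_OUTGROUP: tuple[str, ...] = ("Euparkeria capensis", "Postosuchus kirkpatricki")

#: Hypothesis codes: S = theropod+sauropodomorph sister pair (Saurischia),
#: Of = sauropodomorph+ornithischian (Ornithischiformes),
#: Os = theropod+ornithischian (Ornithoscelida).
HYPOTHESES = ("S", "Of", "Os")
_PAIR_OF = {"S": (0, 1), "Of": (1, 2), "Os": (0, 2)}


@dataclass(frozen=True)
class HypothesisLabel:
    """Detected resolution of the focal branch, with optional clade support."""

    label: str  # one of "S", "Of", "Os", "none"
    focal_support: float | None = None


# ----------------------------------------------------------------------
# I/O helpers
# ----------------------------------------------------------------------

def tree_from_newick(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick", suppress_internal_node_taxa=True)


def to_newick(t: dendropy.Tree, **kwargs) -> str:
    return t.as_string(schema="newick", suppress_rooting=True, **kwargs).strip()


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=True)


def read_trees(path: str | Path, schema: str = "newick") -> list[dendropy.Tree]:
    """Read a multi-tree Newick file or a NEXUS TREES block."""
    tl = dendropy.TreeList.get(path=str(path), schema=schema,
                               suppress_internal_node_taxa=True)
    return list(tl)


def write_trees(trees: Iterable[dendropy.Tree], path: str | Path) -> None:
    Path(path).write_text("".join(to_newick(t) + "\n" for t in trees))


def leaf_labels(t: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in t.leaf_node_iter())


def canonical_newick(t: dendropy.Tree) -> str:
    """Topology-only newick with sorted child order: equal strings iff equal
    labeled topologies (used for deterministic tie-breaking)."""

    labels = leaf_labels(t)
    bit = {lab: i for i, lab in enumerate(labels)}

    def render(node) -> tuple[int, str]:
        if node.is_leaf():
            return bit[node.taxon.label], node.taxon.label
        parts = sorted(render(c) for c in node.child_nodes())
        return parts[0][0], "(" + ",".join(p[1] for p in parts) + ")"

    # reroot deterministically at the lowest-label leaf's edge
    t2 = t.clone(depth=1)
    low = min(t2.leaf_node_iter(), key=lambda l: bit[l.taxon.label])
    t2.reroot_at_edge(low.edge, suppress_unifurcations=True)
    return render(t2.seed_node)[1] + ";"


# ----------------------------------------------------------------------
# Bitmask splits
# ----------------------------------------------------------------------

def _bitmap(t: dendropy.Tree) -> tuple[dict[str, int], int]:
    labels = leaf_labels(t)
    bit = {lab: 1 << i for i, lab in enumerate(labels)}
    full = (1 << len(labels)) - 1
    return bit, full


def _edge_masks(t: dendropy.Tree, bit: dict[str, int]) -> dict:
    """Leafset bitmask below each node (postorder)."""
    masks = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            masks[node] = bit[node.taxon.label]
        else:
            m = 0
            for c in node.child_nodes():
                m |= masks[c]
            masks[node] = m
    return masks


def split_set(t: dendropy.Tree) -> set[int]:
    """Non-trivial splits as canonical bitmasks (the side not containing
    the lowest-label leaf)."""
    bit, full = _bitmap(t)
    masks = _edge_masks(t, bit)
    splits = set()
    for node, m in masks.items():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = m if not (m & 1) else (full ^ m)
        pop = bin(side).count("1")
        if 2 <= pop <= len(bit) - 2:
            splits.add(side)
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds symmetric difference (bipartition count)."""
    if leaf_labels(t1) != leaf_labels(t2):
        raise ValueError("trees have different leaf sets")
    s1, s2 = split_set(t1), split_set(t2)
    return len(s1 ^ s2)


def rf_distance_normalized(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """RF distance divided by its binary-tree maximum 2(n-3)."""
    n = len(leaf_labels(t1))
    if n < 4:
        raise ValueError("need >= 4 leaves for a normalized RF distance")
    denom = 2 * (n - 3)
    return rf_distance(t1, t2) / denom


def pairwise_rf_matrix(trees: Sequence[dendropy.Tree]):
    """Normalized-RF matrix over a tree collection (shared leaf set)."""
    import numpy as np

    if not trees:
        return np.zeros((0, 0))
    labels = leaf_labels(trees[0])
    n = len(labels)
    denom = 2 * (n - 3)
    sets = []
    for t in trees:
        if leaf_labels(t) != labels:
            raise ValueError("trees have different leaf sets")
        sets.append(split_set(t))
    m = len(trees)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = len(sets[i] ^ sets[j]) / denom
    return out


# ----------------------------------------------------------------------
# Outgroup-rooted clades
# ----------------------------------------------------------------------

def _node_support(node) -> float | None:
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def clades_with_support(
    t: dendropy.Tree, outgroup: Sequence[str]
) -> list[tuple[int, float | None]]:
    """All clades of the outgroup-rooted tree as (bitmask, support) pairs.

    The tree is rooted at the first outgroup taxon present, so a clade is
    the side of any split that does not contain that taxon (singletons
    included).  Support is the internal-node label parsed as a number,
    where available; both sides of an edge carry the same support.
    """
    bit, full = _bitmap(t)
    root_taxon = next((o for o in outgroup if o in bit), None)
    if root_taxon is None:
        raise ValueError(f"no outgroup taxon present in tree: {outgroup}")
    rb = bit[root_taxon]
    masks = _edge_masks(t, bit)
    clades = []
    for node, m in masks.items():
        if node.parent_node is None:
            continue
        side = m if not (m & rb) else (full ^ m)
        clades.append((side, _node_support(node)))
    return clades


def pair_clade_taxa(
    t: dendropy.Tree,
    pair: Sequence[str],
    outgroup: Sequence[str] = DEFAULT_OUTGROUP,
) -> frozenset[str]:
    """Taxon content of the smallest outgroup-rooted clade containing both
    members of ``pair`` (used to turn a hypothesis tree into a monophyly
    constraint)."""
    bit, _ = _bitmap(t)
    labels = leaf_labels(t)
    target = 0
    for p in pair:
        if p not in bit:
            raise ValueError(f"taxon {p!r} not in tree")
        target |= bit[p]
    containing = [
        m for m, _ in clades_with_support(t, outgroup) if (m & target) == target
    ]
    if not containing:
        raise ValueError(f"no clade contains {pair!r}")
    smallest = min(containing, key=lambda m: bin(m).count("1"))
    return frozenset(lab for i, lab in enumerate(labels) if smallest & (1 << i))


def is_monophyletic(
    t: dendropy.Tree, taxa: Iterable[str], outgroup: Sequence[str] = DEFAULT_OUTGROUP
) -> bool:
    """True iff some edge of the outgroup-rooted tree subtends exactly
    the given taxon set."""
    bit, full = _bitmap(t)
    target = 0
    taxa = list(taxa)
    for lab in taxa:
        if lab not in bit:
            raise ValueError(f"taxon {lab!r} not in tree")
        target |= bit[lab]
    if target == full or len(taxa) == 1:
        return True
    return any(m == target for m, _ in clades_with_support(t, outgroup))


def detect_hypothesis(
    t: dendropy.Tree,
    refs: Sequence[str] = DEFAULT_REFERENCE_TAXA,
    outgroup: Sequence[str] = DEFAULT_OUTGROUP,
) -> HypothesisLabel:
    """Classify the resolution of the focal branch by reference-taxon
    ancestry.

    The tree is rooted at the outgroup; for each reference pair the smallest
    clade containing both is found, and the detected hypothesis is the one
    whose pair's ancestor excludes the third reference taxon.
    ``focal_support`` is the support value of that ancestral clade's edge.
    For a binary tree containing all three references exactly one hypothesis
    is detected; unresolved trees may yield ``"none"``.
    """
    bit, _ = _bitmap(t)
    for r in refs:
        if r not in bit:
            raise ValueError(f"reference taxon {r!r} not in tree")
    ref_bits = [bit[r] for r in refs]
    clades = clades_with_support(t, outgroup)
    detected = []
    for hyp in HYPOTHESES:
        i, j = _PAIR_OF[hyp]
        third = ref_bits[3 - i - j]
        pair = ref_bits[i] | ref_bits[j]
        containing = [(m, s) for m, s in clades if (m & pair) == pair]
        if not containing:
            continue
        mrca_mask, support = min(containing, key=lambda ms: bin(ms[0]).count("1"))
        if not (mrca_mask & third):
            detected.append((hyp, support))
    if len(detected) != 1:
        return HypothesisLabel("none", None)
    hyp, support = detected[0]
    return HypothesisLabel(hyp, support)
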