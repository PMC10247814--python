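"""Maximum-likelihood tree search and bootstrap support.

The search is a multi-start NNI hill climb: starting trees come from
random-addition-order stepwise parsimony (or a neighbor-joining tree on
pairwise mismatch distances), numeric parameters are optimized by coordinate
ascent, and NNI neighborhoods are screened at current parameter values with
full re-optimization applied on acceptance, so the total log-likelihood is
strictly increasing along the accepted-move sequence.  Monophyly constraints
are enforced both during stepwise addition and by rejecting violating NNI
moves.

Clade support uses a standard nonparametric bootstrap: characters are
resampled with replacement within partitions (preserving the partition
scheme), each replicate is re-searched from the ML tree under a constrained
hill-climb budget, and support is the percentage of replicate trees
containing each bipartition.  This is a deliberately simple, clearly labeled
support heuristic, not a reimplementation of the ultrafast bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .matrix_io import CharacterMatrix, PartitionScheme
from .mk_engine import MatrixData, MkEngine
from .trees import canonical_newick, split_set, tree_from_newick

__all__ = [
    "ConstraintSet",
    "SearchResult",
    "starting_tree",
    "ml_search",
    "bootstrap_support",
    "derive_seed",
]


def derive_seed(master: int, *tokens) -> int:
    """Deterministic per-stage seed below 2**31 derived from a master seed."""
    import zlib

    text = ":".join(str(t) for t in tokens)
    return (int(master) * 2654435761 + zlib.crc32(text.encode())) % (2**31 - 1)


# ----------------------------------------------------------------------
# Constraints
# ----------------------------------------------------------------------

@dataclass
class ConstraintSet:
    """Monophyly constraints (unrooted sense: each clade must be one side of
    some split)."""

    required_clades: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        clades = [frozenset(c) for c in self.required_clades]
        for i, a in enumerate(clades):
            for b in clades[i + 1 :]:
                if a & b and not (a <= b or b <= a):
                    raise ValueError(f"incompatible constraints: {sorted(a)} vs {sorted(b)}")
        self.required_clades = clades

    def check_taxa(self, taxa: Sequence[str]) -> None:
        taxa_set = set(taxa)
        for c in self.required_clades:
            missing = c - taxa_set
            if missing:
                raise ValueError(f"constraint taxa not in matrix: {sorted(missing)}")

    def satisfied_by_splits(self, splits: set[int], bit: dict[str, int], full: int) -> bool:
        for clade in self.required_clades:
            mask = 0
            for t in clade:
                mask |= bit.get(t, 0)
            pop = bin(mask).count("1")
            n = bin(full).count("1")
            if pop <= 1 or pop >= n - 1:
                continue
            canon = mask if not (mask & 1) else (full ^ mask)
            if canon not in splits:
                return False
        return True

    def satisfied_by_tree(self, tree: dendropy.Tree) -> bool:
        from .trees import leaf_labels

        labels = leaf_labels(tree)
        bit = {lab: 1 << i for i, lab in enumerate(labels)}
        full = (1 << len(labels)) - 1
        return self.satisfied_by_splits(split_set(tree), bit, full)


# ----------------------------------------------------------------------
# Starting trees
# ----------------------------------------------------------------------

class _AdjTree:
    """Small mutable unrooted tree on integer node ids (leaves carry labels)."""

    def __init__(self) -> None:
        self.adj: dict[int, set[int]] = {}
        self.label: dict[int, str] = {}
        self._next = 0

    def new_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = set()
        if label is not None:
            self.label[nid] = label
        return nid

    def connect(self, a: int, b: int) -> None:
        self.adj[a].add(b)
        self.adj[b].add(a)

    def disconnect(self, a: int, b: int) -> None:
        self.adj[a].discard(b)
        self.adj[b].discard(a)

    def edges(self) -> list[tuple[int, int]]:
        return [(a, b) for a in self.adj for b in self.adj[a] if a < b]

    def insert_leaf(self, leaf: int, edge: tuple[int, int]) -> int:
        a, b = edge
        mid = self.new_node()
        self.disconnect(a, b)
        self.connect(a, mid)
        self.connect(mid, b)
        self.connect(mid, leaf)
        return mid

    def remove_leaf(self, leaf: int, mid: int, edge: tuple[int, int]) -> None:
        a, b = edge
        self.disconnect(mid, leaf)
        self.disconnect(a, mid)
        self.disconnect(mid, b)
        self.connect(a, b)
        del self.adj[mid]

    def postorder(self, root: int) -> list[tuple[int, list[int]]]:
        """(node, children) pairs, children-first, rooted at ``root``."""
        out = []
        stack = [(root, -1, False)]
        while stack:
            node, parent, done = stack.pop()
            kids = [n for n in self.adj[node] if n != parent]
            if done or not kids:
                out.append((node, kids))
            else:
                stack.append((node, parent, True))
                for k in kids:
                    stack.append((k, node, False))
        return out

    def to_newick(self) -> str:
        leaves = sorted(self.label)
        root = leaves[0]
        start = next(iter(self.adj[root]))

        def render(node: int, parent: int) -> str:
            kids = [n for n in self.adj[node] if n != parent]
            if not kids:
                return _nexus_safe(self.label[node])
            return "(" + ",".join(render(k, node) for k in kids) + ")"

        kids = [n for n in self.adj[start] if n != root]
        parts = [_nexus_safe(self.label[root])] + [render(k, start) for k in kids]
        return "(" + ",".join(parts) + ");"


def _nexus_safe(label: str) -> str:
    if " " in label or "(" in label or "," in label:
        return "'" + label + "'"
    return label


def _fitch_score(tree: _AdjTree, masks: dict[int, np.ndarray]) -> int:
    """Total Fitch parsimony length over all characters (bitmask sets)."""
    root = next(iter(masks))
    order = tree.postorder(root)
    sets: dict[int, np.ndarray] = {}
    score = 0
    for node, kids in order:
        if not kids:
            sets[node] = masks[node]
            continue
        # the root is a leaf: its own state set participates too
        items = [sets[k] for k in kids]
        if node in masks:
            items.append(masks[node])
        cur = items[0]
        for s in items[1:]:
            inter = cur & s
            empty = inter == 0
            score += int(empty.sum())
            cur = np.where(empty, cur | s, inter)
        sets[node] = cur
    return score


def _fitch_masks(matrix: CharacterMatrix) -> np.ndarray:
    """Per-taxon per-character state-set bitmasks; missing-like = all states."""
    masks = matrix.masks.astype(np.uint8).copy()
    missing_like = masks == 0
    masks[missing_like] = 0x3F
    return masks


def starting_tree(
    matrix: CharacterMatrix,
    mode: str = "random_addition",
    seed: int = 0,
    constraint: ConstraintSet | None = None,
    default_length: float = 0.1,
) -> dendropy.Tree:
    """Build a binary starting tree.

    ``random_addition``: stepwise addition in random taxon order, placing
    each taxon on the edge minimizing Fitch parsimony length (ties broken at
    random); constraint-violating placements are skipped.
    ``neighbor_like``: neighbor joining on pairwise mismatch distances.
    """
    if matrix.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    if mode == "neighbor_like":
        tree = _nj_tree(matrix)
    elif mode == "random_addition":
        tree = _random_addition_tree(matrix, rng, constraint)
    else:
        raise ValueError(f"unknown starting-tree mode {mode!r}")
    for edge in tree.edges():
        if edge.head_node.parent_node is not None:
            edge.length = default_length
    if constraint is not None and not constraint.satisfied_by_tree(tree):
        raise RuntimeError("starting tree violates constraints")
    return tree


def _random_addition_tree(
    matrix: CharacterMatrix, rng: np.random.Generator, constraint: ConstraintSet | None
) -> dendropy.Tree:
    fm = _fitch_masks(matrix)
    order = rng.permutation(matrix.n_taxa)
    tree = _AdjTree()
    leaf_ids = {}
    char_masks: dict[int, np.ndarray] = {}
    first3 = order[:3]
    hub = tree.new_node()
    for t in first3:
        nid = tree.new_node(matrix.taxa[t])
        leaf_ids[t] = nid
        tree.connect(hub, nid)
        char_masks[nid] = fm[t]
    placed = list(first3)
    bit = {matrix.taxa[t]: 1 << int(t) for t in range(matrix.n_taxa)}
    for t in order[3:]:
        nid = tree.new_node(matrix.taxa[t])
        leaf_ids[t] = nid
        char_masks[nid] = fm[t]
        best_edges: list[tuple[int, int]] = []
        best_score = None
        for edge in tree.edges():
            mid = tree.insert_leaf(nid, edge)
            ok = True
            if constraint is not None:
                ok = _adj_satisfies(tree, constraint, matrix, placed + [t])
            if ok:
                score = _fitch_score(tree, char_masks)
                if best_score is None or score < best_score:
                    best_score, best_edges = score, [edge]
                elif score == best_score:
                    best_edges.append(edge)
            tree.remove_leaf(nid, mid, edge)
        if not best_edges:
            raise RuntimeError("no constraint-compatible placement found")
        choice = best_edges[int(rng.integers(len(best_edges)))]
        tree.insert_leaf(nid, choice)
        placed.append(t)
    return tree_from_newick(tree.to_newick())


def _adj_satisfies(
    tree: _AdjTree,
    constraint: ConstraintSet,
    matrix: CharacterMatrix,
    placed: list[int],
) -> bool:
    """Check that each constraint's placed subset is a split of the tree."""
    placed_labels = {matrix.taxa[t] for t in placed}
    need = []
    for clade in constraint.required_clades:
        sub = clade & placed_labels
        if 2 <= len(sub) <= len(placed_labels) - 2:
            need.append(sub)
    if not need:
        return True
    # collect splits of the current tree as frozensets of labels
    label_of = tree.label
    root = next(iter(label_of))
    sets: dict[int, frozenset[str]] = {}
    splits = set()
    for node, kids in tree.postorder(root):
        if not kids:
            sets[node] = frozenset([label_of[node]])
        else:
            s = frozenset().union(*(sets[k] for k in kids))
            sets[node] = s
            splits.add(s)
    full = frozenset(placed_labels)
    for sub in need:
        target = frozenset(sub)
        comp = full - target
        if target not in splits and comp not in splits:
            return False
    return True


def _nj_tree(matrix: CharacterMatrix) -> dendropy.Tree:
    """Neighbor joining on pairwise mismatch proportions (scikit-bio)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    codes = matrix.state_codes()
    n = matrix.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (codes[i] >= 0) & (codes[j] >= 0)
            if both.sum() == 0:
                d = 0.75
            else:
                d = float((codes[i][both] != codes[j][both]).mean())
            D[i, j] = D[j, i] = max(d, 1e-6)
    ids = [f"t{i}" for i in range(n)]
    sk = nj(DistanceMatrix(D, ids))
    t = tree_from_newick(str(sk))
    for leaf in t.leaf_node_iter():
        leaf.taxon.label = matrix.taxa[int(leaf.taxon.label[1:])]
    return t


# ----------------------------------------------------------------------
# NNI moves
# ----------------------------------------------------------------------

def _internal_edges(tree: dendropy.Tree):
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and not node.is_leaf():
            yield node  # edge (parent(node), node)


def _nni_candidates(tree: dendropy.Tree):
    """Yield (v, a, c) triples: swapping subtrees a (child of v) and c
    (child of parent(v)) gives one NNI neighbor across the edge above v."""
    for v in list(_internal_edges(tree)):
        u = v.parent_node
        others = [c for c in u.child_nodes() if c is not v]
        if not others:
            continue
        c = others[0]
        kids = v.child_nodes()
        if len(kids) < 2:
            continue
        yield (v, kids[0], c)
        yield (v, kids[1], c)


def _apply_nni(v, a, c) -> None:
    u = v.parent_node
    u.remove_child(c)
    v.remove_child(a)
    u.add_child(a)
    v.add_child(c)


def _revert_nni(v, a, c) -> None:
    _apply_nni(v, c, a)  # swapping back


# ----------------------------------------------------------------------
# Search
# ----------------------------------------------------------------------

@dataclass
class SearchResult:
    """Outcome of a multi-start ML search."""

    best_tree: dendropy.Tree
    best_lnL: float
    all_trees: list[tuple[dendropy.Tree, float]]
    seed: int
    data: MatrixData | None = None
    #: per-run fitted parameter sets (parallel to all_trees)
    all_data: list[MatrixData] | None = None

    def site_loglike_table(self, scheme=None):
        """Per-character log-likelihood table over the per-run best trees
        (columns run1..runN), at each run's own fitted parameters."""
        import pandas as pd

        from .topo_tests import SiteLikelihoodTable

        if self.all_data is None:
            raise ValueError("search did not retain per-run parameter sets")
        cols = {}
        for i, ((tree, _), data) in enumerate(zip(self.all_trees, self.all_data)):
            eng = MkEngine(data, tree.clone(depth=1))
            cols[f"run{i + 1}"] = pd.Series(eng.site_loglikes())
        partition_of = scheme.partition_of() if scheme is not None else None
        return SiteLikelihoodTable(pd.DataFrame(cols), partition_of)

    @property
    def run_lnLs(self) -> list[float]:
        return [l for _, l in self.all_trees]


def _hill_climb(
    data: MatrixData,
    tree: dendropy.Tree,
    constraint: ConstraintSet | None,
    ascertainment: bool,
    max_rounds: int,
    opt_sweeps: int,
    xatol: float,
    final_sweeps: int = 50,
    final_tol: float = 1e-6,
) -> tuple[dendropy.Tree, float]:
    eng = MkEngine(data, tree, ascertainment)
    cur_lnl, _, _ = eng.optimize(tol=1e-4, max_sweeps=opt_sweeps, xatol=xatol, warn=False)
    for _ in range(max_rounds):
        best_gain = 0.0
        best_move = None
        for v, a, c in _nni_candidates(tree):
            _apply_nni(v, a, c)
            ok = constraint is None or constraint.satisfied_by_tree(tree)
            if ok:
                cand = MkEngine(data, tree, ascertainment).total_lnL()
                if cand - cur_lnl > best_gain + 1e-12:
                    best_gain = cand - cur_lnl
                    best_move = (v, a, c)
            _revert_nni(v, a, c)
        if best_move is None or best_gain <= 1e-9:
            break
        v, a, c = best_move
        _apply_nni(v, a, c)
        eng = MkEngine(data, tree, ascertainment)
        cur_lnl, _, _ = eng.optimize(tol=1e-4, max_sweeps=opt_sweeps, xatol=xatol, warn=False)
    eng = MkEngine(data, tree, ascertainment)
    cur_lnl, _, _ = eng.optimize(tol=final_tol, max_sweeps=final_sweeps, xatol=1e-5, warn=False)
    return tree, cur_lnl


def ml_search(
    matrix: CharacterMatrix,
    scheme: PartitionScheme | None = None,
    n_starts: int = 10,
    constraint: ConstraintSet | None = None,
    seed: int = 0,
    model=None,
    n_gamma_categories: int = 4,
    ascertainment: bool = True,
    max_rounds: int = 100,
    opt_sweeps: int = 8,
    xatol: float = 1e-4,
    start_mode: str = "random_addition",
) -> SearchResult:
    """Multi-start constrained NNI hill-climbing ML search.

    Every start builds its own starting tree (seeded deterministically from
    ``seed``), optimizes numeric parameters, and climbs until no NNI
    neighbor improves the likelihood.  The best tree across starts is
    returned; exact ties are broken by the lexicographically smallest
    canonical newick string.
    """
    if constraint is not None:
        constraint.check_taxa(matrix.taxa)
    if model is not None:
        base_data = model.data
        ascertainment = model.ascertainment
    else:
        base_data = MatrixData(
            matrix, scheme, n_gamma_categories=n_gamma_categories
        )
    runs: list[tuple[dendropy.Tree, float]] = []
    runs_data: list[MatrixData] = []
    for i in range(n_starts):
        run_seed = derive_seed(seed, "mlsearch", i)
        tree = starting_tree(matrix, mode=start_mode, seed=run_seed, constraint=constraint)
        data = base_data.copy()
        tree, lnl = _hill_climb(
            data, tree, constraint, ascertainment, max_rounds, opt_sweeps, xatol
        )
        runs.append((tree, lnl))
        runs_data.append(data)
    best_idx = _argmax_with_tiebreak(runs)
    best_tree, best_lnl = runs[best_idx]
    return SearchResult(
        best_tree=best_tree,
        best_lnL=best_lnl,
        all_trees=runs,
        seed=seed,
        data=runs_data[best_idx],
        all_data=runs_data,
    )


def _argmax_with_tiebreak(runs: list[tuple[dendropy.Tree, float]]) -> int:
    best = max(l for _, l in runs)
    tied = [i for i, (_, l) in enumerate(runs) if abs(l - best) <= 1e-9]
    if len(tied) == 1:
        return tied[0]
    return min(tied, key=lambda i: canonical_newick(runs[i][0]))


# ----------------------------------------------------------------------
# Bootstrap
# ----------------------------------------------------------------------

def bootstrap_support(
    matrix: CharacterMatrix,
    scheme: PartitionScheme | None,
    tree: dendropy.Tree,
    B: int = 200,
    seed: int = 0,
    n_gamma_categories: int = 4,
    ascertainment: bool = True,
    replicate_rounds: int = 3,
    opt_sweeps: int = 2,
    resample: bool = True,
    data: MatrixData | None = None,
) -> dendropy.Tree:
    """Nonparametric bootstrap clade support mapped onto ``tree``.

    Characters are resampled with replacement within partitions; each
    replicate is re-searched from the input tree with a constrained NNI
    budget.  Support values (percent of replicates containing each split)
    are written as internal-node labels of the returned tree clone.
    """
    if B < 1:
        raise ValueError("B must be positive")
    if data is None:
        data = MatrixData(matrix, scheme, n_gamma_categories=n_gamma_categories)
    from .trees import leaf_labels

    labels = leaf_labels(tree)
    bit = {lab: 1 << i for i, lab in enumerate(labels)}
    full = (1 << len(labels)) - 1
    counts: dict[int, int] = {}
    for b in range(B):
        rep_seed = derive_seed(seed, "bootstrap", b)
        rng = np.random.default_rng(rep_seed)
        rep_data = data.copy()
        if resample:
            for p in rep_data.partitions:
                drawn = rng.integers(0, p.n_chars, size=p.n_chars)
                p.pattern_weights = np.bincount(
                    p.pattern_of_char[drawn], minlength=p.n_patterns
                ).astype(float)
        rep_tree = tree.clone(depth=1)
        rep_tree, _ = _hill_climb(
            rep_data, rep_tree, None, ascertainment,
            max_rounds=replicate_rounds, opt_sweeps=opt_sweeps, xatol=1e-3,
            final_sweeps=0, final_tol=1e-3,
        )
        for s in split_set(rep_tree):
            counts[s] = counts.get(s, 0) + 1
    out = tree.clone(depth=1)
    # annotate internal nodes with split support
    masks = {}
    for node in out.postorder_node_iter():
        if node.is_leaf():
            masks[node] = bit[node.taxon.label]
        else:
            m = 0
            for c in node.child_nodes():
                m |= masks[c]
            masks[node] = m
            if node.parent_node is not None:
                side = m if not (m & 1) else (full ^ m)
                pop = bin(side).count("1")
                if 2 <= pop <= len(labels) - 2:
                    node.label = f"{100.0 * counts.get(side, 0) / B:.1f}"
    return out
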