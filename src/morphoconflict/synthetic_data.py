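"""Synthetic morphological matrices with known ground truth.

The generator emulates the statistical structure of large early-dinosaur
character matrices: tens of taxa by hundreds of discrete characters with
2-5 states, a small ordered fraction, heavy and taxon-wise heterogeneous
missing data, occasional polymorphic cells, and — crucially — a
controllable mixture of characters whose signal supports each of the three
possible resolutions (S, Of, Os) of one focal internal branch.

Each character draws a generating topology from ``conflict_weights``, a
state count, an ordering flag, and a gamma rate multiplier, then evolves
along that topology under the Mk process and is conditioned (by rejection)
to be variable, matching the ascertainment assumption of the
variable-characters-only correction.  Missingness is applied afterwards as
per-taxon completeness drawn from a Beta distribution, since uniform random
missingness is unrealistically benign compared to fossil taxa of very
uneven completeness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .matrix_io import (
    KIND_MISSING,
    KIND_POLYMORPHIC,
    KIND_STATE,
    CharacterMatrix,
)
from .mk_engine import _eig
from .trees import (
    DEFAULT_OUTGROUP,
    DEFAULT_REFERENCE_TAXA,
    clades_with_support,
    leaf_labels,
    tree_from_newick,
    to_newick,
)

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "random_base_tree",
    "make_hypothesis_trees",
    "simulate_matrix",
    "bea_like_config",
]

HYPOTHESES = ("S", "Of", "Os")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated matrix.

    ``state_count_weights`` is the distribution over k in {2, 3, 4, 5};
    ``conflict_weights`` gives the (S, Of, Os) generating-tree mixture;
    ``taxon_completeness_spread`` controls how unevenly missing data is
    spread across taxa (0 = uniform-ish, 1 = very uneven).
    """

    n_taxa: int = 80
    n_chars: int = 457
    state_count_weights: tuple[float, float, float, float] = (0.82, 0.12, 0.04, 0.02)
    ordered_fraction: float = 0.08
    alpha: float | None = 1.0
    conflict_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    focal_branch_length: float = 0.05
    missing_fraction: float = 0.57
    taxon_completeness_spread: float = 0.5
    polymorphic_fraction: float = 0.003
    branch_length_mean: float = 0.1
    seed: int = 0
    base_tree: str | None = None  # newick; generated from n_taxa when absent
    refs: tuple[str, str, str] = DEFAULT_REFERENCE_TAXA
    outgroup: tuple[str, ...] = DEFAULT_OUTGROUP

    def __post_init__(self) -> None:
        w = np.asarray(self.conflict_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("conflict weights must be non-negative and sum to 1")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if not 0.0 <= self.polymorphic_fraction < 1.0:
            raise ValueError("polymorphic_fraction must be in [0, 1)")


def bea_like_config(**overrides) -> SimulationConfig:
    """Default emulation preset: 80 taxa x 457 characters, ~8% ordered,
    57% missing, binary:multistate ratio matching a 375:76 split."""
    return SimulationConfig(**overrides)


@dataclass
class TruthManifest:
    """Ground truth of a simulated matrix."""

    tree_labels: list[str]  # per character: generating hypothesis
    k: list[int]
    ordered: list[bool]
    rate: list[float]
    hypothesis_trees: dict[str, str]  # label -> newick
    config: dict = field(default_factory=dict)

    def counts_per_label(self) -> dict[str, int]:
        return {h: self.tree_labels.count(h) for h in HYPOTHESES}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))


# ----------------------------------------------------------------------
# Trees
# ----------------------------------------------------------------------

def _random_clade_newick(
    labels: list[str], rng: np.random.Generator, blen_mean: float
) -> str:
    """Random binary subtree over the labels by repeated random joins."""

    def bl() -> str:
        return f":{rng.gamma(2.0, blen_mean / 2.0):.6f}"

    nodes = [f"'{lab}'" + bl() if " " in lab else lab + bl() for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})" + bl())
    return nodes[0]


def random_base_tree(
    n_taxa: int = 80,
    seed: int = 0,
    refs: Sequence[str] = DEFAULT_REFERENCE_TAXA,
    outgroup: Sequence[str] = DEFAULT_OUTGROUP,
    branch_length_mean: float = 0.1,
) -> dendropy.Tree:
    """Random scaffold: an outgroup plus three reference clades of roughly
    equal size, arbitrarily resolved around the focal branch."""
    n_og = len(outgroup)
    n_in = n_taxa - n_og
    if n_in < 3:
        raise ValueError("need at least 3 ingroup taxa")
    rng = np.random.default_rng(seed)
    group_names = ("theropod", "sauropodomorph", "ornithischian")
    sizes = np.full(3, n_in // 3)
    sizes[: n_in % 3] += 1
    clades = []
    for g, (name, ref) in enumerate(zip(group_names, refs)):
        labels = [ref] + [f"{name}_{i + 2:02d}" for i in range(sizes[g] - 1)]
        clades.append(_random_clade_newick(labels, rng, branch_length_mean))
    og_parts = [
        (f"'{o}'" if " " in o else o) + f":{rng.gamma(2.0, branch_length_mean / 2.0):.6f}"
        for o in outgroup
    ]
    stem = f":{branch_length_mean:.6f}"
    ingroup = f"(({clades[0]},{clades[1]}){stem},{clades[2]}){stem}"
    newick = "(" + ",".join(og_parts + [ingroup]) + ");"
    return tree_from_newick(newick)


def _subtree_newick(node: dendropy.Node) -> str:
    if node.is_leaf():
        lab = node.taxon.label
        lab = f"'{lab}'" if " " in lab else lab
    else:
        lab = "(" + ",".join(_subtree_newick(c) for c in node.child_nodes()) + ")"
    length = node.edge.length if node.edge.length is not None else 0.1
    return f"{lab}:{length:.6f}"


def make_hypothesis_trees(
    base: dendropy.Tree,
    refs: Sequence[str] = DEFAULT_REFERENCE_TAXA,
    outgroup: Sequence[str] = DEFAULT_OUTGROUP,
    focal_branch_length: float = 0.05,
) -> dict[str, dendropy.Tree]:
    """Three trees identical except for the resolution of the focal branch.

    The base tree must partition its ingroup into three clades, each
    containing exactly one reference taxon; the S/Of/Os trees re-join those
    clades as (T,S)+O, (S,O)+T and (T,O)+S respectively, with the focal
    branch set to ``focal_branch_length`` and all other branch lengths
    shared.
    """
    labels = set(leaf_labels(base))
    for r in list(refs) + list(outgroup):
        if r not in labels:
            raise ValueError(f"taxon {r!r} not in base tree")
    ingroup = labels - set(outgroup)
    bit = {lab: 1 << i for i, lab in enumerate(sorted(labels))}

    work = base.clone(depth=1)
    # find, for each reference taxon, the largest clade containing it but
    # no other reference and no outgroup taxon
    clade_masks = [m for m, _ in clades_with_support(work, outgroup)]
    ref_bits = [bit[r] for r in refs]
    chosen = []
    for i, rb in enumerate(ref_bits):
        candidates = [
            m
            for m in clade_masks
            if (m & rb) and not any(m & ref_bits[j] for j in range(3) if j != i)
        ]
        if not candidates:
            raise ValueError(f"reference taxon {refs[i]!r} has no exclusive clade")
        chosen.append(max(candidates, key=lambda m: bin(m).count("1")))
    union = chosen[0] | chosen[1] | chosen[2]
    ingroup_mask = 0
    for lab in ingroup:
        ingroup_mask |= bit[lab]
    if (chosen[0] & chosen[1]) or (chosen[0] & chosen[2]) or (chosen[1] & chosen[2]):
        raise ValueError("reference taxa are not in distinct clades of the base tree")
    if union != ingroup_mask:
        raise ValueError(
            "the three reference clades do not partition the ingroup; "
            "refs must sit in distinct clades around the focal branch"
        )

    # materialize each clade's newick from the base (rooted away from ingroup)
    og_leaf = next(l for l in work.leaf_node_iter() if l.taxon.label == outgroup[0])
    work.reroot_at_edge(og_leaf.edge, suppress_unifurcations=True)
    mask_below = {}
    node_of_mask = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            mask_below[node] = bit[node.taxon.label]
        else:
            m = 0
            for c in node.child_nodes():
                m |= mask_below[c]
            mask_below[node] = m
        node_of_mask[mask_below[node]] = node
    sub_newick = []
    stem_len = []
    for m in chosen:
        node = node_of_mask.get(m)
        if node is None:
            raise ValueError("reference clade is not a rooted clade of the base tree")
        nk = _subtree_newick(node)
        # split off the stem length
        lab, _, length = nk.rpartition(":")
        sub_newick.append(lab)
        stem_len.append(float(length))

    og_nodes = [
        next(l for l in work.leaf_node_iter() if l.taxon.label == o) for o in outgroup
    ]
    og_parts = []
    for o, node in zip(outgroup, og_nodes):
        lab = f"'{o}'" if " " in o else o
        og_parts.append(f"{lab}:{(node.edge.length or 0.1):.6f}")

    arrangements = {"S": (0, 1, 2), "Of": (1, 2, 0), "Os": (0, 2, 1)}
    out = {}
    for label, (a, b, c) in arrangements.items():
        pair = (
            f"({sub_newick[a]}:{stem_len[a]:.6f},{sub_newick[b]}:{stem_len[b]:.6f})"
            f":{focal_branch_length:.6f}"
        )
        ing = f"({pair},{sub_newick[c]}:{stem_len[c]:.6f}):0.05"
        newick = "(" + ",".join(og_parts + [ing]) + ");"
        out[label] = tree_from_newick(newick)
    return out


# ----------------------------------------------------------------------
# Character simulation
# ----------------------------------------------------------------------

def _compile_for_sim(tree: dendropy.Tree, taxa: list[str]):
    """Preorder edge list (parent slot, child slot, length) + leaf slots."""
    pos = {t: i for i, t in enumerate(taxa)}
    slot = {}
    nxt = len(taxa)
    edges = []
    leaf_slot_rows = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            slot[node] = pos[node.taxon.label]
        else:
            slot[node] = nxt
            nxt += 1
        if node.parent_node is not None:
            edges.append((slot[node.parent_node], slot[node], node.edge.length or 0.0))
    return edges, nxt


def _simulate_group(
    edges, n_slots: int, n_leaves: int, k: int, ordered: bool,
    rates: np.ndarray, rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``len(rates)`` characters on one compiled tree; returns
    (n_chars, n_leaves) int8 states."""
    n = len(rates)
    lam, V = _eig(k, ordered)
    states = np.zeros((n, n_slots), dtype=np.int8)
    root_slot = edges[0][0]
    states[:, root_slot] = rng.integers(0, k, size=n)
    for parent, child, t in edges:
        E = np.exp(np.outer(rates * t, lam))  # (n, k)
        P = np.einsum("ij,nj,kj->nik", V, E, V)
        np.clip(P, 0.0, None, out=P)
        probs = np.take_along_axis(
            P, states[:, parent][:, None, None].astype(int), axis=1
        )[:, 0, :]
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        states[:, child] = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
    return states[:, :n_leaves]


def simulate_matrix(cfg: SimulationConfig) -> tuple[CharacterMatrix, TruthManifest]:
    """Simulate a matrix under the configured three-way conflict mixture.

    Returns the character matrix (NEXUS-writable) and the ground-truth
    manifest.  Reproducible bit-for-bit from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.base_tree is not None:
        base = tree_from_newick(cfg.base_tree)
    else:
        base = random_base_tree(
            cfg.n_taxa, seed=int(rng.integers(2**31 - 1)), refs=cfg.refs,
            outgroup=cfg.outgroup, branch_length_mean=cfg.branch_length_mean,
        )
    hyp_trees = make_hypothesis_trees(
        base, cfg.refs, cfg.outgroup, cfg.focal_branch_length
    )
    taxa = leaf_labels(base)
    n_taxa = len(taxa)

    # per-character draws
    labels_idx = rng.choice(3, size=cfg.n_chars, p=np.asarray(cfg.conflict_weights))
    ks = rng.choice([2, 3, 4, 5], size=cfg.n_chars,
                    p=np.asarray(cfg.state_count_weights))
    ordered = (rng.random(cfg.n_chars) < cfg.ordered_fraction) & (ks >= 3)
    if cfg.alpha is not None:
        rates = rng.gamma(cfg.alpha, 1.0 / cfg.alpha, size=cfg.n_chars)
    else:
        rates = np.ones(cfg.n_chars)
    rates = np.maximum(rates, 1e-6)

    compiled = {h: _compile_for_sim(hyp_trees[h], taxa) for h in HYPOTHESES}
    states = np.zeros((cfg.n_chars, n_taxa), dtype=np.int8)
    for h_idx, h in enumerate(HYPOTHESES):
        for k in (2, 3, 4, 5):
            for o in (False, True):
                sel = np.nonzero((labels_idx == h_idx) & (ks == k) & (ordered == o))[0]
                if len(sel) == 0:
                    continue
                edges, n_slots = compiled[h]
                out = _simulate_group(
                    edges, n_slots, n_taxa, k, o, rates[sel], rng
                )
                # condition on variability by rejection: the whole character
                # is redrawn, rate included, since a near-zero rate would
                # stay constant forever
                for _ in range(1000):
                    constant = np.nonzero(
                        (out == out[:, :1]).all(axis=1)
                    )[0]
                    if len(constant) == 0:
                        break
                    idx = sel[constant]
                    if cfg.alpha is not None:
                        rates[idx] = np.maximum(
                            rng.gamma(cfg.alpha, 1.0 / cfg.alpha, size=len(idx)),
                            1e-6,
                        )
                    out[constant] = _simulate_group(
                        edges, n_slots, n_taxa, k, o, rates[idx], rng
                    )
                else:
                    raise RuntimeError("variability rejection did not terminate")
                states[sel] = out

    # missingness: per-taxon completeness ~ Beta, scaled to the target mean
    kinds = np.zeros((n_taxa, cfg.n_chars), dtype=np.uint8)
    masks = np.zeros((n_taxa, cfg.n_chars), dtype=np.uint8)
    masks[:] = (1 << states.T).astype(np.uint8)
    if cfg.missing_fraction > 0:
        mean_complete = 1.0 - cfg.missing_fraction
        nu = 2.0 / max(cfg.taxon_completeness_spread, 1e-3)
        completeness = rng.beta(mean_complete * nu, (1 - mean_complete) * nu,
                                size=n_taxa)
        completeness = np.clip(completeness, 0.02, 1.0)
        miss = rng.random((n_taxa, cfg.n_chars)) > completeness[:, None]
        kinds[miss] = KIND_MISSING
        masks[miss] = 0
    if cfg.polymorphic_fraction > 0:
        observed = np.argwhere((kinds == KIND_STATE) & (ks[None, :] >= 2))
        n_poly = int(round(cfg.polymorphic_fraction * len(observed)))
        if n_poly > 0:
            pick = observed[rng.choice(len(observed), size=n_poly, replace=False)]
            for ti, ci in pick:
                s = states[ci, ti]
                other = int(rng.integers(ks[ci] - 1))
                if other >= s:
                    other += 1
                kinds[ti, ci] = KIND_POLYMORPHIC
                masks[ti, ci] = (1 << int(s)) | (1 << other)

    matrix = CharacterMatrix(
        taxa,
        kinds,
        masks,
        ordered_flags=ordered,
        region_labels=None,
    )
    cfg_dict = asdict(cfg)
    manifest = TruthManifest(
        tree_labels=[HYPOTHESES[i] for i in labels_idx],
        k=[int(v) for v in ks],
        ordered=[bool(v) for v in ordered],
        rate=[float(v) for v in rates],
        hypothesis_trees={h: to_newick(hyp_trees[h]) for h in HYPOTHESES},
        config=cfg_dict,
    )
    return matrix, manifest
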