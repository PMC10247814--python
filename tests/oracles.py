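"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's pruning machinery: likelihoods are
computed by explicit enumeration over all internal-node (and missing-leaf)
state assignments with scipy's matrix exponential, and Robinson-Foulds
distances come from dendropy's bipartition comparison.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
from scipy.linalg import expm


def mk_rate_matrix(k: int, ordered: bool) -> np.ndarray:
    Q = np.zeros((k, k))
    if ordered and k > 2:
        mu = k / (2.0 * (k - 1))
        for i in range(k - 1):
            Q[i, i + 1] = Q[i + 1, i] = mu
    else:
        Q[:] = 1.0 / (k - 1)
        np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def enumeration_column_likelihood(
    newick: str,
    taxa: list[str],
    column: list[int | None],
    k: int,
    ordered: bool = False,
    rates: np.ndarray | None = None,
    ascertainment: bool = True,
) -> float:
    """Log-likelihood of one character column by explicit enumeration.

    ``column`` uses ``None`` for missing cells.  Gamma mixing uses the
    supplied category rates with equal weights.
    """
    if rates is None:
        rates = np.ones(1)
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)
    nodes = list(tree.postorder_node_iter())
    colmap = dict(zip(taxa, column))
    Q = mk_rate_matrix(k, ordered)

    def pattern_likelihood(observed: dict[str, int | None]) -> float:
        free = [n for n in nodes
                if (not n.is_leaf()) or observed[n.taxon.label] is None]
        total = 0.0
        for r in rates:
            P = {n: expm(Q * (n.edge.length or 0.0) * r) for n in nodes
                 if n.parent_node is not None}
            acc = 0.0
            for combo in itertools.product(range(k), repeat=len(free)):
                state = {id(n): s for n, s in zip(free, combo)}
                for n in nodes:
                    if n.is_leaf() and observed[n.taxon.label] is not None:
                        state[id(n)] = observed[n.taxon.label]
                like = 1.0 / k  # uniform root frequencies
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    like *= P[n][state[id(n.parent_node)], state[id(n)]]
                acc += like
            total += acc / len(rates)
        return total

    L = pattern_likelihood(colmap)
    if ascertainment:
        p_const = sum(
            pattern_likelihood({lab: s for lab in taxa}) for s in range(k)
        )
        L = L / (1.0 - p_const)
    return float(np.log(L))


def enumeration_pattern_probs(
    newick: str, taxa: list[str], k: int, ordered: bool = False,
    conditioned_on_variable: bool = True,
) -> dict[tuple[int, ...], float]:
    """Probability of every tip pattern on a small tree (optionally
    conditioned on the pattern being variable)."""
    probs = {}
    for pattern in itertools.product(range(k), repeat=len(taxa)):
        probs[pattern] = np.exp(
            enumeration_column_likelihood(
                newick, taxa, list(pattern), k, ordered, ascertainment=False
            )
        )
    if conditioned_on_variable:
        const = [p for p in probs if len(set(p)) == 1]
        z = 1.0 - sum(probs[p] for p in const)
        probs = {p: v / z for p, v in probs.items() if len(set(p)) > 1}
    return probs


def dendropy_rf(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds symmetric difference via dendropy's bipartitions."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def dendropy_detect_pair(
    tree: dendropy.Tree, refs: tuple[str, str, str], outgroup: tuple[str, ...]
) -> str:
    """Hypothesis classification via dendropy rerooting + MRCA queries."""
    t = tree.clone(depth=1)
    og0 = next(l for l in t.leaf_node_iter() if l.taxon.label == outgroup[0])
    t.reroot_at_edge(og0.edge, update_bipartitions=False)
    labels = {"S": (refs[0], refs[1]), "Of": (refs[1], refs[2]),
              "Os": (refs[0], refs[2])}
    third = {"S": refs[2], "Of": refs[0], "Os": refs[1]}
    found = []
    for lab, (x, y) in labels.items():
        mrca = t.mrca(taxon_labels=[x, y])
        leafset = {l.taxon.label for l in mrca.leaf_iter()}
        if third[lab] not in leafset:
            found.append(lab)
    assert len(found) == 1, f"non-unique classification: {found}"
    return found[0]
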