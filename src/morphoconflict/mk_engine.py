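"""Partitioned Mk likelihood engine.

Model
-----
Each partition holds characters with the same number of observed states
``k`` and the same ordering status.  Unordered characters evolve under the
Mk model: a k-state Markov process with equal exchange rates and uniform
stationary frequencies.  Ordered (additive) characters exchange only between
neighboring states (tridiagonal rate matrix).  Both generators are
normalized to one expected substitution per unit branch length at
stationarity.  Rate heterogeneity across characters uses a discrete-gamma
mixture (mean-per-category discretization, equal weights).  Because
morphological matrices contain only variable characters, likelihoods are
corrected for ascertainment bias by conditioning on variability: each
character's likelihood is divided by ``1 - sum_s P(constant pattern s)``
computed on the same tree and model.

Branch lengths are shared across partitions up to a per-partition rate
multiplier (proportional branch lengths); the first partition's multiplier
is fixed at 1 for identifiability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .matrix_io import CharacterMatrix, PartitionScheme, build_partitions

__all__ = [
    "MkModel",
    "transition_matrix",
    "discrete_gamma_rates",
    "CompiledTree",
    "MatrixData",
    "MkEngine",
    "ALPHA_BOUNDS",
    "BRANCH_BOUNDS",
]

ALPHA_BOUNDS = (0.02, 100.0)
BRANCH_BOUNDS = (1e-8, 20.0)
MULTIPLIER_BOUNDS = (1e-3, 1e3)

_EIG_CACHE: dict[tuple[int, bool], tuple[np.ndarray, np.ndarray]] = {}


def rate_matrix(k: int, ordered: bool) -> np.ndarray:
    """Normalized Mk generator: rows sum to 0, expected rate 1 at the
    uniform stationary distribution."""
    if not 2 <= k <= 5:
        raise ValueError(f"k must be in 2..5, got {k}")
    Q = np.zeros((k, k))
    if ordered and k > 2:
        mu = k / (2.0 * (k - 1))
        for i in range(k - 1):
            Q[i, i + 1] = mu
            Q[i + 1, i] = mu
    else:
        Q[:] = 1.0 / (k - 1)
        np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _eig(k: int, ordered: bool) -> tuple[np.ndarray, np.ndarray]:
    key = (k, bool(ordered) and k > 2)
    if key not in _EIG_CACHE:
        lam, V = np.linalg.eigh(rate_matrix(k, key[1]))
        _EIG_CACHE[key] = (lam, V)
    return _EIG_CACHE[key]


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean-per-category discretization of a mean-1 gamma distribution."""
    if ncat == 1:
        return np.ones(1)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    probs = np.arange(1, ncat) / ncat
    bounds = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    upper = gammainc(alpha + 1.0, alpha * bounds[1:])
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    rates = ncat * (upper - lower)
    # guard against numerical drift; the mean must be exactly 1
    return rates / rates.mean()


@dataclass
class MkModel:
    """Mk substitution model for one partition.

    Parameters
    ----------
    k : number of states (2-5).
    ordered : neighbor-only state exchange if True (and k >= 3).
    n_gamma_categories : 1 disables rate heterogeneity.
    alpha : gamma shape; required when ``n_gamma_categories > 1``.
    """

    k: int
    ordered: bool = False
    n_gamma_categories: int = 1
    alpha: float | None = None

    def __post_init__(self) -> None:
        if not 2 <= self.k <= 5:
            raise ValueError(f"k must be in 2..5, got {self.k}")
        if self.n_gamma_categories > 1 and self.alpha is None:
            self.alpha = 1.0

    def gamma_rates(self) -> np.ndarray:
        if self.n_gamma_categories == 1:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.n_gamma_categories)

    def rate_matrix(self) -> np.ndarray:
        return rate_matrix(self.k, self.ordered)


def transition_matrix(model: MkModel, t: float, rate: float = 1.0) -> np.ndarray:
    """Transition probability matrix P(t * rate) for one branch.

    Unordered models use the Jukes-Cantor-type closed form implied by the
    eigendecomposition; ordered models exponentiate the tridiagonal stepwise
    generator.  Rows sum to 1.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    lam, V = _eig(model.k, model.ordered)
    P = (V * np.exp(lam * t * rate)) @ V.T
    return np.clip(P, 0.0, None)


# ----------------------------------------------------------------------
# Compiled tree
# ----------------------------------------------------------------------

class CompiledTree:
    """Array representation of an unrooted tree for pruning.

    Leaves are numbered by their taxon's position in the supplied taxon
    order; internal nodes follow in postorder.  ``edge_len[i]`` is the
    length of the edge above node ``i`` (root entry unused).
    """

    def __init__(self, tree: dendropy.Tree, taxa: Sequence[str]) -> None:
        self.tree = tree
        taxon_pos = {t: i for i, t in enumerate(taxa)}
        leaves = list(tree.leaf_node_iter())
        if len(leaves) != len(taxa):
            raise ValueError(
                f"tree has {len(leaves)} leaves but {len(taxa)} taxa expected"
            )
        _ensure_basal_trifurcation(tree)
        self.n_leaves = len(leaves)
        node_id: dict = {}
        for leaf in tree.leaf_node_iter():
            lab = leaf.taxon.label
            if lab not in taxon_pos:
                raise ValueError(f"tree taxon {lab!r} not in matrix")
            node_id[leaf] = taxon_pos[lab]
        internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
        for i, node in enumerate(internals):
            node_id[node] = self.n_leaves + i
        self.n_nodes = self.n_leaves + len(internals)
        self.root = node_id[tree.seed_node]
        self.post_internal: list[tuple[int, tuple[int, ...]]] = [
            (node_id[n], tuple(node_id[c] for c in n.child_nodes())) for n in internals
        ]
        self.edge_len = np.full(self.n_nodes, 0.1)
        self._nodes_by_id: dict[int, dendropy.Node] = {v: k for k, v in node_id.items()}
        for node, nid in node_id.items():
            if node.parent_node is not None:
                self.edge_len[nid] = (
                    node.edge.length if node.edge.length is not None else 0.1
                )
        self.edge_ids = np.array(
            [nid for nid in range(self.n_nodes) if nid != self.root], dtype=int
        )
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.children: dict[int, tuple[int, ...]] = {}
        for nid, kids in self.post_internal:
            self.children[nid] = kids
            for c in kids:
                self.parent[c] = nid

    def path_to_root(self, nid: int) -> list[int]:
        """Ancestor chain [parent(nid), ..., root]."""
        path = []
        cur = self.parent[nid]
        while cur != -1:
            path.append(int(cur))
            cur = self.parent[cur]
        return path

    def write_back_lengths(self) -> None:
        """Copy optimized lengths back onto the dendropy tree's edges."""
        for nid, node in self._nodes_by_id.items():
            if node.parent_node is not None:
                node.edge.length = float(self.edge_len[nid])


def _ensure_basal_trifurcation(tree: dendropy.Tree) -> None:
    """Suppress a bifurcating seed node so the tree is treated as unrooted."""
    seed = tree.seed_node
    children = seed.child_nodes()
    if len(children) == 2 and sum(1 for _ in tree.leaf_node_iter()) >= 3:
        internal = next((c for c in children if not c.is_leaf()), None)
        if internal is None:
            return
        other = children[0] if children[1] is internal else children[1]
        extra = internal.edge.length or 0.0
        seed.remove_child(internal)
        for gc in internal.child_nodes():
            internal.remove_child(gc)
            seed.add_child(gc)
        if other.edge.length is not None:
            other.edge.length += extra


# ----------------------------------------------------------------------
# Partitioned data
# ----------------------------------------------------------------------

@dataclass
class PartitionData:
    """Pattern-compressed character data for one partition."""

    key: tuple[bool, int]
    char_indices: np.ndarray  # 1-based
    pattern_of_char: np.ndarray
    tipdata: np.ndarray  # (n_taxa, n_patterns, k)
    pattern_weights: np.ndarray
    model: MkModel

    @property
    def n_chars(self) -> int:
        return len(self.char_indices)

    @property
    def n_patterns(self) -> int:
        return self.tipdata.shape[1]


#: Partition groups that do not receive gamma rate heterogeneity by default:
#: the characteristically character-poor unordered 5-state and ordered
#: 4-state groups.
DEFAULT_NO_GAMMA_GROUPS: tuple[tuple[bool, int], ...] = ((False, 5), (True, 4))


class MatrixData:
    """Pattern-compressed matrix + partition models, independent of topology."""

    def __init__(
        self,
        matrix: CharacterMatrix,
        scheme: PartitionScheme | None = None,
        n_gamma_categories: int = 4,
        no_gamma_groups: Sequence[tuple[bool, int]] = DEFAULT_NO_GAMMA_GROUPS,
        default_alpha: float = 1.0,
    ) -> None:
        if scheme is None:
            scheme = build_partitions(matrix)
        self.matrix = matrix
        self.scheme = scheme
        self.taxa = list(matrix.taxa)
        codes = matrix.state_codes()
        self.partitions: list[PartitionData] = []
        no_gamma = set(tuple(g) for g in no_gamma_groups)
        for key in scheme.keys:
            ordered, k = key
            chars = np.array(scheme.groups[key], dtype=int)
            sub = codes[:, chars - 1].astype(np.int8)
            # remap each character's observed states to 0..k-1 by rank
            # (order-preserving, so ordered characters keep their spacing)
            for c in range(sub.shape[1]):
                col = sub[:, c]
                obs = np.unique(col[col >= 0])
                if len(obs) > k:
                    raise ValueError(
                        f"character {chars[c]} has {len(obs)} states, partition k={k}"
                    )
                remap = {int(s): r for r, s in enumerate(obs)}
                sub[:, c] = np.array([remap.get(int(s), -1) for s in col], dtype=np.int8)
            patterns, inverse = np.unique(sub, axis=1, return_inverse=True)
            n_pat = patterns.shape[1]
            tipdata = np.ones((matrix.n_taxa, n_pat, k))
            obs_mask = patterns >= 0
            rows, cols = np.nonzero(obs_mask)
            tipdata[rows, cols, :] = 0.0
            tipdata[rows, cols, patterns[rows, cols]] = 1.0
            weights = np.bincount(inverse, minlength=n_pat).astype(float)
            ncat = 1 if key in no_gamma else n_gamma_categories
            model = MkModel(
                k=k,
                ordered=ordered,
                n_gamma_categories=ncat,
                alpha=default_alpha if ncat > 1 else None,
            )
            self.partitions.append(
                PartitionData(
                    key=key,
                    char_indices=chars,
                    pattern_of_char=inverse.astype(int),
                    tipdata=tipdata,
                    pattern_weights=weights,
                    model=model,
                )
            )
        # per-partition branch-length multipliers; first fixed at 1
        self.multipliers = np.ones(len(self.partitions))

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    def copy(self) -> "MatrixData":
        """Copy with independent model parameters but shared pattern data."""
        import copy as _copy

        new = _copy.copy(self)
        new.partitions = [
            PartitionData(
                key=p.key,
                char_indices=p.char_indices,
                pattern_of_char=p.pattern_of_char,
                tipdata=p.tipdata,
                pattern_weights=p.pattern_weights,
                model=MkModel(
                    k=p.model.k,
                    ordered=p.model.ordered,
                    n_gamma_categories=p.model.n_gamma_categories,
                    alpha=p.model.alpha,
                ),
            )
            for p in self.partitions
        ]
        new.multipliers = self.multipliers.copy()
        return new

    def included_characters(self) -> np.ndarray:
        return np.sort(np.concatenate([p.char_indices for p in self.partitions])) if self.partitions else np.array([], dtype=int)


# ----------------------------------------------------------------------
# Pruning engine
# ----------------------------------------------------------------------

def _partition_pattern_loglikes(
    ct: CompiledTree,
    tipdata: np.ndarray,
    k: int,
    ordered: bool,
    rates: np.ndarray,
    multiplier: float,
    ascertainment: bool = True,
) -> tuple[np.ndarray, float]:
    """Per-pattern corrected log-likelihoods and ln(1 - p_const).

    Felsenstein pruning with per-pattern scaling; gamma categories mixed
    with equal weights.  Constant patterns for the correction are appended
    as fully observed pseudo-patterns and evaluated in the same pass.
    """
    n_pat = tipdata.shape[1]
    ncat = len(rates)
    if ascertainment:
        const_block = np.broadcast_to(
            np.eye(k)[None, :, :], (ct.n_leaves, k, k)
        )
        tipdata = np.concatenate([tipdata, const_block], axis=1)
    n_aug = tipdata.shape[1]

    lam, V = _eig(k, ordered)
    ts = ct.edge_len * multiplier
    if np.any(ts < 0):
        raise ValueError("negative branch length")
    # P[node, cat] = V diag(exp(lam * t * r)) V^T
    E = np.exp(ts[:, None, None] * rates[None, :, None] * lam[None, None, :])
    P = np.einsum("ij,ncj,kj->ncik", V, E, V)
    np.clip(P, 0.0, None, out=P)

    partial = np.empty((ct.n_nodes, n_aug, ncat, k))
    partial[: ct.n_leaves] = tipdata[:, :, None, :]
    logscale = np.zeros(n_aug)
    for nid, children in ct.post_internal:
        work = np.einsum("cij,pcj->pci", P[children[0]], partial[children[0]])
        for child in children[1:]:
            work *= np.einsum("cij,pcj->pci", P[child], partial[child])
        mx = work.max(axis=(1, 2))
        mx = np.where(mx > 0.0, mx, 1.0)
        work /= mx[:, None, None]
        logscale += np.log(mx)
        partial[nid] = work
    site_l = partial[ct.root].mean(axis=2).mean(axis=1)  # mix cats, uniform pi
    with np.errstate(divide="ignore"):
        lnl = np.log(site_l) + logscale
    if not ascertainment:
        return lnl, 0.0
    p_const = float(np.exp(lnl[n_pat:]).sum())
    p_const = min(p_const, 1.0 - 1e-12)
    log_denom = np.log1p(-p_const)
    return lnl[:n_pat] - log_denom, log_denom


def column_loglike(
    tree: dendropy.Tree,
    taxa: Sequence[str],
    column: Sequence[int],
    model: MkModel,
    multiplier: float = 1.0,
    ascertainment: bool = True,
) -> float:
    """Corrected log-likelihood of a single character column.

    ``column`` holds one state code per taxon (-1 for missing-like cells:
    missing, inapplicable, or polymorphic scorings).
    """
    col = np.asarray(column, dtype=int)
    if np.any(col >= model.k):
        raise ValueError(f"state >= k={model.k} in column")
    ct = CompiledTree(tree.clone(depth=1), list(taxa))
    tipdata = np.ones((len(taxa), 1, model.k))
    for i, s in enumerate(col):
        if s >= 0:
            tipdata[i, 0, :] = 0.0
            tipdata[i, 0, s] = 1.0
    lnl, _ = _partition_pattern_loglikes(
        ct, tipdata, model.k, model.ordered, model.gamma_rates(), multiplier,
        ascertainment,
    )
    return float(lnl[0])


class MkEngine:
    """Likelihood machinery binding one topology to a :class:`MatrixData`.

    Branch lengths live in the compiled tree; partition rate multipliers and
    gamma shapes live in the shared :class:`MatrixData` (so a search can
    carry them across topologies).  Per-partition log-likelihoods are cached
    and invalidated selectively.
    """

    def __init__(
        self,
        data: MatrixData,
        tree: dendropy.Tree,
        ascertainment: bool = True,
    ) -> None:
        self.data = data
        self.ct = CompiledTree(tree, data.taxa)
        self.ascertainment = ascertainment
        self._cache: list[tuple[np.ndarray, float] | None] = [None] * data.n_partitions

    # -- likelihood ----------------------------------------------------
    def _partition(self, pidx: int) -> tuple[np.ndarray, float]:
        if self._cache[pidx] is None:
            p = self.data.partitions[pidx]
            self._cache[pidx] = _partition_pattern_loglikes(
                self.ct,
                p.tipdata,
                p.model.k,
                p.model.ordered,
                p.model.gamma_rates(),
                float(self.data.multipliers[pidx]),
                self.ascertainment,
            )
        return self._cache[pidx]

    def partition_lnL(self, pidx: int) -> float:
        lnl, _ = self._partition(pidx)
        return float(lnl @ self.data.partitions[pidx].pattern_weights)

    def total_lnL(self) -> float:
        return sum(self.partition_lnL(i) for i in range(self.data.n_partitions))

    def site_loglikes(self) -> dict[int, float]:
        """Corrected per-character log-likelihoods keyed by 1-based index."""
        out: dict[int, float] = {}
        for i, p in enumerate(self.data.partitions):
            lnl, _ = self._partition(i)
            per_char = lnl[p.pattern_of_char]
            for c, v in zip(p.char_indices, per_char):
                out[int(c)] = float(v)
        return out

    def _invalidate(self, pidx: int | None = None) -> None:
        if pidx is None:
            self._cache = [None] * self.data.n_partitions
        else:
            self._cache[pidx] = None

    # -- fast per-edge optimization -------------------------------------
    def _sweep_edges(self, edges: Sequence[int], xatol: float) -> None:
        """One branch-length sweep using cached up/down partials.

        For each edge the likelihood is a cheap one-dimensional function of
        that edge's length (outside partial x P(t) x inside partial), so the
        line search costs almost nothing; after each accepted update the
        inside partials are refreshed only along the path to the root.
        """
        states = [_SweepState(self, pidx) for pidx in range(self.data.n_partitions)]
        for eid in edges:
            views = [s.edge_view(eid) for s in states]
            cur_len = float(self.ct.edge_len[eid])

            def neg(t: float) -> float:
                return -sum(s.edge_lnl(t, v) for s, v in zip(states, views))

            f_cur = neg(cur_len)
            res = minimize_scalar(
                neg, bounds=BRANCH_BOUNDS, method="bounded",
                options={"xatol": xatol, "maxiter": 60},
            )
            if res.fun < f_cur - 1e-12:
                self.ct.edge_len[eid] = float(res.x)
                for s in states:
                    s.refresh_edge(eid)
        self._invalidate()

    # -- coordinate-ascent optimization ---------------------------------
    def _opt_edge(self, eid: int, xatol: float) -> None:
        cur_len = self.ct.edge_len[eid]
        cur = self.total_lnL()

        def neg(x: float) -> float:
            self.ct.edge_len[eid] = x
            self._invalidate()
            return -self.total_lnL()

        res = minimize_scalar(
            neg, bounds=BRANCH_BOUNDS, method="bounded",
            options={"xatol": xatol, "maxiter": 40},
        )
        if -res.fun > cur:
            self.ct.edge_len[eid] = float(res.x)
        else:
            self.ct.edge_len[eid] = cur_len
        self._invalidate()

    def _opt_partition_scalar(self, pidx: int, kind: str, xatol: float) -> None:
        data = self.data
        if kind == "multiplier":
            cur_val = float(data.multipliers[pidx])
            bounds = np.log(MULTIPLIER_BOUNDS)
        else:
            cur_val = float(data.partitions[pidx].model.alpha)
            bounds = np.log(ALPHA_BOUNDS)
        cur = self.partition_lnL(pidx)

        def setval(v: float) -> None:
            if kind == "multiplier":
                data.multipliers[pidx] = v
            else:
                data.partitions[pidx].model.alpha = v
            self._invalidate(pidx)

        def neg(logx: float) -> float:
            setval(float(np.exp(logx)))
            return -self.partition_lnL(pidx)

        res = minimize_scalar(
            neg, bounds=tuple(bounds), method="bounded",
            options={"xatol": xatol, "maxiter": 40},
        )
        if -res.fun > cur:
            setval(float(np.exp(res.x)))
        else:
            setval(cur_val)

    def optimize(
        self,
        tol: float = 1e-6,
        max_sweeps: int = 200,
        xatol: float = 1e-5,
        optimize_lengths: bool = True,
        optimize_rates: bool = True,
        edge_subset: Sequence[int] | None = None,
        warn: bool = True,
    ) -> tuple[float, bool, int]:
        """Coordinate ascent over branch lengths, partition multipliers and
        gamma shapes.  Returns (lnL, converged, sweeps).

        Each one-dimensional line search only ever replaces a parameter when
        it improves the target partition's likelihood, so the total
        log-likelihood is non-decreasing across sweeps.
        """
        prev = self.total_lnL()
        converged = False
        sweeps = 0
        if max_sweeps <= 0:
            self.ct.write_back_lengths()
            return prev, True, 0
        edges = list(edge_subset) if edge_subset is not None else list(self.ct.edge_ids)
        for sweeps in range(1, max_sweeps + 1):
            if optimize_lengths:
                self._sweep_edges(edges, xatol)
            if optimize_rates:
                for pidx in range(1, self.data.n_partitions):
                    self._opt_partition_scalar(pidx, "multiplier", xatol)
                for pidx in range(self.data.n_partitions):
                    if self.data.partitions[pidx].model.n_gamma_categories > 1:
                        self._opt_partition_scalar(pidx, "alpha", xatol)
            cur = self.total_lnL()
            if cur - prev < tol:
                converged = True
                prev = max(cur, prev)
                break
            prev = cur
        if not converged and warn:
            warnings.warn(
                f"optimizer did not converge in {max_sweeps} sweeps; "
                "returning best-so-far",
                RuntimeWarning,
            )
        self.ct.write_back_lengths()
        return prev, converged, sweeps


class _SweepState:
    """Per-partition cached partials for one branch-length sweep."""

    def __init__(self, eng: MkEngine, pidx: int) -> None:
        p = eng.data.partitions[pidx]
        self.ct = eng.ct
        self.k = p.model.k
        self.rates = p.model.gamma_rates()
        self.ncat = len(self.rates)
        self.mult = float(eng.data.multipliers[pidx])
        self.lam, self.V = _eig(self.k, p.model.ordered)
        self.weights = p.pattern_weights
        self.n_pat = p.n_patterns
        self.ascertainment = eng.ascertainment
        tip = p.tipdata
        if self.ascertainment:
            const_block = np.broadcast_to(
                np.eye(self.k)[None, :, :], (self.ct.n_leaves, self.k, self.k)
            )
            tip = np.concatenate([tip, const_block], axis=1)
        self.tip = tip
        self.n_aug = tip.shape[1]
        self.P = np.empty((self.ct.n_nodes, self.ncat, self.k, self.k))
        for nid in range(self.ct.n_nodes):
            if nid != self.ct.root:
                self.P[nid] = self.P_of(self.ct.edge_len[nid])
        self.partial = np.empty((self.ct.n_nodes, self.n_aug, self.ncat, self.k))
        self.scale = np.zeros((self.ct.n_nodes, self.n_aug))
        self.partial[: self.ct.n_leaves] = tip[:, :, None, :]
        for nid, kids in self.ct.post_internal:
            self._combine(nid, kids)

    def P_of(self, t: float) -> np.ndarray:
        E = np.exp(self.lam[None, :] * (t * self.mult * self.rates)[:, None])
        P = np.einsum("ij,cj,kj->cik", self.V, E, self.V)
        return np.clip(P, 0.0, None)

    def _message(self, nid: int) -> np.ndarray:
        return np.einsum("cij,pcj->pci", self.P[nid], self.partial[nid])

    def _combine(self, nid: int, kids: tuple[int, ...]) -> None:
        work = self._message(kids[0])
        sc = self.scale[kids[0]].copy()
        for c in kids[1:]:
            work = work * self._message(c)
            sc += self.scale[c]
        mx = work.max(axis=(1, 2))
        mx = np.where(mx > 0.0, mx, 1.0)
        work /= mx[:, None, None]
        self.partial[nid] = work
        self.scale[nid] = sc + np.log(mx)

    def refresh_edge(self, eid: int) -> None:
        """Edge length changed: update its P and ancestor partials."""
        self.P[eid] = self.P_of(self.ct.edge_len[eid])
        for u in self.ct.path_to_root(eid):
            self._combine(u, self.ct.children[u])

    def up_to_edge(self, eid: int) -> tuple[np.ndarray, np.ndarray]:
        """Outside partial W at the parent end of edge ``eid`` (with the
        uniform root frequencies folded in) and its per-pattern log-scaler."""
        chain = [eid] + self.ct.path_to_root(eid)
        U = np.full((self.n_aug, self.ncat, self.k), 1.0 / self.k)
        sU = np.zeros(self.n_aug)
        for depth in range(len(chain) - 1, 0, -1):
            u, v = chain[depth], chain[depth - 1]
            W = U
            sW = sU
            for x in self.ct.children[u]:
                if x == v:
                    continue
                W = W * self._message(x)
                sW = sW + self.scale[x]
            mx = W.max(axis=(1, 2))
            mx = np.where(mx > 0.0, mx, 1.0)
            W = W / mx[:, None, None]
            sW = sW + np.log(mx)
            if v == eid:
                return W, sW
            U = np.einsum("pci,cij->pcj", W, self.P[v])
            sU = sW
        raise AssertionError("edge not reached")  # pragma: no cover

    def edge_view(self, eid: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Precompute the diagonalized inside-x-outside product for one edge.

        With P(t) = V diag(exp(lam t)) V', the per-pattern likelihood is
        sum_j G[p, c, j] * exp(lam_j * m * r_c * t) where G folds the
        outside partial W and the inside partial through V, so each trial
        length costs one small contraction.
        """
        W, sW = self.up_to_edge(eid)
        G = (W @ self.V) * (self.partial[eid] @ self.V)
        S = sW + self.scale[eid]
        coef = self.lam[None, :] * (self.mult * self.rates)[:, None]
        return G, S, coef

    def edge_lnl(self, t: float, view: tuple) -> float:
        """Weighted corrected log-likelihood of this partition as a function
        of one edge length, using a precomputed edge view."""
        G, S, coef = view
        val = np.einsum("pck,ck->pc", G, np.exp(coef * t)).mean(axis=1)
        np.maximum(val, 1e-300, out=val)
        lnl = np.log(val) + S
        if not self.ascertainment:
            return float(lnl[: self.n_pat] @ self.weights)
        p_const = float(np.exp(lnl[self.n_pat :]).sum())
        p_const = min(p_const, 1.0 - 1e-12)
        return float(
            (lnl[: self.n_pat] - np.log1p(-p_const)) @ self.weights
        )
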