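"""Nonparametric tree-space difficulty score.

Given the maximum-likelihood trees from a collection of independent
searches and the plausibility flags assigned to them by the topology tests,
the difficulty of the inference problem is the unweighted mean of five
terms, each in [0, 1]:

    difficulty = ( d_all + d_pl + n'_all/n_all + n'_pl/n_pl
                   + (1 - n_pl/n_all) ) / 5

where d_all is the average pairwise normalized Robinson-Foulds distance over
all n_all trees, n'_all the number of unique topologies among them, and the
"pl" quantities are the same restricted to the plausible subset.  A value of
0 means the search problem is trivial (every search finds the same, single
plausible topology); 1 means it is effectively impossible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .trees import pairwise_rf_matrix, split_set

__all__ = ["DifficultyReport", "difficulty_score"]


@dataclass
class DifficultyReport:
    """Components and value of the difficulty score."""

    d_bar_all: float
    d_bar_pl: float
    n_all: int
    n_unique_all: int
    n_pl: int
    n_unique_pl: int

    @property
    def score(self) -> float:
        return (
            self.d_bar_all
            + self.d_bar_pl
            + self.n_unique_all / self.n_all
            + self.n_unique_pl / self.n_pl
            + (1.0 - self.n_pl / self.n_all)
        ) / 5.0

    def as_dict(self) -> dict:
        return {
            "d_bar_all": self.d_bar_all,
            "d_bar_pl": self.d_bar_pl,
            "n_all": self.n_all,
            "n_unique_all": self.n_unique_all,
            "n_pl": self.n_pl,
            "n_unique_pl": self.n_unique_pl,
            "score": self.score,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


def _mean_pairwise(rf: np.ndarray) -> float:
    m = rf.shape[0]
    if m < 2:
        return 0.0
    iu = np.triu_indices(m, k=1)
    return float(rf[iu].mean())


def _n_unique(trees: Sequence[dendropy.Tree]) -> int:
    """Unique topologies under RF = 0 equivalence (identical split sets)."""
    seen = set()
    for t in trees:
        seen.add(frozenset(split_set(t)))
    return len(seen)


def difficulty_score(
    trees: Sequence[dendropy.Tree], plausible: Sequence[bool]
) -> DifficultyReport:
    """Compute the difficulty report for a searched tree collection.

    ``plausible`` flags trees retained by the topology tests; at least one
    tree (the best-scoring one) must be plausible.  Topology uniqueness
    ignores branch lengths and support values; the average-distance terms
    are means over unordered pairs, defined as 0 for singleton sets.
    """
    trees = list(trees)
    plausible = [bool(p) for p in plausible]
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    if len(plausible) != len(trees):
        raise ValueError("plausible flags must match tree count")
    if not any(plausible):
        raise ValueError("no plausible tree (the best tree is always plausible)")
    rf = pairwise_rf_matrix(trees)
    pl_idx = [i for i, p in enumerate(plausible) if p]
    rf_pl = rf[np.ix_(pl_idx, pl_idx)]
    pl_trees = [trees[i] for i in pl_idx]
    return DifficultyReport(
        d_bar_all=_mean_pairwise(rf),
        d_bar_pl=_mean_pairwise(rf_pl),
        n_all=len(trees),
        n_unique_all=_n_unique(trees),
        n_pl=len(pl_trees),
        n_unique_pl=_n_unique(pl_trees),
    )
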