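"""Site-likelihood-based tree comparison.

All tests operate on a table of per-character log-likelihoods under each
candidate topology, using RELL (resampling estimated log-likelihoods):
bootstrap replicates resample characters with replacement (stratified by
partition) and sum stored values, with no re-optimization.

Implemented tests
-----------------
* bp (RELL): bootstrap proportion — the fraction of replicates in which a
  tree has the highest total (ties split evenly).
* KH: one-sided Kishino-Hasegawa test of each tree against the best of the
  other trees, with the centered-RELL null.
* SH / wSH: Shimodaira-Hasegawa max-statistic test over all candidates, and
  its per-pair standardized (weighted) variant.
* ELW: expected likelihood weights — replicate-wise likelihood weights
  averaged over replicates; confidence set by cumulative weight.
* AU: approximately unbiased test — multiscale RELL with a signed
  distance / curvature fit by weighted least squares, p = 1 - Phi(d - c).

A tree is *plausible* if no test rejects it at the chosen level (the
maximum-likelihood tree is always plausible).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SiteLikelihoodTable",
    "TopoTestResult",
    "rell_resample",
    "run_tests",
    "plausible_set",
]


class SiteLikelihoodTable:
    """Characters x trees table of per-character log-likelihoods.

    Values are on the ascertainment-corrected scale, so each column sums to
    the corresponding tree's total log-likelihood.  ``partition_of``
    optionally maps each 1-based character index to a partition key, used to
    stratify RELL resampling.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        partition_of: Mapping[int, object] | None = None,
    ) -> None:
        self.df = values.sort_index()
        self.df.index.name = "character"
        if partition_of is not None:
            strata: dict[object, list[int]] = {}
            for c in self.df.index:
                strata.setdefault(partition_of.get(int(c), 0), []).append(int(c))
            self._strata = [np.array([self.df.index.get_loc(c) for c in chars])
                            for chars in strata.values()]
        else:
            self._strata = [np.arange(len(self.df))]

    @classmethod
    def from_results(cls, results: Sequence, partition_of=None) -> "SiteLikelihoodTable":
        """Assemble from fitted :class:`~morphoconflict.model.MkResults`
        (their labels become tree names)."""
        cols = {}
        for i, r in enumerate(results):
            label = r.label or f"tree{i + 1}"
            cols[label] = r.site_loglikes()
        df = pd.DataFrame(cols)
        if partition_of is None and results:
            partition_of = results[0].model.scheme.partition_of()
        return cls(df, partition_of)

    @property
    def tree_labels(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_characters(self) -> int:
        return len(self.df)

    def totals(self) -> pd.Series:
        return self.df.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        long = self.df.reset_index().melt(
            id_vars="character", var_name="tree", value_name="lnL"
        )
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SiteLikelihoodTable":
        long = pd.read_csv(path, sep="\t")
        wide = long.pivot(index="character", columns="tree", values="lnL")
        wide.columns.name = None
        return cls(wide)


def _stratified_counts(
    strata: list[np.ndarray], n_total: int, B: int, rng: np.random.Generator,
    scale: float = 1.0,
) -> np.ndarray:
    """(B, n_chars) resample counts, drawn within each stratum."""
    counts = np.zeros((B, n_total), dtype=np.int32)
    for idx in strata:
        n_p = len(idx)
        n_draw = max(1, int(round(scale * n_p)))
        c = rng.multinomial(n_draw, np.full(n_p, 1.0 / n_p), size=B)
        counts[:, idx] = c
    return counts


def rell_resample(
    table: SiteLikelihoodTable, B: int, seed: int = 0, scale: float = 1.0
) -> np.ndarray:
    """(B, n_trees) matrix of resampled total log-likelihoods."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    V = table.df.to_numpy()
    counts = _stratified_counts(table._strata, len(V), B, rng, scale)
    return counts.astype(float) @ V


def _bp_from_totals(R: np.ndarray) -> np.ndarray:
    """Bootstrap proportions with exact ties split evenly."""
    B, T = R.shape
    mx = R.max(axis=1, keepdims=True)
    winners = R >= mx - 1e-12
    return (winners / winners.sum(axis=1, keepdims=True)).sum(axis=0) / B


@dataclass
class TopoTestResult:
    """Per-tree test outcomes (a DataFrame wrapper)."""

    table: pd.DataFrame  # index: tree label
    alpha: float

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]

    @property
    def plausible(self) -> pd.Series:
        return self.table["plausible"]

    def summary(self) -> str:
        df = self.table.copy()
        lines = [f"Topology tests (alpha = {self.alpha})", "-" * 78]
        lines.append(df.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def run_tests(
    table: SiteLikelihoodTable,
    B: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    au_scales: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4),
) -> TopoTestResult:
    """Run RELL, KH, SH, wSH, ELW, and AU on a site-likelihood table."""
    labels = table.tree_labels
    T = len(labels)
    totals = table.totals().to_numpy()
    R = rell_resample(table, B, seed=seed)
    C = R - R.mean(axis=0, keepdims=True)

    bp = _bp_from_totals(R)

    # --- KH: one-sided vs. the best of the other trees -----------------
    p_kh = np.ones(T)
    for t in range(T):
        others = [j for j in range(T) if j != t]
        if not others:
            continue
        j = others[int(np.argmax(totals[others]))]
        d_obs = totals[j] - totals[t]
        D = C[:, j] - C[:, t]
        if np.allclose(D, 0.0) and abs(d_obs) < 1e-12:
            p_kh[t] = 1.0
        else:
            p_kh[t] = float(np.mean(D >= d_obs - 1e-12))

    # --- SH: max statistic over all candidates --------------------------
    p_sh = np.ones(T)
    null_max = C.max(axis=1)
    best_total = totals.max()
    for t in range(T):
        d_obs = best_total - totals[t]
        p_sh[t] = float(np.mean(null_max - C[:, t] >= d_obs - 1e-12))

    # --- wSH: per-pair standardized max statistic ------------------------
    p_wsh = np.ones(T)
    for t in range(T):
        stats_obs = []
        null_stats = np.full(R.shape[0], -np.inf)
        any_pair = False
        degenerate_worse = False
        for j in range(T):
            if j == t:
                continue
            D = C[:, j] - C[:, t]
            s = float(D.std(ddof=1)) if R.shape[0] > 1 else 0.0
            if s <= 1e-12:
                # no resampling variance for this pair: reject outright if
                # the tree is genuinely worse, otherwise the pair is inert
                if totals[j] - totals[t] > 1e-9:
                    degenerate_worse = True
                continue
            any_pair = True
            stats_obs.append((totals[j] - totals[t]) / s)
            null_stats = np.maximum(null_stats, D / s)
        if degenerate_worse:
            p_wsh[t] = 0.0
        elif not any_pair:
            p_wsh[t] = 1.0
        else:
            p_wsh[t] = float(np.mean(null_stats >= max(stats_obs) - 1e-12))

    # --- ELW -------------------------------------------------------------
    W = R - R.max(axis=1, keepdims=True)
    W = np.exp(W)
    W /= W.sum(axis=1, keepdims=True)
    c_elw = W.mean(axis=0)
    order = np.argsort(-c_elw, kind="stable")
    cum = np.cumsum(c_elw[order])
    in_set = np.zeros(T, dtype=bool)
    needed = True
    for rank, t in enumerate(order):
        in_set[t] = needed
        if needed and cum[rank] >= 1.0 - alpha - 1e-12:
            needed = False

    # --- AU --------------------------------------------------------------
    p_au = _au_test(table, B, seed, au_scales)

    best = int(np.argmax(totals))
    plausible = (
        (p_kh >= alpha) & (p_sh >= alpha) & (p_wsh >= alpha) & (p_au >= alpha) & in_set
    )
    plausible[best] = True

    df = pd.DataFrame(
        {
            "lnL": totals,
            "bp_RELL": bp,
            "p_KH": p_kh,
            "p_SH": p_sh,
            "p_wSH": p_wsh,
            "p_AU": p_au,
            "c_ELW": c_elw,
            "plausible": plausible,
        },
        index=pd.Index(labels, name="tree"),
    ).sort_values("lnL", ascending=False)
    return TopoTestResult(df, alpha)


def _au_test(
    table: SiteLikelihoodTable, B: int, seed: int, scales: Sequence[float]
) -> np.ndarray:
    """Approximately unbiased test via multiscale RELL."""
    V = table.df.to_numpy()
    T = V.shape[1]
    n_scales = len(scales)
    B_r = max(100, B // n_scales)
    rng = np.random.default_rng(seed + 1)
    bps = np.zeros((n_scales, T))
    for si, r in enumerate(scales):
        counts = _stratified_counts(table._strata, len(V), B_r, rng, scale=r)
        R = counts.astype(float) @ V
        bps[si] = _bp_from_totals(R)
    eps = 0.5 / B_r
    p = np.zeros(T)
    rs = np.asarray(scales, dtype=float)
    for t in range(T):
        b = bps[:, t]
        valid = (b > eps) & (b < 1 - eps)
        if b.min() >= 1 - eps:
            p[t] = 1.0
            continue
        if b.max() <= eps:
            p[t] = 0.0
            continue
        if valid.sum() < 2:
            p[t] = float(np.clip(b[np.argmin(np.abs(rs - 1.0))], 0.0, 1.0))
            continue
        z = norm.ppf(1.0 - b[valid])
        X = np.column_stack([np.sqrt(rs[valid]), 1.0 / np.sqrt(rs[valid])])
        w = B_r * norm.pdf(z) ** 2 / (b[valid] * (1 - b[valid]))
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ z, rcond=None)
        d, c = beta
        p[t] = float(np.clip(1.0 - norm.cdf(d - c), 0.0, 1.0))
    return p


def plausible_set(results: TopoTestResult) -> pd.Series:
    """Boolean plausibility flags: a tree stays in the set iff no test
    rejects it (and the best tree is always retained)."""
    return results.plausible
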