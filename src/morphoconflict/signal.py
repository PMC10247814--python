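"""Per-character support decomposition.

Given per-character log-likelihoods under the three candidate resolutions of
the focal branch (S, Of, Os), this module computes:

* phylogenetic signal PS — the mean of the three absolute pairwise
  log-likelihood differences;
* pairwise support dCLS(A, B) = lnL(A) - lnL(B);
* favored-hypothesis counts (argmax per character, near-ties excluded) and
  an exact multinomial test of uniformity;
* outlier characters (values more than three standard deviations above the
  mean, one-sided) with a two-of-three rule across the pairwise
  comparisons;
* "strong" characters whose best-vs-second-best gap exceeds a threshold.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .topo_tests import SiteLikelihoodTable

__all__ = [
    "HYPOTHESES",
    "TIE_TOL",
    "phylogenetic_signal",
    "delta_cls",
    "SignalReport",
    "signal_report",
    "favored_counts",
    "multinomial_uniformity",
    "ranking_agreement",
    "detect_outliers",
    "strong_characters",
]

HYPOTHESES = ("S", "Of", "Os")
PAIRS = (("S", "Of"), ("S", "Os"), ("Of", "Os"))

#: log-likelihoods within this tolerance are treated as exact ties;
#: PS-style quantities are overly sensitive to minor branch-length
#: differences, so near-ties must not be silently assigned a winner.
TIE_TOL = 1e-9


def phylogenetic_signal(lnl_s, lnl_of, lnl_os):
    """Mean of the three absolute pairwise log-likelihood differences."""
    a, b, c = (np.asarray(x, dtype=float) for x in (lnl_s, lnl_of, lnl_os))
    return (np.abs(a - b) + np.abs(a - c) + np.abs(b - c)) / 3.0


def delta_cls(lnl_a, lnl_b):
    """Signed per-character support for hypothesis A over hypothesis B."""
    return np.asarray(lnl_a, dtype=float) - np.asarray(lnl_b, dtype=float)


def detect_outliers(values: Sequence[float]) -> np.ndarray:
    """One-sided outlier flags: value > mean + 3 * sample standard deviation.

    Sample (n-1) standard deviation; with fewer than two values, or zero
    spread, nothing is flagged.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0.0:
        return np.zeros(len(v), dtype=bool)
    return v > v.mean() + 3.0 * sd


def _favored(values: np.ndarray) -> str:
    order = np.argsort(-values, kind="stable")
    if values[order[0]] - values[order[1]] <= TIE_TOL:
        return "tie"
    return HYPOTHESES[order[0]]


def strong_characters(
    lnls: np.ndarray | pd.DataFrame, threshold: float = 0.5
) -> np.ndarray:
    """Flag characters whose best-minus-second-best lnL gap exceeds
    ``threshold`` (default 0.5)."""
    V = np.asarray(lnls, dtype=float)
    part = np.sort(V, axis=1)
    return (part[:, -1] - part[:, -2]) > threshold


class SignalReport:
    """Per-character signal decomposition (wraps a DataFrame).

    Columns: lnL_S, lnL_Of, lnL_Os, PS, dCLS_S_Of, dCLS_S_Os, dCLS_Of_Os,
    favored, region, is_ps_outlier, dcls_outlier_count, is_strong.
    """

    def __init__(self, df: pd.DataFrame, strong_threshold: float = 0.5) -> None:
        self.df = df
        self.strong_threshold = strong_threshold

    @property
    def ps(self) -> pd.Series:
        return self.df["PS"]

    def outlier_characters(self) -> list[int]:
        """PS outliers, in descending order of PS."""
        sub = self.df[self.df["is_ps_outlier"]]
        return list(sub.sort_values("PS", ascending=False).index)

    def top_characters(self, n: int) -> list[int]:
        """The n highest-PS characters (PS ties broken by lower index)."""
        if n > len(self.df):
            raise ValueError(f"top_n={n} exceeds character count {len(self.df)}")
        sub = self.df.assign(_i=self.df.index).sort_values(
            ["PS", "_i"], ascending=[False, True]
        )
        return list(sub.index[:n])

    def strong_flags(self) -> pd.Series:
        return self.df["is_strong"]

    def table4_style(self) -> pd.DataFrame:
        """Characters that are PS outliers and dCLS outliers in at least two
        of the three pairwise comparisons, with the hypothesis they strongly
        favor (+) or disfavor (-) relative to both alternatives."""
        sub = self.df[(self.df["is_ps_outlier"]) & (self.df["dcls_outlier_count"] >= 2)]
        rows = []
        for c, row in sub.iterrows():
            lnls = np.array([row["lnL_S"], row["lnL_Of"], row["lnL_Os"]])
            marks = []
            hi, lo = int(np.argmax(lnls)), int(np.argmin(lnls))
            if _pair_outliers_for(row, hi) >= 2:
                marks.append(f"{HYPOTHESES[hi]} (+)")
            if lo != hi and _pair_outliers_for(row, lo) >= 2:
                marks.append(f"{HYPOTHESES[lo]} (-)")
            rows.append({"character": c, "PS": row["PS"], "label": "; ".join(marks)})
        return pd.DataFrame(rows).set_index("character") if rows else pd.DataFrame(
            columns=["PS", "label"]
        )

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t")


_PAIR_COLS = ("dCLS_S_Of", "dCLS_S_Os", "dCLS_Of_Os")
_PAIRS_OF_HYP = {0: ("dCLS_S_Of", "dCLS_S_Os"), 1: ("dCLS_S_Of", "dCLS_Of_Os"),
                 2: ("dCLS_S_Os", "dCLS_Of_Os")}


def _pair_outliers_for(row: pd.Series, hyp_idx: int) -> int:
    cols = _PAIRS_OF_HYP[hyp_idx]
    return sum(int(row[f"outlier_{c}"]) for c in cols)


def signal_report(
    table: SiteLikelihoodTable | pd.DataFrame,
    regions: Mapping[int, str] | Sequence[str] | None = None,
    strong_threshold: float = 0.5,
) -> SignalReport:
    """Build the per-character signal decomposition from a site-likelihood
    table with columns S, Of, Os."""
    df_in = table.df if isinstance(table, SiteLikelihoodTable) else table
    missing = [h for h in HYPOTHESES if h not in df_in.columns]
    if missing:
        raise ValueError(f"site-likelihood table lacks hypothesis columns {missing}")
    idx = df_in.index
    V = df_in[list(HYPOTHESES)].to_numpy(dtype=float)
    out = pd.DataFrame(index=idx)
    out["lnL_S"], out["lnL_Of"], out["lnL_Os"] = V[:, 0], V[:, 1], V[:, 2]
    out["PS"] = phylogenetic_signal(V[:, 0], V[:, 1], V[:, 2])
    out["dCLS_S_Of"] = V[:, 0] - V[:, 1]
    out["dCLS_S_Os"] = V[:, 0] - V[:, 2]
    out["dCLS_Of_Os"] = V[:, 1] - V[:, 2]
    out["favored"] = [_favored(v) for v in V]
    if regions is not None:
        if isinstance(regions, Mapping):
            out["region"] = [regions.get(int(c), "") for c in idx]
        else:
            out["region"] = [regions[int(c) - 1] for c in idx]
    else:
        out["region"] = ""
    out["is_ps_outlier"] = detect_outliers(out["PS"].to_numpy())
    count = np.zeros(len(out), dtype=int)
    for col in _PAIR_COLS:
        flags = detect_outliers(np.abs(out[col].to_numpy()))
        out[f"outlier_{col}"] = flags
        count += flags.astype(int)
    out["dcls_outlier_count"] = count
    out["is_strong"] = strong_characters(V, strong_threshold)
    return SignalReport(out, strong_threshold)


def favored_counts(
    report: SignalReport | pd.DataFrame, by_region: bool = False
) -> pd.DataFrame | pd.Series:
    """Characters favoring each hypothesis (ties reported separately)."""
    df = report.df if isinstance(report, SignalReport) else report
    cats = list(HYPOTHESES) + ["tie"]
    if by_region:
        out = df.groupby("region")["favored"].value_counts().unstack(fill_value=0)
        for c in cats:
            if c not in out.columns:
                out[c] = 0
        return out[cats]
    counts = df["favored"].value_counts()
    return pd.Series({c: int(counts.get(c, 0)) for c in cats})


def multinomial_uniformity(
    counts: Sequence[int], n_mc: int = 1_000_000, seed: int = 0, exact_max: int = 600
) -> float:
    """Exact multinomial goodness-of-fit p-value against uniform (1/k each).

    The p-value is the total probability, under the uniform multinomial, of
    all outcomes whose probability does not exceed that of the observed
    outcome.  Exhaustive enumeration is used for n <= ``exact_max``
    (three categories); Monte Carlo with ``n_mc`` draws beyond.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 1 or len(counts) != 3:
        raise ValueError("expected three category counts")
    if np.any(counts < 0) or counts.sum() < 1:
        raise ValueError("counts must be non-negative with a positive total")
    n = int(counts.sum())
    logp_obs = _multinomial_logpmf(counts[None, :], n)

    if n <= exact_max:
        i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        keep = (i + j) <= n
        outcomes = np.column_stack([i[keep], j[keep], (n - i - j)[keep]])
        logp = _multinomial_logpmf(outcomes, n)
        return float(np.exp(logp[logp <= logp_obs + 1e-10]).sum().clip(0.0, 1.0))
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, [1 / 3] * 3, size=n_mc)
    logp = _multinomial_logpmf(draws, n)
    return float(np.mean(logp <= logp_obs + 1e-10))


def _multinomial_logpmf(outcomes: np.ndarray, n: int) -> np.ndarray:
    k = outcomes.shape[1]
    return (
        gammaln(n + 1)
        - gammaln(outcomes + 1).sum(axis=1)
        - n * np.log(k)
    )


def ranking_agreement(
    table_a: SiteLikelihoodTable | pd.DataFrame,
    table_b: SiteLikelihoodTable | pd.DataFrame,
) -> tuple[int, int]:
    """Count shared characters with identical three-way lnL ranking, and with
    the same favored hypothesis, between two site-likelihood tables."""
    da = table_a.df if isinstance(table_a, SiteLikelihoodTable) else table_a
    db = table_b.df if isinstance(table_b, SiteLikelihoodTable) else table_b
    shared = da.index.intersection(db.index)
    va = da.loc[shared, list(HYPOTHESES)].to_numpy(dtype=float)
    vb = db.loc[shared, list(HYPOTHESES)].to_numpy(dtype=float)
    ra = np.argsort(np.argsort(-va, axis=1, kind="stable"), axis=1)
    rb = np.argsort(np.argsort(-vb, axis=1, kind="stable"), axis=1)
    n_same_ranking = int(np.all(ra == rb, axis=1).sum())
    fa = np.array([_favored(v) for v in va])
    fb = np.array([_favored(v) for v in vb])
    n_same_favored = int(((fa == fb) & (fa != "tie")).sum())
    return n_same_ranking, n_same_favored
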