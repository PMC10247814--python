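"""Sensitivity experiments: high-signal character removal and the
one-character-at-a-time rescoring scan.

Removal experiments drop the characters with the highest phylogenetic
signal (top-n, ties broken by lower index, or the PS-outlier set) and
re-search the reduced matrix to see whether the favored resolution of the
focal branch survives.

The rescoring scan takes two matrices that score the same characters (a
matrix pair differing by recoding), and for each eligible character swaps
its column in one matrix for its scoring in the other, re-runs the ML
search plus bootstrap, and records which resolution of the focal branch the
re-estimated tree supports.  A character is eligible iff its column
actually differs between the matrices and the swap does not render it
constant.  Where the target matrix has taxa the source lacks, only
shared-taxon cells are transferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .matrix_io import CharacterMatrix, build_partitions, profile_characters
from .search import ConstraintSet, bootstrap_support, derive_seed, ml_search
from .signal import SignalReport
from .trees import (
    DEFAULT_OUTGROUP,
    DEFAULT_REFERENCE_TAXA,
    HypothesisLabel,
    detect_hypothesis,
)

__all__ = [
    "remove_characters",
    "RemovalExperiment",
    "removal_experiment",
    "eligible_characters",
    "build_hybrid",
    "RescoringScanRecord",
    "rescoring_scan",
]


# ----------------------------------------------------------------------
# Character removal
# ----------------------------------------------------------------------

def remove_characters(
    m: CharacterMatrix,
    signal: SignalReport,
    top_n: int | None = None,
    outliers: bool = False,
) -> tuple[CharacterMatrix, list[int]]:
    """Drop the top-n PS characters or the PS-outlier set.

    Returns the reduced matrix and the removed 1-based indices.  The
    partition scheme of the reduced matrix must be rebuilt by the caller
    (character counts per group change).
    """
    if (top_n is None) == (not outliers):
        raise ValueError("specify exactly one of top_n / outliers")
    if top_n is not None:
        removed = signal.top_characters(top_n)
    else:
        removed = signal.outlier_characters()
    return m.drop_characters(removed), sorted(removed)


@dataclass
class RemovalExperiment:
    removal_spec: dict
    removed_characters: list[int]
    result: object  # SearchResult
    hypothesis: HypothesisLabel


def removal_experiment(
    m: CharacterMatrix,
    signal: SignalReport,
    spec: dict,
    seed: int = 0,
    refs: Sequence[str] = DEFAULT_REFERENCE_TAXA,
    outgroup: Sequence[str] = DEFAULT_OUTGROUP,
    bootstrap_B: int = 0,
    **search_kwargs,
) -> RemovalExperiment:
    """Remove characters per ``spec`` ({'top_n': n} or {'outliers': True}),
    re-search, and classify the resulting focal-branch resolution."""
    reduced, removed = remove_characters(
        m, signal, top_n=spec.get("top_n"), outliers=spec.get("outliers", False)
    )
    scheme = build_partitions(reduced)
    res = ml_search(reduced, scheme, seed=derive_seed(seed, "removal", *removed),
                    **search_kwargs)
    tree = res.best_tree
    if bootstrap_B > 0:
        tree = bootstrap_support(
            reduced, scheme, tree, B=bootstrap_B,
            seed=derive_seed(seed, "removal-boot", *removed), data=res.data,
        )
    return RemovalExperiment(
        removal_spec=spec,
        removed_characters=removed,
        result=res,
        hypothesis=detect_hypothesis(tree, refs, outgroup),
    )


# ----------------------------------------------------------------------
# Rescoring scan
# ----------------------------------------------------------------------

def _column_key(m: CharacterMatrix, rows: Sequence[int], j: int) -> tuple:
    """Comparable representation of one column over the given taxon rows,
    with polymorphic and inapplicable cells equated to missing (the
    maximum-likelihood view of the data)."""
    from .matrix_io import _comparable

    key = _comparable(m.kinds[rows, j : j + 1], m.masks[rows, j : j + 1], True)
    return tuple(int(v) for v in key[:, 0])


def build_hybrid(
    a: CharacterMatrix, b: CharacterMatrix, char_1based: int
) -> CharacterMatrix:
    """Matrix ``a`` with one character column rescored as in ``b`` (cells
    transferred for shared taxa only)."""
    j = char_1based - 1
    kinds_col = a.kinds[:, j].copy()
    masks_col = a.masks[:, j].copy()
    b_index = {t: i for i, t in enumerate(b.taxa)}
    for ia, t in enumerate(a.taxa):
        ib = b_index.get(t)
        if ib is not None:
            kinds_col[ia] = b.kinds[ib, j]
            masks_col[ia] = b.masks[ib, j]
    return a.with_column(char_1based, kinds_col, masks_col)


def eligible_characters(
    a: CharacterMatrix, b: CharacterMatrix
) -> dict[str, list[int]]:
    """Characters eligible for the rescoring scan, per direction.

    Direction ``a2b`` rescoring character c means: in matrix ``a``, replace
    column c by matrix ``b``'s scoring (shared taxa only).  Eligible iff the
    hybrid column differs from the original under the likelihood view of
    the data and the hybrid column is not constant.
    """
    if a.n_chars != b.n_chars:
        raise ValueError("matrices must score the same characters")
    out: dict[str, list[int]] = {"a2b": [], "b2a": []}
    for direction, src, other in (("a2b", a, b), ("b2a", b, a)):
        rows = list(range(src.n_taxa))
        for c in range(1, src.n_chars + 1):
            hybrid = build_hybrid(src, other, c)
            if _column_key(src, rows, c - 1) == _column_key(hybrid, rows, c - 1):
                continue
            prof = profile_characters(hybrid)[c - 1]
            if prof.is_constant:
                continue
            out[direction].append(c)
    return out


@dataclass
class RescoringScanRecord:
    """One analysis of the rescoring scan."""

    character: int
    direction: str  # "a2b" or "b2a"
    eligible: bool
    hypothesis: HypothesisLabel
    lnL: float | None = None
    failed: bool = False


def rescoring_scan(
    a: CharacterMatrix,
    b: CharacterMatrix,
    direction: str = "a2b",
    characters: Sequence[int] | None = None,
    seed: int = 0,
    refs: Sequence[str] = DEFAULT_REFERENCE_TAXA,
    outgroup: Sequence[str] = DEFAULT_OUTGROUP,
    n_starts: int = 2,
    bootstrap_B: int = 0,
    constraint: ConstraintSet | None = None,
    **search_kwargs,
) -> list[RescoringScanRecord]:
    """Re-search after swapping each eligible character's scoring.

    ``characters`` restricts the scan to a subset (they must be eligible
    unless explicitly supplied).  Per-character seeds derive
    deterministically from the master seed, so records are independent of
    execution order and reproducible bit-for-bit.
    """
    if direction not in ("a2b", "b2a"):
        raise ValueError("direction must be 'a2b' or 'b2a'")
    src, other = (a, b) if direction == "a2b" else (b, a)
    if characters is None:
        characters = eligible_characters(a, b)[direction]
    records: list[RescoringScanRecord] = []
    for c in characters:
        rec_seed = derive_seed(seed, "rescoring", direction, c)
        try:
            hybrid = build_hybrid(src, other, c)
            scheme = build_partitions(hybrid)
            res = ml_search(
                hybrid, scheme, n_starts=n_starts, seed=rec_seed,
                constraint=constraint, **search_kwargs,
            )
            tree = res.best_tree
            if bootstrap_B > 0:
                tree = bootstrap_support(
                    hybrid, scheme, tree, B=bootstrap_B,
                    seed=derive_seed(rec_seed, "boot"), data=res.data,
                )
            records.append(
                RescoringScanRecord(
                    character=c,
                    direction=direction,
                    eligible=True,
                    hypothesis=detect_hypothesis(tree, refs, outgroup),
                    lnL=res.best_lnL,
                )
            )
        except Exception:
            records.append(
                RescoringScanRecord(
                    character=c, direction=direction, eligible=True,
                    hypothesis=HypothesisLabel("none"), failed=True,
                )
            )
    return records


def scan_records_tsv(records: Sequence[RescoringScanRecord], path) -> None:
    """Long-format scan report: character, direction, hypothesis, support."""
    with open(path, "w") as fh:
        fh.write("character\tdirection\teligible\thypothesis\tfocal_support\tfailed\n")
        for r in records:
            sup = "" if r.hypothesis.focal_support is None else f"{r.hypothesis.focal_support:.1f}"
            fh.write(
                f"{r.character}\t{r.direction}\t{int(r.eligible)}\t"
                f"{r.hypothesis.label}\t{sup}\t{int(r.failed)}\n"
            )
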