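"""Reading, validating, comparing, and partitioning NEXUS morphological matrices.

Cell conventions
----------------
Each cell of a discrete character matrix is one of

* a single state symbol ``0``–``5``,
* missing data ``?``,
* an inapplicable / gap token ``-``,
* a polymorphic state set written ``{01}`` or ``(01)``.

For all likelihood and state-counting purposes, polymorphic and inapplicable
cells are treated as missing: under maximum likelihood a polymorphism over
all plausible states is functionally equivalent to an unknown state, and the
missing/inapplicable distinction is purely notational.  The strict/lenient
distinction survives only in :func:`compare_matrices`, which can count
differences either way.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CharacterMatrix",
    "CharacterProfile",
    "MatrixDiff",
    "PartitionScheme",
    "read_nexus",
    "write_nexus",
    "read_ordered_list",
    "profile_characters",
    "compare_matrices",
    "build_partitions",
    "DEFAULT_REGIONS",
    "region_labels_from_ranges",
]

# Cell kinds
KIND_STATE = 0
KIND_MISSING = 1
KIND_INAPPLICABLE = 2
KIND_POLYMORPHIC = 3

MAX_STATES = 6  # symbols 0..5

#: Default anatomical-region ranges (1-based, inclusive) for 457-character
#: early-dinosaur matrices; overridable wherever regions are consumed.
DEFAULT_REGIONS: tuple[tuple[str, int, int], ...] = (
    ("cranial", 1, 146),
    ("dental", 147, 185),
    ("axial", 186, 236),
    ("pectoral", 237, 250),
    ("forelimb", 251, 291),
    ("pelvic", 292, 351),
    ("hindlimb", 352, 457),
)


def region_labels_from_ranges(
    n_chars: int, regions: Sequence[tuple[str, int, int]] = DEFAULT_REGIONS
) -> list[str]:
    """Per-character region tags from (name, first, last) 1-based ranges."""
    labels = [""] * n_chars
    for name, lo, hi in regions:
        for i in range(lo, min(hi, n_chars) + 1):
            labels[i - 1] = name
    return labels


class NexusParseError(ValueError):
    """Malformed NEXUS input; the message names the offending line."""


class DimensionError(ValueError):
    """Ragged rows or a dimension mismatch in a character matrix."""


class CharacterMatrix:
    """A taxa x characters table of discrete morphological states.

    Parameters
    ----------
    taxa
        Ordered taxon labels (unique).
    kinds
        ``(n_taxa, n_chars)`` uint8 array of cell kinds (state / missing /
        inapplicable / polymorphic).
    masks
        ``(n_taxa, n_chars)`` uint8 array; bit ``s`` set iff state ``s`` is
        part of the cell's scoring.  Zero for missing/inapplicable cells.
    ordered_flags
        Per-character booleans: declared ordered (additive) characters.
    region_labels
        Optional per-character anatomical region tags.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        kinds: np.ndarray,
        masks: np.ndarray,
        ordered_flags: np.ndarray | None = None,
        region_labels: Sequence[str] | None = None,
    ) -> None:
        self.taxa = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        self.kinds = np.asarray(kinds, dtype=np.uint8)
        self.masks = np.asarray(masks, dtype=np.uint8)
        if self.kinds.shape != self.masks.shape:
            raise DimensionError("kinds and masks shapes differ")
        if self.kinds.shape[0] != len(self.taxa):
            raise DimensionError(
                f"{len(self.taxa)} taxa but {self.kinds.shape[0]} matrix rows"
            )
        n_chars = self.kinds.shape[1]
        if ordered_flags is None:
            ordered_flags = np.zeros(n_chars, dtype=bool)
        self.ordered_flags = np.asarray(ordered_flags, dtype=bool)
        if self.ordered_flags.shape != (n_chars,):
            raise DimensionError("ordered_flags length mismatch")
        self.region_labels = list(region_labels) if region_labels is not None else None
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        state_cells = self.kinds == KIND_STATE
        if np.any(self.masks[state_cells] == 0):
            raise ValueError("state cell without a state bit")
        # single state cells carry exactly one bit
        pops = _popcount(self.masks)
        if np.any(pops[state_cells] != 1):
            raise ValueError("single-state cell with multiple state bits")
        poly = self.kinds == KIND_POLYMORPHIC
        if np.any(pops[poly] < 2):
            raise ValueError("polymorphic cell with fewer than 2 states")
        if np.any(self.masks >= (1 << MAX_STATES)):
            raise ValueError(f"state symbol >= {MAX_STATES} observed")

    # ------------------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return int(self.kinds.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_taxa, self.n_chars)

    def taxon_index(self, label: str) -> int:
        return self.taxa.index(label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.kinds.shape == other.kinds.shape
            and bool(np.array_equal(self.kinds, other.kinds))
            and bool(np.array_equal(self.masks, other.masks))
            and bool(np.array_equal(self.ordered_flags, other.ordered_flags))
        )

    def __repr__(self) -> str:
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_chars} characters>"

    # ------------------------------------------------------------------
    @classmethod
    def from_rows(
        cls,
        taxa: Sequence[str],
        rows: Sequence[str],
        ordered: Iterable[int] | None = None,
        region_labels: Sequence[str] | None = None,
    ) -> "CharacterMatrix":
        """Build a matrix from row strings like ``"01?{01}-2"``.

        ``ordered`` is an iterable of 1-based character indices declared as
        ordered (additive).
        """
        cell_rows = [_tokenize_row(r, taxon=t) for t, r in zip(taxa, rows)]
        lengths = {len(r) for r in cell_rows}
        if len(lengths) > 1:
            raise DimensionError(f"ragged rows: lengths {sorted(lengths)}")
        n_chars = lengths.pop() if lengths else 0
        kinds = np.zeros((len(taxa), n_chars), dtype=np.uint8)
        masks = np.zeros((len(taxa), n_chars), dtype=np.uint8)
        for i, row in enumerate(cell_rows):
            for j, (kind, mask) in enumerate(row):
                kinds[i, j] = kind
                masks[i, j] = mask
        flags = np.zeros(n_chars, dtype=bool)
        if ordered is not None:
            for idx in ordered:
                if not 1 <= idx <= n_chars:
                    raise ValueError(f"ordered index {idx} out of range 1..{n_chars}")
                flags[idx - 1] = True
        return cls(taxa, kinds, masks, flags, region_labels)

    # ------------------------------------------------------------------
    def cell_token(self, i: int, j: int) -> str:
        """The NEXUS token for cell (taxon i, character j), 0-based."""
        kind = self.kinds[i, j]
        if kind == KIND_MISSING:
            return "?"
        if kind == KIND_INAPPLICABLE:
            return "-"
        states = mask_to_states(self.masks[i, j])
        if kind == KIND_STATE:
            return str(states[0])
        return "{" + "".join(str(s) for s in states) + "}"

    def row_string(self, i: int) -> str:
        return "".join(self.cell_token(i, j) for j in range(self.n_chars))

    # ------------------------------------------------------------------
    def state_codes(self, treat_polymorphic_as_missing: bool = True) -> np.ndarray:
        """``(n_taxa, n_chars)`` int8 array of single states, -1 for missing-like."""
        codes = np.full(self.shape, -1, dtype=np.int8)
        single = self.kinds == KIND_STATE
        codes[single] = np.log2(self.masks[single]).astype(np.int8)
        if not treat_polymorphic_as_missing:
            raise NotImplementedError("polymorphic cells are always missing-like here")
        return codes

    def drop_characters(self, indices_1based: Iterable[int]) -> "CharacterMatrix":
        """Return a copy without the given 1-based character columns."""
        drop = set(indices_1based)
        bad = [i for i in drop if not 1 <= i <= self.n_chars]
        if bad:
            raise ValueError(f"character indices out of range: {sorted(bad)}")
        keep = [j for j in range(self.n_chars) if (j + 1) not in drop]
        regions = [self.region_labels[j] for j in keep] if self.region_labels else None
        return CharacterMatrix(
            self.taxa,
            self.kinds[:, keep],
            self.masks[:, keep],
            self.ordered_flags[keep],
            regions,
        )

    def subset_taxa(self, labels: Sequence[str]) -> "CharacterMatrix":
        idx = [self.taxon_index(t) for t in labels]
        return CharacterMatrix(
            [self.taxa[i] for i in idx],
            self.kinds[idx],
            self.masks[idx],
            self.ordered_flags,
            self.region_labels,
        )

    def with_column(self, j_1based: int, kinds_col: np.ndarray, masks_col: np.ndarray) -> "CharacterMatrix":
        """Copy with one character column replaced (used by rescoring scans)."""
        kinds = self.kinds.copy()
        masks = self.masks.copy()
        kinds[:, j_1based - 1] = kinds_col
        masks[:, j_1based - 1] = masks_col
        return CharacterMatrix(self.taxa, kinds, masks, self.ordered_flags, self.region_labels)


def _popcount(a: np.ndarray) -> np.ndarray:
    return np.unpackbits(a[..., None], axis=-1).sum(axis=-1)


def mask_to_states(mask: int) -> list[int]:
    return [s for s in range(MAX_STATES) if mask & (1 << s)]


_TOKEN_RE = re.compile(r"\{[0-9]+\}|\([0-9]+\)|[0-9?\-]")


def _tokenize_row(row: str, taxon: str = "") -> list[tuple[int, int]]:
    cells: list[tuple[int, int]] = []
    pos = 0
    row = row.strip()
    while pos < len(row):
        if row[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(row, pos)
        if not m:
            raise NexusParseError(f"unrecognized token {row[pos]!r} in row for {taxon!r}")
        tok = m.group(0)
        pos = m.end()
        if tok == "?":
            cells.append((KIND_MISSING, 0))
        elif tok == "-":
            cells.append((KIND_INAPPLICABLE, 0))
        elif tok[0] in "{(":
            states = sorted({int(c) for c in tok[1:-1]})
            if any(s >= MAX_STATES for s in states):
                raise ValueError(f"state symbol >= {MAX_STATES} in {tok!r}")
            if len(states) < 2:
                raise NexusParseError(f"polymorphic token {tok!r} with <2 distinct states")
            mask = 0
            for s in states:
                mask |= 1 << s
            cells.append((KIND_POLYMORPHIC, mask))
        else:
            s = int(tok)
            if s >= MAX_STATES:
                raise ValueError(f"state symbol {s} >= {MAX_STATES}")
            cells.append((KIND_STATE, 1 << s))
    return cells


# ----------------------------------------------------------------------
# NEXUS I/O
# ----------------------------------------------------------------------

def read_nexus(
    path: str | Path,
    ordered: Iterable[int] | str | Path | None = None,
    regions: Sequence[tuple[str, int, int]] | None = None,
) -> CharacterMatrix:
    """Read a NEXUS CHARACTERS/DATA block into a :class:`CharacterMatrix`.

    Ordering flags are taken from an ``ASSUMPTIONS`` block ``TYPESET`` line
    (``ord:`` entries) if present, or from ``ordered`` — either an iterable
    of 1-based indices or a path to a plain-text list (one index per line).
    An explicit ``ordered`` argument overrides the file's own typeset.
    """
    import dendropy

    path = Path(path)
    text = path.read_text()
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises schema-specific errors with line info
        raise NexusParseError(f"{path}: {exc}") from exc
    taxa = [t.label for t in dmat.taxon_namespace]
    rows = []
    lengths = set()
    for t in dmat.taxon_namespace:
        seq = dmat[t]
        row: list[tuple[int, int]] = []
        for s in seq:
            row.append(_dendropy_state_cell(s))
        rows.append(row)
        lengths.add(len(row))
    if len(lengths) > 1:
        raise DimensionError(f"{path}: ragged rows, lengths {sorted(lengths)}")
    n_chars = lengths.pop() if lengths else 0
    kinds = np.zeros((len(taxa), n_chars), dtype=np.uint8)
    masks = np.zeros((len(taxa), n_chars), dtype=np.uint8)
    for i, row in enumerate(rows):
        for j, (kind, mask) in enumerate(row):
            kinds[i, j] = kind
            masks[i, j] = mask

    flags = _parse_typeset(text, n_chars)
    if ordered is not None:
        if isinstance(ordered, (str, Path)):
            ordered = read_ordered_list(ordered)
        flags = np.zeros(n_chars, dtype=bool)
        for idx in ordered:
            if not 1 <= idx <= n_chars:
                raise ValueError(f"ordered index {idx} out of range 1..{n_chars}")
            flags[idx - 1] = True

    labels = None
    if regions is not None:
        labels = region_labels_from_ranges(n_chars, regions)
    elif n_chars == 457:
        labels = region_labels_from_ranges(n_chars)
    return CharacterMatrix(taxa, kinds, masks, flags, labels)


def _dendropy_state_cell(s) -> tuple[int, int]:
    """Map a dendropy StateIdentity to a (kind, mask) cell."""
    # denomination: 0 = fundamental, 1 = polymorphic, 2 = ambiguous
    symbol = s.symbol
    if symbol == "?":
        return (KIND_MISSING, 0)
    if symbol == "-":
        return (KIND_INAPPLICABLE, 0)
    members = s.member_states or []
    if len(members) > 1 or symbol is None:
        states = sorted(int(m.symbol) for m in members if m.symbol not in ("?", "-"))
        mask = 0
        for st in states:
            if st >= MAX_STATES:
                raise ValueError(f"state symbol {st} >= {MAX_STATES}")
            mask |= 1 << st
        if len(states) >= MAX_STATES:  # '?' expanded to everything
            return (KIND_MISSING, 0)
        return (KIND_POLYMORPHIC, mask)
    st = int(symbol)
    if st >= MAX_STATES:
        raise ValueError(f"state symbol {st} >= {MAX_STATES}")
    return (KIND_STATE, 1 << st)


_TYPESET_RE = re.compile(r"typeset[^;]*;", re.IGNORECASE | re.DOTALL)
_ORD_RE = re.compile(r"\bord\s*:\s*([0-9\s,\-]+)", re.IGNORECASE)


def _parse_typeset(text: str, n_chars: int) -> np.ndarray:
    flags = np.zeros(n_chars, dtype=bool)
    m = _TYPESET_RE.search(text)
    if not m:
        return flags
    om = _ORD_RE.search(m.group(0))
    if not om:
        return flags
    for part in re.split(r"[\s,]+", om.group(1).strip()):
        if not part:
            continue
        if "-" in part:
            lo, hi = part.split("-")
            for idx in range(int(lo), int(hi) + 1):
                flags[idx - 1] = True
        else:
            flags[int(part) - 1] = True
    return flags


def _quote_label(label: str) -> str:
    # underscores are quoted too: a bare underscore reads back as a space
    if re.fullmatch(r"[A-Za-z0-9.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_nexus(m: CharacterMatrix, path: str | Path) -> None:
    """Write a CHARACTERS-block NEXUS file with an ASSUMPTIONS typeset
    recording ordered characters."""
    path = Path(path)
    width = max(len(_quote_label(t)) for t in m.taxa) + 2
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_chars};",
        '  FORMAT DATATYPE=STANDARD SYMBOLS="012345" MISSING=? GAP=-;',
        "  MATRIX",
    ]
    for i, t in enumerate(m.taxa):
        lines.append(f"    {_quote_label(t):<{width}}{m.row_string(i)}")
    lines += ["  ;", "END;", ""]
    ordered = [str(j + 1) for j in range(m.n_chars) if m.ordered_flags[j]]
    if ordered:
        unordered = [str(j + 1) for j in range(m.n_chars) if not m.ordered_flags[j]]
        lines += [
            "BEGIN ASSUMPTIONS;",
            f"  TYPESET * default = ord: {' '.join(ordered)}, unord: {' '.join(unordered)};",
            "END;",
            "",
        ]
    path.write_text("\n".join(lines))


def read_ordered_list(path: str | Path) -> list[int]:
    """Plain-text ordered-character list: one 1-based index per line."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(int(line))
    return out


# ----------------------------------------------------------------------
# Character profiles
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CharacterProfile:
    """Summary of one character column (1-based ``index``).

    Polymorphic cells are treated as missing for state observation, so
    ``observed_states`` collects single-state cells only.  A character is
    parsimony-informative iff at least two states are each observed in at
    least two taxa; autapomorphic means variable but not informative.
    """

    index: int
    observed_states: frozenset[int]
    n_observed_states: int
    is_constant: bool
    is_autapomorphic: bool
    is_parsimony_informative: bool
    effective_ordered: bool


def profile_characters(m: CharacterMatrix) -> list[CharacterProfile]:
    codes = m.state_codes()
    profiles = []
    for j in range(m.n_chars):
        col = codes[:, j]
        col = col[col >= 0]
        states, counts = np.unique(col, return_counts=True)
        n_states = len(states)
        informative = int(np.sum(counts >= 2)) >= 2
        constant = n_states <= 1
        profiles.append(
            CharacterProfile(
                index=j + 1,
                observed_states=frozenset(int(s) for s in states),
                n_observed_states=n_states,
                is_constant=constant,
                is_autapomorphic=(not constant) and (not informative),
                is_parsimony_informative=informative,
                effective_ordered=bool(m.ordered_flags[j]) and n_states >= 3,
            )
        )
    return profiles


# ----------------------------------------------------------------------
# Matrix comparison
# ----------------------------------------------------------------------

@dataclass
class MatrixDiff:
    """Cell-level differences between two matrices over their shared taxa.

    Missing-vs-inapplicable never counts as a difference.  Two counts are
    kept: ``n_diff_strict`` treats polymorphic cells as distinct scorings,
    ``n_diff_poly_as_missing`` equates them with missing data.
    """

    n_overlap_cells: int
    n_diff_strict: int
    n_diff_poly_as_missing: int
    unchanged_taxa: list[str]
    unchanged_characters: list[int]
    shared_taxa: list[str] = field(default_factory=list)
    polymorphic_as_missing: bool = False

    @property
    def n_diff(self) -> int:
        return self.n_diff_poly_as_missing if self.polymorphic_as_missing else self.n_diff_strict

    @property
    def fraction_diff(self) -> float:
        return self.n_diff / self.n_overlap_cells if self.n_overlap_cells else 0.0


def _comparable(kinds: np.ndarray, masks: np.ndarray, poly_as_missing: bool):
    """Canonical per-cell comparison keys: -1 for any missing-like cell,
    otherwise the state-set bitmask (optionally demoting polymorphisms)."""
    key = masks.astype(np.int16)
    missing_like = (kinds == KIND_MISSING) | (kinds == KIND_INAPPLICABLE)
    if poly_as_missing:
        missing_like |= kinds == KIND_POLYMORPHIC
    key[missing_like] = -1
    return key


def compare_matrices(
    a: CharacterMatrix, b: CharacterMatrix, polymorphic_as_missing: bool = False
) -> MatrixDiff:
    """Count differing cells between two matrices over their shared taxa.

    Requires at least one shared taxon label and an equal character count.
    """
    if a.n_chars != b.n_chars:
        raise DimensionError(f"character counts differ: {a.n_chars} vs {b.n_chars}")
    shared = [t for t in a.taxa if t in set(b.taxa)]
    if not shared:
        raise ValueError("matrices share no taxon labels")
    ia = [a.taxon_index(t) for t in shared]
    ib = [b.taxon_index(t) for t in shared]
    diffs = {}
    for flag in (False, True):
        ka = _comparable(a.kinds[ia], a.masks[ia], flag)
        kb = _comparable(b.kinds[ib], b.masks[ib], flag)
        diffs[flag] = ka != kb
    selected = diffs[polymorphic_as_missing]
    unchanged_taxa = [t for t, row in zip(shared, selected) if not row.any()]
    unchanged_chars = [j + 1 for j in range(a.n_chars) if not selected[:, j].any()]
    return MatrixDiff(
        n_overlap_cells=len(shared) * a.n_chars,
        n_diff_strict=int(diffs[False].sum()),
        n_diff_poly_as_missing=int(diffs[True].sum()),
        unchanged_taxa=unchanged_taxa,
        unchanged_characters=unchanged_chars,
        shared_taxa=shared,
        polymorphic_as_missing=polymorphic_as_missing,
    )


def write_diff_tsv(a: CharacterMatrix, b: CharacterMatrix, path: str | Path,
                   polymorphic_as_missing: bool = False) -> None:
    """Cell-level diff report: taxon, character, state_a, state_b."""
    shared = [t for t in a.taxa if t in set(b.taxa)]
    ia = [a.taxon_index(t) for t in shared]
    ib = [b.taxon_index(t) for t in shared]
    ka = _comparable(a.kinds[ia], a.masks[ia], polymorphic_as_missing)
    kb = _comparable(b.kinds[ib], b.masks[ib], polymorphic_as_missing)
    lines = ["taxon\tcharacter\tstate_a\tstate_b"]
    for r, t in enumerate(shared):
        for j in np.nonzero(ka[r] != kb[r])[0]:
            lines.append(
                f"{t}\t{j + 1}\t{a.cell_token(ia[r], j)}\t{b.cell_token(ib[r], j)}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Partition scheme
# ----------------------------------------------------------------------

@dataclass
class PartitionScheme:
    """Characters grouped by (effective_ordered, n_observed_states).

    Constant characters are excluded.  Declared-ordered characters with only
    two observed states are demoted to the unordered binary group, because a
    two-state stepwise model is identical to the unordered two-state model.
    All indices are 1-based.
    """

    groups: dict[tuple[bool, int], list[int]]
    excluded_constant: list[int]

    @property
    def keys(self) -> list[tuple[bool, int]]:
        return sorted(self.groups, key=lambda kv: (kv[0], kv[1]))

    @property
    def n_partitions(self) -> int:
        return len(self.groups)

    def partition_of(self) -> dict[int, tuple[bool, int]]:
        """1-based character index -> group key."""
        out: dict[int, tuple[bool, int]] = {}
        for key, chars in self.groups.items():
            for c in chars:
                out[c] = key
        return out

    def included_characters(self) -> list[int]:
        out: list[int] = []
        for key in self.keys:
            out.extend(self.groups[key])
        return sorted(out)


def build_partitions(
    m: CharacterMatrix, profiles: Sequence[CharacterProfile] | None = None
) -> PartitionScheme:
    if profiles is None:
        profiles = profile_characters(m)
    groups: dict[tuple[bool, int], list[int]] = {}
    excluded = []
    for p in profiles:
        if p.is_constant:
            excluded.append(p.index)
            continue
        key = (p.effective_ordered, p.n_observed_states)
        groups.setdefault(key, []).append(p.index)
    return PartitionScheme(groups=groups, excluded_constant=excluded)
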