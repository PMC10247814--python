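import pytest
from hypothesis import given, settings, strategies as st

from morphoconflict.matrix_io import (
    CharacterMatrix,
    DimensionError,
    NexusParseError,
    build_partitions,
    compare_matrices,
    profile_characters,
    read_nexus,
    read_ordered_list,
    write_nexus,
)


def test_parse_cell_kinds(toy_matrix):
    m = toy_matrix
    assert m.shape == (5, 6)
    assert m.cell_token(0, 3) == "{01}"
    assert m.cell_token(1, 2) == "-"
    assert m.cell_token(3, 1) == "?"
    assert m.cell_token(0, 0) == "0"
    assert m.ordered_flags.tolist() == [False, False, False, False, True, False]


def test_two_taxon_toy_parse():
    m = CharacterMatrix.from_rows(["tA", "tB"], ["01?", "0{01}-"])
    kinds = m.kinds
    assert (kinds == 3).sum() == 1  # one polymorphic cell
    assert (kinds == 1).sum() + (kinds == 2).sum() == 2  # two non-state cells


def test_ragged_rows_rejected():
    with pytest.raises(DimensionError):
        CharacterMatrix.from_rows(["A", "B"], ["010", "01"])


def test_bad_symbol_rejected():
    with pytest.raises(ValueError):
        CharacterMatrix.from_rows(["A", "B"], ["07", "00"])
    with pytest.raises(NexusParseError):
        CharacterMatrix.from_rows(["A", "B"], ["0x", "00"])


def test_nexus_round_trip(tmp_path, toy_matrix):
    path = tmp_path / "toy.nex"
    write_nexus(toy_matrix, path)
    again = read_nexus(path)
    assert again == toy_matrix
    # second round trip is the identity on the file's content too
    path2 = tmp_path / "toy2.nex"
    write_nexus(again, path2)
    assert path.read_text() == path2.read_text()


def test_nexus_quoted_labels_round_trip(tmp_path):
    m = CharacterMatrix.from_rows(
        ["Euparkeria capensis", "tax_B", "C"], ["012", "0?2", "11-"]
    )
    path = tmp_path / "q.nex"
    write_nexus(m, path)
    assert read_nexus(path).taxa == m.taxa


def test_malformed_nexus_parse_error(tmp_path):
    path = tmp_path / "bad.nex"
    path.write_text("#NEXUS\nBEGIN DATA;\n DIMENSIONS banana;\nEND;\n")
    with pytest.raises(NexusParseError):
        read_nexus(path)


def test_ordered_list_side_channel(tmp_path, toy_matrix):
    path = tmp_path / "m.nex"
    write_nexus(toy_matrix, path)
    ord_path = tmp_path / "ord.txt"
    ord_path.write_text("1\n5\n")
    assert read_ordered_list(ord_path) == [1, 5]
    m = read_nexus(path, ordered=ord_path)
    assert m.ordered_flags.tolist() == [True, False, False, False, True, False]


# ----------------------------------------------------------------------
# Profiles
# ----------------------------------------------------------------------

def test_constant_column_profile():
    m = CharacterMatrix.from_rows(["A", "B", "C", "D"], ["0", "0", "?", "-"])
    p = profile_characters(m)[0]
    assert p.is_constant
    assert not p.is_parsimony_informative
    assert not p.is_autapomorphic


def test_informative_vs_autapomorphic(toy_matrix):
    profs = profile_characters(toy_matrix)
    # char 1: states (0,0,1,0,1) -> both states twice -> informative
    assert profs[0].is_parsimony_informative
    # char 4 (index 3): polymorphic cell ignored -> states 1,1,2,0 ->
    # only state 1 seen twice -> variable but not informative
    assert profs[3].is_autapomorphic and not profs[3].is_parsimony_informative
    assert profs[3].observed_states == {0, 1, 2}


def test_effective_ordered_requires_three_states(toy_matrix):
    profs = profile_characters(toy_matrix)
    assert profs[4].effective_ordered  # declared ordered, 3 states
    m2 = CharacterMatrix.from_rows(["A", "B", "C"], ["0", "1", "0"], ordered=[1])
    assert not profile_characters(m2)[0].effective_ordered


# ----------------------------------------------------------------------
# Comparison
# ----------------------------------------------------------------------

def test_compare_identity(toy_matrix):
    d = compare_matrices(toy_matrix, toy_matrix)
    assert d.n_diff == 0
    assert d.unchanged_taxa == toy_matrix.taxa
    assert d.unchanged_characters == list(range(1, toy_matrix.n_chars + 1))


def test_compare_missing_vs_inapplicable_never_counts():
    a = CharacterMatrix.from_rows(["A", "B"], ["?-", "01"])
    b = CharacterMatrix.from_rows(["A", "B"], ["-?", "01"])
    assert compare_matrices(a, b).n_diff == 0


def test_compare_polymorphic_conventions():
    a = CharacterMatrix.from_rows(["A", "B"], ["{01}1", "00"])
    b = CharacterMatrix.from_rows(["A", "B"], ["?1", "0{12}"])
    strict = compare_matrices(a, b, polymorphic_as_missing=False)
    lenient = compare_matrices(a, b, polymorphic_as_missing=True)
    # strict: {01} vs ? differs, 0 vs {12} differs
    assert strict.n_diff == 2
    # lenient: {01} vs ? becomes missing vs missing, but 0 vs {12} is still
    # an observed state against missing data
    assert lenient.n_diff == 1
    assert lenient.n_diff_poly_as_missing <= strict.n_diff_strict


def test_compare_requires_shared_taxa():
    a = CharacterMatrix.from_rows(["A"], ["01"])
    b = CharacterMatrix.from_rows(["B"], ["01"])
    with pytest.raises(ValueError):
        compare_matrices(a, b)


@st.composite
def matrix_pair(draw):
    n_taxa = draw(st.integers(3, 6))
    n_chars = draw(st.integers(2, 8))
    alphabet = "012?-" + "{01}"
    cells = st.sampled_from(["0", "1", "2", "?", "-", "{01}", "{12}"])
    rows_a = [
        "".join(draw(st.lists(cells, min_size=n_chars, max_size=n_chars)))
        for _ in range(n_taxa)
    ]
    rows_b = [
        "".join(draw(st.lists(cells, min_size=n_chars, max_size=n_chars)))
        for _ in range(n_taxa)
    ]
    taxa = [f"t{i}" for i in range(n_taxa)]
    return (
        CharacterMatrix.from_rows(taxa, rows_a),
        CharacterMatrix.from_rows(taxa, rows_b),
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(matrix_pair())
def test_compare_symmetry_and_poly_ordering(pair):
    a, b = pair
    for flag in (False, True):
        d_ab = compare_matrices(a, b, flag)
        d_ba = compare_matrices(b, a, flag)
        assert d_ab.n_diff_strict == d_ba.n_diff_strict
        assert d_ab.n_diff_poly_as_missing == d_ba.n_diff_poly_as_missing
        assert d_ab.n_overlap_cells == d_ba.n_overlap_cells
    assert d_ab.n_diff_poly_as_missing <= d_ab.n_diff_strict <= d_ab.n_overlap_cells


# ----------------------------------------------------------------------
# Partitions
# ----------------------------------------------------------------------

def test_partitions_exact_cover(toy_matrix):
    scheme = build_partitions(toy_matrix)
    covered = sorted(
        [c for chars in scheme.groups.values() for c in chars]
        + scheme.excluded_constant
    )
    assert covered == list(range(1, toy_matrix.n_chars + 1))
    for key, chars in scheme.groups.items():
        assert len(chars) == len(set(chars))


def test_single_binary_group():
    m = CharacterMatrix.from_rows(["A", "B", "C", "D"], ["01", "10", "01", "11"])
    scheme = build_partitions(m)
    assert list(scheme.groups) == [(False, 2)]
    assert scheme.excluded_constant == []


def test_declared_ordered_binary_demoted():
    m = CharacterMatrix.from_rows(
        ["A", "B", "C", "D"], ["00", "01", "11", "10"], ordered=[1, 2]
    )
    scheme = build_partitions(m)
    assert (False, 2) in scheme.groups and (True, 2) not in scheme.groups
    assert sorted(scheme.groups[(False, 2)]) == [1, 2]


@settings(max_examples=40, deadline=None, derandomize=True)
@given(matrix_pair())
def test_partitions_cover_random_matrices(pair):
    m, _ = pair
    scheme = build_partitions(m)
    covered = sorted(
        [c for chars in scheme.groups.values() for c in chars]
        + scheme.excluded_constant
    )
    assert covered == list(range(1, m.n_chars + 1))
    profs = {p.index: p for p in profile_characters(m)}
    for (ordered, k), chars in scheme.groups.items():
        for c in chars:
            assert not profs[c].is_constant
            assert profs[c].n_observed_states == k
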