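import numpy as np
import pytest
from scipy.stats import chisquare

from oracles import enumeration_pattern_probs

from morphoconflict.matrix_io import profile_characters
from morphoconflict.mk_engine import MatrixData, MkEngine
from morphoconflict.synthetic_data import (
    SimulationConfig,
    make_hypothesis_trees,
    random_base_tree,
    simulate_matrix,
    _compile_for_sim,
    _simulate_group,
)
from morphoconflict.trees import (
    detect_hypothesis,
    rf_distance,
    tree_from_newick,
)


def test_hypothesis_trees_detect_as_constructed():
    base = random_base_tree(20, seed=3)
    trees = make_hypothesis_trees(base)
    for label, t in trees.items():
        assert detect_hypothesis(t).label == label
    # the three trees differ pairwise by exactly one split
    for a in trees.values():
        for b in trees.values():
            expected = 0 if a is b else 2
            assert rf_distance(a, b) == expected


def test_focal_length_zero_trees_equal_likelihood():
    cfg = SimulationConfig(
        n_taxa=10, n_chars=40, focal_branch_length=0.0, missing_fraction=0.0,
        polymorphic_fraction=0.0, state_count_weights=(1, 0, 0, 0), alpha=None,
        seed=5,
    )
    matrix, truth = simulate_matrix(cfg)
    data = MatrixData(matrix, n_gamma_categories=1)
    lnls = [
        MkEngine(data.copy(), tree_from_newick(truth.hypothesis_trees[h])).total_lnL()
        for h in ("S", "Of", "Os")
    ]
    assert max(lnls) - min(lnls) < 1e-9


def test_variable_conditioning_leaves_no_constant_characters():
    cfg = SimulationConfig(
        n_taxa=15, n_chars=200, missing_fraction=0.0, polymorphic_fraction=0.0,
        seed=2,
    )
    matrix, _ = simulate_matrix(cfg)
    assert all(not p.is_constant for p in profile_characters(matrix))


def test_missing_fraction_realized():
    # at low taxon-completeness spread the realized fraction concentrates
    # on the target; the spread parameter then widens per-taxon variation
    cfg = SimulationConfig(
        n_taxa=100, n_chars=150, missing_fraction=0.58,
        taxon_completeness_spread=0.1, seed=4,
    )
    matrix, _ = simulate_matrix(cfg)
    missing = (matrix.kinds == 1) | (matrix.kinds == 2)
    assert abs(missing.mean() - 0.58) < 0.02

    wide = SimulationConfig(
        n_taxa=100, n_chars=150, missing_fraction=0.58,
        taxon_completeness_spread=0.9, seed=4,
    )
    matrix_w, _ = simulate_matrix(wide)
    missing_w = (matrix_w.kinds == 1) | (matrix_w.kinds == 2)
    assert missing_w.mean(axis=1).std() > 2 * missing.mean(axis=1).std()


def test_polymorphic_cells_written():
    cfg = SimulationConfig(
        n_taxa=30, n_chars=200, missing_fraction=0.3, polymorphic_fraction=0.01,
        seed=6,
    )
    matrix, _ = simulate_matrix(cfg)
    n_poly = int((matrix.kinds == 3).sum())
    n_obs = int((matrix.kinds == 0).sum()) + n_poly
    assert n_poly > 0
    assert abs(n_poly / n_obs - 0.01) < 0.005


def test_simulation_reproducible_and_manifest_consistent():
    cfg = SimulationConfig(n_taxa=12, n_chars=80, seed=9)
    m1, t1 = simulate_matrix(cfg)
    m2, t2 = simulate_matrix(SimulationConfig(n_taxa=12, n_chars=80, seed=9))
    assert m1 == m2
    assert t1.tree_labels == t2.tree_labels and t1.rate == t2.rate
    assert len(t1.tree_labels) == 80
    assert sum(t1.counts_per_label().values()) == 80


def test_manifest_round_trip(tmp_path):
    cfg = SimulationConfig(n_taxa=10, n_chars=30, seed=1)
    _, manifest = simulate_matrix(cfg)
    p = tmp_path / "truth.json"
    manifest.to_json(p)
    from morphoconflict.synthetic_data import TruthManifest

    again = TruthManifest.from_json(p)
    assert again.tree_labels == manifest.tree_labels
    assert again.hypothesis_trees == manifest.hypothesis_trees


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(missing_fraction=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(conflict_weights=(0.5, 0.5, 0.5))


def test_pattern_frequencies_match_mk_distribution():
    """Simulated tip patterns on a fixed 4-taxon tree follow the
    variable-conditioned Mk pattern distribution (chi-square, alpha=0.01)."""
    newick = "((A:0.3,B:0.2):0.1,(C:0.15,D:0.4):0.2);"
    taxa = ["A", "B", "C", "D"]
    tree = tree_from_newick(newick)
    edges, n_slots = _compile_for_sim(tree, taxa)
    rng = np.random.default_rng(123)
    n = 100_000
    out = _simulate_group(edges, n_slots, 4, 2, False, np.ones(n), rng)
    keep = ~(out == out[:, :1]).all(axis=1)
    out = out[keep]
    probs = enumeration_pattern_probs(newick, taxa, k=2)
    patterns = list(probs)
    idx = {p: i for i, p in enumerate(patterns)}
    counts = np.zeros(len(patterns))
    for row in out:
        counts[idx[tuple(row)]] += 1
    expected = np.array([probs[p] for p in patterns]) * len(out)
    stat, p_value = chisquare(counts, expected)
    assert p_value > 0.01


def test_generating_tree_receives_higher_mean_support():
    """Characters simulated on one resolution support it on average: the
    mean dCLS toward the generating tree is positive."""
    from morphoconflict.mk_engine import MkModel, column_loglike

    cfg = SimulationConfig(
        n_taxa=10, n_chars=120, conflict_weights=(1.0, 0.0, 0.0),
        state_count_weights=(1, 0, 0, 0), alpha=None, missing_fraction=0.0,
        polymorphic_fraction=0.0, focal_branch_length=0.15, seed=21,
    )
    matrix, truth = simulate_matrix(cfg)
    codes = matrix.state_codes()
    trees = {h: tree_from_newick(nwk) for h, nwk in truth.hypothesis_trees.items()}
    model = MkModel(2)
    sums = {h: 0.0 for h in trees}
    for j in range(matrix.n_chars):
        for h, t in trees.items():
            sums[h] += column_loglike(t, matrix.taxa, codes[:, j], model)
    assert sums["S"] > sums["Of"]
    assert sums["S"] > sums["Os"]
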