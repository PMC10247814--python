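import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from oracles import enumeration_column_likelihood

from morphoconflict.matrix_io import CharacterMatrix
from morphoconflict.mk_engine import (
    MatrixData,
    MkEngine,
    MkModel,
    column_loglike,
    discrete_gamma_rates,
    transition_matrix,
)
from morphoconflict.trees import tree_from_newick

NEWICK5 = "((A:0.2,B:0.35):0.15,(C:0.4,D:0.1):0.05,E:0.3);"
TAXA5 = ["A", "B", "C", "D", "E"]


# ----------------------------------------------------------------------
# Transition matrices
# ----------------------------------------------------------------------

@pytest.mark.parametrize("k", [2, 3, 4, 5])
@pytest.mark.parametrize("ordered", [False, True])
def test_transition_matrix_is_stochastic(k, ordered):
    m = MkModel(k, ordered=ordered)
    for t in (0.0, 0.01, 0.5, 3.0):
        P = transition_matrix(m, t)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()
    assert np.allclose(transition_matrix(m, 0.0), np.eye(k), atol=1e-12)


def test_transition_matrix_limits_and_closed_form():
    m = MkModel(2)
    assert transition_matrix(m, 0.5)[0, 0] == pytest.approx(
        (1 + np.exp(-1.0)) / 2, abs=1e-12
    )
    for k in (2, 3, 5):
        P = transition_matrix(MkModel(k), 200.0)
        assert np.allclose(P, 1.0 / k, atol=1e-9)
    with pytest.raises(ValueError):
        transition_matrix(m, -0.1)


def test_chapman_kolmogorov():
    rng = np.random.default_rng(3)
    for k, ordered in [(2, False), (4, False), (4, True), (5, True)]:
        m = MkModel(k, ordered=ordered)
        for _ in range(5):
            t1, t2 = rng.uniform(0.01, 1.5, size=2)
            P12 = transition_matrix(m, t1) @ transition_matrix(m, t2)
            assert np.allclose(P12, transition_matrix(m, t1 + t2), atol=1e-10)


def test_ordered_model_steps_through_neighbors():
    # at short times, a 2-step change is O(t^2) while a 1-step is O(t)
    m = MkModel(4, ordered=True)
    P = transition_matrix(m, 0.01)
    assert P[0, 1] > 50 * P[0, 2] > 0


def test_gamma_discretization_against_integral():
    for alpha in (0.3, 0.5, 1.0, 2.5):
        rates = discrete_gamma_rates(alpha, 4)
        assert rates.mean() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(rates) > 0).all()
        # independent check: mean of the distribution within each quantile bin
        bounds = np.concatenate(
            [[0], gamma_dist.ppf([0.25, 0.5, 0.75], a=alpha, scale=1 / alpha), [np.inf]]
        )
        for i in range(4):
            num, _ = quad(
                lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1 / alpha),
                bounds[i], bounds[i + 1],
            )
            assert rates[i] == pytest.approx(4 * num, rel=1e-6)
    assert discrete_gamma_rates(0.5, 1).tolist() == [1.0]


# ----------------------------------------------------------------------
# Likelihood engine vs. enumeration
# ----------------------------------------------------------------------

def test_column_loglike_spot_checks_against_enumeration():
    col = [0, 1, 1, None, 0]
    for k, ordered, ncat, asc in [(2, False, 1, True), (3, True, 4, False)]:
        column = [c if c is None else min(c, k - 1) for c in col]
        model = MkModel(k, ordered=ordered, n_gamma_categories=ncat, alpha=0.7)
        mine = column_loglike(
            tree_from_newick(NEWICK5), TAXA5,
            [-1 if c is None else c for c in column], model, ascertainment=asc,
        )
        oracle = enumeration_column_likelihood(
            NEWICK5, TAXA5, column, k, ordered,
            rates=model.gamma_rates(), ascertainment=asc,
        )
        assert mine == pytest.approx(oracle, abs=1e-10)


def test_state_exceeding_k_rejected():
    with pytest.raises(ValueError):
        column_loglike(tree_from_newick(NEWICK5), TAXA5, [0, 1, 2, 0, 1], MkModel(2))


def test_all_missing_column_has_probability_one():
    lnl = column_loglike(
        tree_from_newick(NEWICK5), TAXA5, [-1] * 5, MkModel(2), ascertainment=False
    )
    assert lnl == pytest.approx(0.0, abs=1e-12)


def test_zero_branch_lengths_constant_column_is_one_over_k():
    newick = "((A:0,B:0):0,(C:0,D:0):0);"
    for k in (2, 4):
        lnl = column_loglike(
            tree_from_newick(newick), ["A", "B", "C", "D"], [0, 0, 0, 0],
            MkModel(k), ascertainment=False,
        )
        assert lnl == pytest.approx(np.log(1.0 / k), abs=1e-12)


def test_ascertainment_corrected_variable_patterns_sum_to_one():
    """On a small tree, corrected probabilities of all variable patterns
    must form a distribution."""
    newick = "((A:0.3,B:0.2):0.1,(C:0.15,D:0.4):0.2);"
    taxa = ["A", "B", "C", "D"]
    for k in (2, 3):
        total = 0.0
        for pattern in itertools.product(range(k), repeat=4):
            if len(set(pattern)) == 1:
                continue
            total += np.exp(
                column_loglike(tree_from_newick(newick), taxa, list(pattern),
                               MkModel(k), ascertainment=True)
            )
        assert total == pytest.approx(1.0, abs=1e-10)


def test_gamma_single_category_equals_plain():
    col = [0, 1, 0, 1, -1]
    t = tree_from_newick(NEWICK5)
    plain = column_loglike(t, TAXA5, col, MkModel(2))
    one_cat = column_loglike(t, TAXA5, col, MkModel(2, n_gamma_categories=1, alpha=0.5))
    assert plain == pytest.approx(one_cat, abs=1e-14)


def test_total_lnl_invariant_to_row_and_column_order():
    rows = ["01011", "11010", "00110", "10011"]
    taxa = ["A", "B", "C", "D"]
    tree = tree_from_newick("((A:0.2,B:0.35):0.15,(C:0.4,D:0.1):0.05);")
    base = MkEngine(
        MatrixData(CharacterMatrix.from_rows(taxa, rows)), tree.clone(depth=1)
    ).total_lnL()
    # permute taxa rows
    perm = [2, 0, 3, 1]
    m2 = CharacterMatrix.from_rows([taxa[i] for i in perm], [rows[i] for i in perm])
    assert MkEngine(MatrixData(m2), tree.clone(depth=1)).total_lnL() == pytest.approx(
        base, abs=1e-10
    )
    # permute character columns
    cols = [3, 1, 4, 0, 2]
    rows3 = ["".join(r[c] for c in cols) for r in rows]
    m3 = CharacterMatrix.from_rows(taxa, rows3)
    assert MkEngine(MatrixData(m3), tree.clone(depth=1)).total_lnL() == pytest.approx(
        base, abs=1e-10
    )


def test_empty_matrix_total_is_zero():
    m = CharacterMatrix.from_rows(["A", "B", "C", "D"], [""] * 4)
    tree = tree_from_newick("((A:0.2,B:0.35):0.15,(C:0.4,D:0.1):0.05);")
    assert MkEngine(MatrixData(m), tree).total_lnL() == 0.0


# ----------------------------------------------------------------------
# Optimizer
# ----------------------------------------------------------------------

def test_optimizer_monotone_from_truth(pure_signal_sim):
    matrix, truth, scheme = pure_signal_sim
    data = MatrixData(matrix, scheme, n_gamma_categories=1)
    tree = tree_from_newick(truth.hypothesis_trees["S"])
    eng = MkEngine(data, tree)
    before = eng.total_lnL()
    after, converged, _ = eng.optimize(tol=1e-6, max_sweeps=30, warn=False)
    assert after >= before - 1e-9
    assert converged


def test_optimizer_matches_analytic_pairwise_mle():
    """For a two-taxon comparison the ML path length has a closed form from
    the mismatch proportion: t = -ln(1 - 2p) / 2 for the binary model."""
    n, mismatches = 50, 10
    p = mismatches / n
    rows_a = "0" * n
    rows_b = "1" * mismatches + "0" * (n - mismatches)
    m = CharacterMatrix.from_rows(
        ["A", "B", "C", "D"],
        [rows_a, rows_b, "?" * n, "?" * n],
    )
    # keep the constant (matching) columns: no variable-only conditioning here
    from morphoconflict.matrix_io import PartitionScheme

    scheme = PartitionScheme(
        groups={(False, 2): list(range(1, n + 1))}, excluded_constant=[]
    )
    data = MatrixData(m, scheme, n_gamma_categories=1)
    tree = tree_from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
    eng = MkEngine(data, tree, ascertainment=False)
    eng.optimize(tol=1e-9, max_sweeps=100, xatol=1e-7, warn=False)
    # all likelihood flows through the A-B path (C, D are unscored)
    by_label = {
        leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
    }
    path = by_label["A"] + by_label["B"]
    expected = -np.log(1 - 2 * p) / 2
    assert path == pytest.approx(expected, abs=1e-4)
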