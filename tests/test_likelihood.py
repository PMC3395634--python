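import numpy as np
import pytest

from memesel.likelihood import (
    CategoryMixture,
    SitePruner,
    branch_mixture_matrix,
    brute_force_mixture_likelihood,
    site_log_likelihood,
)
from memesel.phylo import parse_newick

TREE4 = "((A:0.2,B:0.3):0.15,(C:0.25,D:0.1):0.2);"


def _single_state_col(code, mapping):
    idx = code.codon_index
    return {name: frozenset([idx[codon]]) for name, codon in mapping.items()}


def test_two_leaf_closed_form(code, kernel):
    tree = parse_newick("(A:0.4,B:0.9);")
    col = _single_state_col(code, {"A": "AAA", "B": "AAG"})
    mats = {b.name: kernel.transition_matrix(1.0, 0.5, b.length)
            for b in tree.branches}
    stack = [mats[b.name] for b in tree.branches]
    lnl = site_log_likelihood(col, tree, stack, kernel.pi)
    i, j = code.codon_index["AAA"], code.codon_index["AAG"]
    direct = np.log(np.sum(kernel.pi * mats["A"][:, i] * mats["B"][:, j]))
    assert lnl == pytest.approx(direct, abs=1e-12)


def test_fully_ambiguous_column_has_probability_one(code, kernel):
    tree = parse_newick(TREE4)
    col = {n: frozenset(range(61)) for n in "ABCD"}
    stack = [kernel.transition_matrix(1.0, 1.0, b.length) for b in tree.branches]
    assert site_log_likelihood(col, tree, stack, kernel.pi) == pytest.approx(0.0)


def test_zero_branch_lengths_give_log_pi(code, kernel):
    tree = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
    col = _single_state_col(code, dict.fromkeys("ABCD", "ACG"))
    stack = [np.eye(61) for _ in tree.branches]
    lnl = site_log_likelihood(col, tree, stack, kernel.pi)
    assert lnl == pytest.approx(np.log(kernel.pi[code.codon_index["ACG"]]))


def test_impossible_column_returns_neg_inf(code, kernel):
    tree = parse_newick("(A:0,B:0);")
    col = _single_state_col(code, {"A": "AAA", "B": "TTT"})
    stack = [np.eye(61), np.eye(61)]
    assert site_log_likelihood(col, tree, stack, kernel.pi) == -np.inf


def test_mixture_matrix_edge_cases(kernel):
    t = 0.3
    pure = kernel.transition_matrix(1.0, 0.4, t)
    one_cat = branch_mixture_matrix(
        CategoryMixture([(1.0, 0.4)], [1.0]), kernel, t
    )
    assert np.allclose(one_cat, pure, atol=1e-14)
    zero_weight = branch_mixture_matrix(
        CategoryMixture([(1.0, 0.4), (1.0, 7.0)], [1.0, 0.0]), kernel, t
    )
    assert np.allclose(zero_weight, pure, atol=1e-14)


def test_mixture_matrix_is_convex_combination(kernel):
    t = 0.3
    p_lo = kernel.transition_matrix(1.0, 0.4, t)
    p_hi = kernel.transition_matrix(1.0, 7.0, t)
    mix = branch_mixture_matrix(
        CategoryMixture([(1.0, 0.4), (1.0, 7.0)], [0.65, 0.35]), kernel, t
    )
    lo = np.minimum(p_lo, p_hi)
    hi = np.maximum(p_lo, p_hi)
    assert np.all(mix >= lo - 1e-12)
    assert np.all(mix <= hi + 1e-12)


def test_mixture_weight_validation():
    with pytest.raises(ValueError):
        CategoryMixture([(1.0, 1.0)], [0.9])
    with pytest.raises(ValueError):
        CategoryMixture([(1.0, 1.0), (1.0, 2.0)], [0.7, -0.3])


def test_pruner_boundary_weights_equal_pure_likelihoods(code, kernel):
    tree = parse_newick(TREE4)
    col = _single_state_col(code, {"A": "AAA", "B": "AAG", "C": "ACA", "D": "AAA"})
    pr = SitePruner(col, tree, kernel)
    assert pr.loglike_mixture(1.0, 0.2, 5.0, 0.0) == pytest.approx(
        pr.loglike_single(1.0, 0.2), abs=1e-12
    )
    assert pr.loglike_mixture(1.0, 0.2, 5.0, 1.0) == pytest.approx(
        pr.loglike_single(1.0, 5.0), abs=1e-12
    )


def test_oracle_equivalence_on_random_instances(code, kernel):
    rng = np.random.default_rng(31)
    for _ in range(6):
        tree = parse_newick(TREE4)
        col = {
            n: frozenset(rng.choice(61, size=int(rng.integers(1, 3)),
                                    replace=False).tolist())
            for n in "ABCD"
        }
        a = float(rng.uniform(0.2, 2.0))
        bm = float(rng.uniform(0.0, 0.8)) * a
        bp = float(rng.uniform(1.0, 9.0))
        pp = float(rng.uniform(0.05, 0.95))
        mix = CategoryMixture([(a, bm), (a, bp)], [1 - pp, pp])
        oracle = brute_force_mixture_likelihood(col, tree, mix, kernel)
        fast = SitePruner(col, tree, kernel).loglike_mixture(a, bm, bp, pp)
        assert fast == pytest.approx(oracle, abs=1e-9)


def test_brute_force_guard(code, kernel):
    tree = parse_newick(TREE4)
    col = _single_state_col(code, dict.fromkeys("ABCD", "AAA"))
    mix = CategoryMixture([(1.0, 0.1), (1.0, 5.0)], [0.5, 0.5])
    with pytest.raises(ValueError, match="guard"):
        brute_force_mixture_likelihood(col, tree, mix, kernel, guard=3)


def test_likelihood_invariant_to_rerooting(code, kernel):
    """Under the reversible model the site lnL does not depend on root
    placement."""
    import dendropy

    col = _single_state_col(
        code, {"A": "AAA", "B": "AAG", "C": "ACA", "D": "TTA"}
    )
    newick1 = "((A:0.2,B:0.3):0.15,(C:0.25,D:0.1):0.2);"
    dt = dendropy.Tree.get(data=newick1, schema="newick")
    edge = [e for e in dt.preorder_edge_iter()
            if e.head_node.taxon and e.head_node.taxon.label == "C"][0]
    dt.reroot_at_edge(edge, length1=0.1, length2=0.15,
                      update_bipartitions=False)
    newick2 = dt.as_string(schema="newick").strip()
    vals = []
    for nwk in (newick1, newick2):
        tree = parse_newick(nwk)
        pr = SitePruner(col, tree, kernel)
        vals.append(pr.loglike_single(1.0, 0.7))
    assert vals[0] == pytest.approx(vals[1], abs=1e-8)


def test_mixture_invariant_to_branch_enumeration_order(code, kernel):
    """Rotating clades preserves the branch set, hence the mixture lnL;
    (re-rooting that splits or merges edges changes the per-branch
    category draws and is *not* an invariance of the mixture model)."""
    col = _single_state_col(
        code, {"A": "AAA", "B": "AAG", "C": "ACA", "D": "TTA"}
    )
    vals = []
    for nwk in (
        "((A:0.2,B:0.3):0.15,(C:0.25,D:0.1):0.2);",
        "((D:0.1,C:0.25):0.2,(B:0.3,A:0.2):0.15);",
    ):
        pr = SitePruner(col, parse_newick(nwk), kernel)
        vals.append(pr.loglike_mixture(1.0, 0.3, 4.0, 0.25))
    assert vals[0] == pytest.approx(vals[1], abs=1e-12)


def test_no_underflow_on_deep_caterpillar(code, kernel):
    """Rescaling keeps long chains of improbable columns finite."""
    n = 24
    parts = "A0:0.01"
    for i in range(1, n):
        parts = f"({parts},A{i}:0.01):0.01"
    tree = parse_newick(parts + ";")
    idx = code.codon_index
    col = {f"A{i}": frozenset([idx["AAA"] if i % 2 else idx["TTT"]])
           for i in range(n)}
    pr = SitePruner(col, tree, kernel)
    lnl = pr.loglike_mixture(0.5, 0.1, 3.0, 0.2)
    assert np.isfinite(lnl)
    assert lnl < -100  # wildly improbable, but representable
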