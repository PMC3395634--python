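import numpy as np
import pytest

from memesel.eb import (
    BranchSelectionEvidence,
    branch_posteriors,
    flag_selected_branches,
)
from memesel.global_fit import GlobalFit
from memesel.likelihood import SitePruner, site_log_likelihood
from memesel.phylo import parse_newick
from memesel.rate_matrix import CodonModelKernel
from memesel.simulate import default_freqs, default_theta
from memesel.site_tests import MemeSiteParams


@pytest.fixture(scope="module")
def toy_gfit(code):
    tree = parse_newick("((A:0.05,B:0.05):0.05,(C:1.2,D:0.05):0.05);")
    raw = CodonModelKernel(code, default_theta(), default_freqs(), 1.0)
    return GlobalFit(
        theta=default_theta(), freqs=default_freqs(), omega_global=1.0,
        tree=tree, scale=1.0 / raw.mean_rate(1.0, 1.0), lnL=0.0, code=code,
    )


def _toy_col(code):
    idx = code.codon_index
    # A, B, D conserve AAA; C (long branch) shows a radical change
    return {"A": frozenset([idx["AAA"]]), "B": frozenset([idx["AAA"]]),
            "C": frozenset([idx["TGG"]]), "D": frozenset([idx["AAA"]])}


def test_equal_betas_give_posterior_equal_prior(toy_gfit, code):
    alt = MemeSiteParams(alpha=1.0, beta_minus=0.7, beta_plus=0.7, p_plus=0.3)
    for e in branch_posteriors(_toy_col(code), toy_gfit, alt):
        assert e.posterior == pytest.approx(0.3, abs=1e-12)
        assert e.ebf == pytest.approx(1.0, abs=1e-9)


def test_degenerate_prior_flags_undefined_ebf(toy_gfit, code):
    alt = MemeSiteParams(alpha=1.0, beta_minus=0.2, beta_plus=5.0, p_plus=0.0)
    ev = branch_posteriors(_toy_col(code), toy_gfit, alt)
    for e in ev:
        assert e.posterior == 0.0
        assert e.ebf is None
        assert not e.ebf_defined


def test_posterior_complement_sums_to_one(toy_gfit, code):
    alt = MemeSiteParams(alpha=1.0, beta_minus=0.0, beta_plus=8.0, p_plus=0.2)
    for e in branch_posteriors(_toy_col(code), toy_gfit, alt):
        # Pr(beta+) + Pr(beta-) = 1 by construction of the two-way posterior
        assert 0.0 <= e.posterior <= 1.0
        assert (e.posterior + (1.0 - e.posterior)) == pytest.approx(1.0,
                                                                    abs=1e-12)


def test_long_diversified_branch_attains_max_ebf(toy_gfit, code):
    """Cross-checked against direct computation of the two constrained
    pruning likelihoods through explicit mixture matrices."""
    col = _toy_col(code)
    alt = MemeSiteParams(alpha=1.0, beta_minus=0.0, beta_plus=8.0, p_plus=0.2)
    ev = branch_posteriors(col, toy_gfit, alt)
    defined = [e for e in ev if e.ebf is not None]
    best = max(defined, key=lambda e: e.ebf)
    assert best.branch_name == "C"

    # independent route: explicit matrices, plain pruning
    kernel = toy_gfit.kernel()
    tree = toy_gfit.tree
    from memesel.likelihood import CategoryMixture, branch_mixture_matrix

    mix = CategoryMixture([(1.0, 0.0), (1.0, 8.0)], [0.8, 0.2])
    focal = next(b for b in tree.branches if b.name == "A")
    mats = [branch_mixture_matrix(mix, kernel, b.length) for b in tree.branches]
    mats_plus = list(mats)
    mats_plus[focal.id] = kernel.transition_matrix(1.0, 8.0, focal.length)
    mats_minus = list(mats)
    mats_minus[focal.id] = kernel.transition_matrix(1.0, 0.0, focal.length)
    l_plus = site_log_likelihood(col, tree, mats_plus, kernel.pi)
    l_minus = site_log_likelihood(col, tree, mats_minus, kernel.pi)
    post = 0.2 * np.exp(l_plus) / (0.2 * np.exp(l_plus) + 0.8 * np.exp(l_minus))
    e_a = next(e for e in ev if e.branch_name == "A")
    assert e_a.posterior == pytest.approx(post, abs=1e-10)
    ebf_direct = (post / (1 - post)) / (0.2 / 0.8)
    assert e_a.ebf == pytest.approx(ebf_direct, rel=1e-8)


def test_flagging_thresholds_and_monotonicity():
    ev = [
        BranchSelectionEvidence(0, "x", 0.99, 0.2, 25.0),
        BranchSelectionEvidence(1, "y", 0.60, 0.2, 6.0),
        BranchSelectionEvidence(2, "z", 0.20, 0.2, None),
    ]
    assert flag_selected_branches(ev, site_p=0.5) == []  # site not significant
    flagged = flag_selected_branches(ev, site_p=0.01)
    assert [e.branch_name for e in flagged] == ["x"]
    looser = flag_selected_branches(ev, site_p=0.01, ebf_threshold=5.0)
    assert {e.branch_name for e in flagged} <= {e.branch_name for e in looser}


def test_branch_detection_beats_background_false_flags(episodic32_analysis):
    """Branch-level evidence is weak by design, but truly selected
    branches must be flagged at EBF >= 20 more often than background
    branches at significant sites."""
    aln, truth, gfit, results = episodic32_analysis
    kernel = gfit.kernel()
    true_hits = back_hits = true_n = back_n = 0
    for r in results:
        if r.p_meme > 0.05 or r.invariant:
            continue
        plus = set(truth.loc[r.site - 1, "plus_branches"].split("|")) - {""}
        pruner = SitePruner(aln.columns[r.site - 1], gfit.tree, kernel)
        ev = branch_posteriors(pruner, gfit, r.meme_alt)
        for e in ev:
            hit = e.ebf is not None and e.ebf >= 20.0
            if e.branch_name in plus:
                true_n += 1
                true_hits += hit
            else:
                back_n += 1
                back_hits += hit
    assert true_n > 0 and back_n > 0
    assert true_hits / true_n >= back_hits / back_n
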