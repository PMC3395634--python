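import numpy as np
import pytest
from scipy.stats import chi2

from memesel.likelihood import SitePruner
from memesel.site_tests import (
    MemeSiteParams,
    MixtureNull,
    bh_qvalues,
    fit_fel_site,
    fit_meme_alternative,
    fit_meme_null,
    meme_pvalue,
    meme_vs_fel_test,
)


# ---- asymptotic machinery (closed-form pieces) -----------------------


def test_meme_pvalue_at_zero_is_one():
    assert meme_pvalue(0.0) == 1.0


def test_meme_pvalue_brackets_between_component_tails():
    for lrt in (0.5, 2.0, 3.84, 8.0):
        p = meme_pvalue(lrt)
        assert chi2.sf(lrt, 1) <= p <= chi2.sf(lrt, 2)


def test_meme_pvalue_exceeds_fel_pvalue_at_equal_lrt():
    """The mixture null is strictly more conservative than chi2(1):
    borderline FEL-significant LRT values are non-significant for the
    branch-site test."""
    for lrt in (0.1, 1.0, 3.84, 6.0, 12.0):
        assert meme_pvalue(lrt) > chi2.sf(lrt, 1)


def test_default_mixture_weights():
    null = MixtureNull()
    assert null.components == [(1, pytest.approx(1 / 3)),
                               (2, pytest.approx(2 / 3))]
    lrt = 4.0
    expected = (chi2.sf(lrt, 1) / 3) + (2 * chi2.sf(lrt, 2) / 3)
    assert null.pvalue(lrt) == pytest.approx(expected)


def test_fel_chi2_quantile():
    # LRT = 3.841 is the 5% point of chi2(1)
    assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-3)


def test_meme_vs_fel_two_df():
    assert meme_vs_fel_test(-100.0, -100.0) == 1.0
    assert meme_vs_fel_test(-97.0, -100.0) == pytest.approx(
        chi2.sf(6.0, 2), abs=1e-12
    )
    assert meme_vs_fel_test(-97.0, -100.0) == pytest.approx(0.0498, abs=1e-3)
    with pytest.raises(ValueError):
        meme_vs_fel_test(-101.0, -100.0)


def test_bh_qvalues():
    q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert bh_qvalues([0.37]) == pytest.approx([0.37])
    assert bh_qvalues([]).size == 0
    rng = np.random.default_rng(8)
    p = rng.uniform(size=50)
    q = bh_qvalues(p)
    assert np.all(q >= p - 1e-15)
    assert np.all((q >= 0) & (q <= 1))
    # monotone transform: sorting p gives non-decreasing q
    q_sorted = bh_qvalues(np.sort(p))
    assert np.all(np.diff(q_sorted) >= -1e-15)


def test_meme_params_validation():
    with pytest.raises(ValueError):
        MemeSiteParams(alpha=1.0, beta_minus=2.0, beta_plus=1.0, p_plus=0.5)
    with pytest.raises(ValueError):
        MemeSiteParams(alpha=1.0, beta_minus=0.5, beta_plus=1.0, p_plus=1.5)


# ---- per-site fits on simulated data ---------------------------------


def test_invariant_column_short_circuits(neutral16_analysis, code):
    from memesel.alignment import CodonAlignment
    from memesel.site_tests import analyze_sites

    _, _, gfit, _ = neutral16_analysis
    names = gfit.tree.leaf_names
    aaa = frozenset([code.codon_index["AAA"]])
    aln = CodonAlignment(
        names=names, columns=[{n: aaa for n in names}], code=code
    )
    (r,) = analyze_sites(aln, gfit)
    assert r.invariant
    assert r.lrt == 0.0
    assert r.p_meme == 1.0
    assert r.fel.classification == "neutral"
    assert r.fel.alpha == 0.0 and r.fel.beta == 0.0


def test_fel_start_reproduces_fel_likelihood(neutral16_analysis):
    """The FEL-equivalent point of the mixture parameter space attains
    the FEL lnL exactly (p_plus at the boundary)."""
    aln, _, gfit, _ = neutral16_analysis
    kernel = gfit.kernel()
    pruner = SitePruner(aln.columns[0], gfit.tree, kernel)
    fel = fit_fel_site(pruner, gfit)
    if fel.beta >= fel.alpha:
        lnl = pruner.loglike_mixture(fel.alpha, fel.alpha, fel.beta, 1.0)
    else:
        lnl = pruner.loglike_mixture(fel.alpha, fel.beta, fel.beta, 0.0)
    assert lnl == pytest.approx(fel.lnl_uncon, abs=1e-9)


def test_null_constraint_behavior(neutral16_analysis):
    """When the alternative MLE already satisfies beta_plus <= alpha the
    LRT is exactly zero; otherwise the null fit respects the constraint."""
    _, _, _, results = neutral16_analysis
    saw_active = False
    for r in results:
        if r.invariant:
            continue
        if r.meme_alt.beta_plus <= r.meme_alt.alpha:
            assert r.lrt == 0.0
            assert r.p_meme == 1.0
        else:
            assert r.meme_null.beta_plus <= r.meme_null.alpha + 1e-6
            saw_active = True
    assert saw_active  # some site should exercise the constrained fit


def test_strongly_selected_column_detected(episodic32_analysis):
    """A column with many positively selected branch draws yields a
    nonzero LRT and beta_plus above alpha."""
    _, truth, _, results = episodic32_analysis
    heavy = truth[truth["n_plus_branches"] >= 6].index
    assert len(heavy) > 0
    hits = [results[i] for i in heavy if results[i].lrt > 0]
    assert len(hits) >= len(heavy) * 0.5
    for r in hits[:5]:
        assert r.meme_alt.beta_plus > r.meme_alt.alpha


def test_results_are_deterministic(neutral16_analysis):
    """Re-fitting the same column reproduces the stored result bit-for-bit
    (the optimization has no stochastic component)."""
    aln, _, gfit, results = neutral16_analysis
    kernel = gfit.kernel()
    r = next(r for r in results if not r.invariant)
    pruner = SitePruner(aln.columns[r.site - 1], gfit.tree, kernel)
    fel = fit_fel_site(pruner, gfit)
    alt, lnl_alt = fit_meme_alternative(pruner, gfit, fel=fel)
    assert lnl_alt == r.lnl_alt
    assert (alt.alpha, alt.beta_minus, alt.beta_plus, alt.p_plus) == (
        r.meme_alt.alpha, r.meme_alt.beta_minus,
        r.meme_alt.beta_plus, r.meme_alt.p_plus,
    )
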