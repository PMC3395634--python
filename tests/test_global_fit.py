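import json

import numpy as np
import pytest

from memesel.frequencies import FrequencyModel
from memesel.global_fit import (
    AlignmentPruner,
    GlobalFit,
    compress_columns,
    empirical_base_frequencies,
    fit_global_mg94,
    fit_nucleotide_gtr,
    leaf_pattern_matrices,
)
from memesel.alignment import alignment_from_strings
from memesel.rate_matrix import GTRKernel, NucleotideExchangeabilities
from memesel.simulate import (
    ConstantSite,
    SimulationScenario,
    balanced_tree,
    simulate_alignment,
)


@pytest.fixture(scope="module")
def jc_like_alignment():
    """Simulation with equal exchangeabilities and uniform frequencies."""
    tree = balanced_tree(8, seed=3, length_range=(0.1, 0.4))
    scn = SimulationScenario(
        tree=tree,
        sites=[ConstantSite(1.0, 1.0)] * 400,
        theta=NucleotideExchangeabilities(),  # all ones
        freqs=FrequencyModel.uniform(),
        seed=29,
    )
    aln, _ = simulate_alignment(scn)
    return tree, aln


def test_gtr_recovers_equal_exchangeabilities(jc_like_alignment):
    tree, aln = jc_like_alignment
    fit = fit_nucleotide_gtr(aln, tree)
    rates = np.array(list(fit.theta.as_dict().values()))
    # true value 1 for every pair; demand recovery within sampling noise
    assert np.all(rates > 0.6)
    assert np.all(rates < 1.6)
    assert np.isfinite(fit.lnL)


def test_gtr_identical_sequences_collapse_lengths(code):
    seqs = {f"s{i}": "ATGAAATTTCCCGGG" * 4 for i in range(4)}
    aln = alignment_from_strings(seqs, code)
    from memesel.phylo import parse_newick

    tree = parse_newick("((s0:0.1,s1:0.1):0.1,(s2:0.1,s3:0.1):0.1);")
    with pytest.warns(UserWarning, match="branch lengths"):
        fit = fit_nucleotide_gtr(aln, tree)
    assert float(np.max(fit.branch_lengths)) < 1e-4


def test_global_mg94_recovers_omega(neutral16_analysis):
    _, _, gfit, _ = neutral16_analysis
    assert 0.8 <= gfit.omega_global <= 1.2  # truth: 1.0, 300 sites
    assert gfit.scale > 0
    # scale is the unit-mean-rate normalizer at the fitted omega
    kernel = gfit.kernel()
    assert kernel.mean_rate(1.0, gfit.omega_global) == pytest.approx(1.0)


def test_global_fit_improves_on_gtr_start(jc_like_alignment):
    tree, aln = jc_like_alignment
    init = fit_nucleotide_gtr(aln, tree)
    gfit = fit_global_mg94(aln, tree, init=init)
    assert np.isfinite(gfit.lnL)
    assert all(v >= 0 for v in gfit.branch_lengths.values())
    # lnL at the fit beats the lnL at the mapped starting point
    from memesel.global_fit import (
        AlignmentPruner,
        compress_columns,
        leaf_pattern_matrices,
    )

    patterns, counts, _ = compress_columns(aln.columns, aln.names)
    leaf_mats = leaf_pattern_matrices(patterns, aln.names, gfit.tree, 61)
    pruner = AlignmentPruner(gfit.tree, leaf_mats, counts, 61)
    kernel = gfit.kernel()
    start_times = np.clip(3.0 * init.branch_lengths, 1e-6, 25.0)
    lnl_start = pruner.loglike(
        kernel.transition_stack(1.0, gfit.omega_global, start_times),
        kernel.pi,
    )
    assert gfit.lnL >= lnl_start - 1e-6


def test_global_fit_serialization_round_trip(neutral16_analysis):
    _, _, gfit, _ = neutral16_analysis
    text = gfit.to_json()
    back = GlobalFit.from_json(text)
    assert back.omega_global == pytest.approx(gfit.omega_global)
    assert back.scale == pytest.approx(gfit.scale)
    assert np.allclose(back.freqs.pos_freqs, gfit.freqs.pos_freqs)
    assert back.theta.as_dict() == pytest.approx(gfit.theta.as_dict())
    assert [b.name for b in back.tree.branches] == [
        b.name for b in gfit.tree.branches
    ]
    assert np.allclose(
        [b.length for b in back.tree.branches],
        [b.length for b in gfit.tree.branches],
    )
    json.loads(text)  # valid JSON document


def test_inside_outside_contexts_match_direct_likelihood(kernel):
    """The branch-local decomposition reproduces the full pruning lnL for
    every branch's transition matrix slot."""
    tree = balanced_tree(8, seed=7)
    scn = SimulationScenario(tree=tree, sites=[ConstantSite(1.0, 0.7)] * 40,
                             seed=3)
    aln, _ = simulate_alignment(scn)
    patterns, counts, _ = compress_columns(aln.columns, aln.names)
    leaf_mats = leaf_pattern_matrices(patterns, aln.names, tree, 61)
    pruner = AlignmentPruner(tree, leaf_mats, counts, 61)
    times = np.array([b.length for b in tree.branches])
    pstack = kernel.transition_stack(1.0, 0.7, times)
    direct = pruner.loglike(pstack, kernel.pi)
    down, dscale, ctx = pruner.branch_contexts(pstack, kernel.pi)
    for b in range(tree.n_branches):
        via_branch = pruner.branch_loglike(b, pstack[b], down, dscale, ctx)
        assert via_branch == pytest.approx(direct, abs=1e-8)


def test_empirical_base_frequencies(code):
    aln = alignment_from_strings({"a": "AAAAAA", "b": "CCCCCC"}, code)
    pi = empirical_base_frequencies(aln)
    assert pi == pytest.approx([0.5, 0.5, 0.0, 0.0])
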