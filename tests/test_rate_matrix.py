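import numpy as np
import pytest

from memesel.frequencies import FrequencyModel, equilibrium_codon_frequencies
from memesel.rate_matrix import (
    CodonModelKernel,
    GTRKernel,
    NucleotideExchangeabilities,
    build_codon_rate_matrix,
    transition_matrix,
)
from memesel.simulate import default_freqs, default_theta


def test_multi_nucleotide_changes_have_zero_rate(kernel, code):
    q = kernel.rate_matrix(1.0, 1.0)
    idx = code.codon_index
    assert q.q[idx["AAA"], idx["ACC"]] == 0.0  # two differences
    assert q.q[idx["AAA"], idx["CCC"]] == 0.0  # three differences
    assert q.q[idx["AAA"], idx["AAC"]] > 0.0   # single difference


def test_single_change_rates_follow_definition(code):
    theta = default_theta()
    freqs = default_freqs()
    scale = 1.7
    q = build_codon_rate_matrix(0.8, 1.9, theta, freqs, code, scale)
    idx = code.codon_index
    # AAA -> AAG: Lys -> Lys, synonymous, change at position 3 to G
    expected_syn = scale * 0.8 * theta("A", "G") * freqs.pos_freqs[2, 2]
    assert q.q[idx["AAA"], idx["AAG"]] == pytest.approx(expected_syn)
    # AAA -> AAC: Lys -> Asn, nonsynonymous, change at position 3 to C
    expected_non = scale * 1.9 * theta("A", "C") * freqs.pos_freqs[2, 1]
    assert q.q[idx["AAA"], idx["AAC"]] == pytest.approx(expected_non)


def test_rows_sum_to_zero_and_reversibility(kernel):
    q = kernel.rate_matrix(0.7, 1.3)
    assert np.abs(q.q.sum(axis=1)).max() < 1e-10
    flux = q.pi[:, None] * q.q
    assert np.abs(flux - flux.T).max() < 1e-10


def test_mean_rate_normalization(code):
    theta, freqs = default_theta(), default_freqs()
    raw = CodonModelKernel(code, theta, freqs, 1.0)
    scale = 1.0 / raw.mean_rate(1.0, 1.0)
    k = CodonModelKernel(code, theta, freqs, scale)
    q = k.rate_matrix(1.0, 1.0)
    assert float(q.pi @ (-np.diag(q.q))) == pytest.approx(1.0)


def test_nonsynonymous_flux_increases_with_beta(kernel, code):
    from memesel.rate_matrix import single_nt_change_table

    tab = single_nt_change_table(code)
    ns = ~tab["syn"]

    def nonsyn_flux(beta):
        q = kernel.rate_matrix(1.0, beta)
        return float(np.sum(q.pi[tab["i"][ns]] * q.q[tab["i"][ns], tab["j"][ns]]))

    fluxes = [nonsyn_flux(b) for b in (0.5, 1.0, 2.0, 5.0)]
    assert all(b > a for a, b in zip(fluxes, fluxes[1:]))


def test_transition_matrix_identity_at_zero(kernel):
    p = kernel.transition_matrix(1.0, 0.5, 0.0)
    assert np.allclose(p, np.eye(61))


def test_transition_matrix_ergodic_limit(kernel):
    p = kernel.transition_matrix(1.0, 0.8, 1e4)
    assert np.abs(p - kernel.pi[None, :]).max() < 1e-6


def test_transition_matrix_semigroup(kernel):
    p1 = kernel.transition_matrix(0.9, 1.7, 0.3)
    p2 = kernel.transition_matrix(0.9, 1.7, 0.7)
    p3 = kernel.transition_matrix(0.9, 1.7, 1.0)
    assert np.abs(p1 @ p2 - p3).max() < 1e-8


def test_transition_reversibility_in_time(kernel):
    p = kernel.transition_matrix(1.0, 2.0, 0.4)
    flux = kernel.pi[:, None] * p
    assert np.abs(flux - flux.T).max() < 1e-8


def test_spectral_path_matches_scipy_expm(kernel):
    q = kernel.rate_matrix(0.7, 1.3)
    p_spec = kernel.transition_matrix(0.7, 1.3, 0.35)
    p_expm = transition_matrix(q, 0.35)
    assert np.abs(p_spec - p_expm).max() < 1e-12
    assert np.abs(p_expm.sum(axis=1) - 1.0).max() < 1e-10


def test_negative_inputs_rejected(code):
    theta, freqs = default_theta(), default_freqs()
    with pytest.raises(ValueError):
        build_codon_rate_matrix(-0.1, 1.0, theta, freqs, code)
    with pytest.raises(ValueError):
        NucleotideExchangeabilities(ac=-1.0)
    k = CodonModelKernel(code, theta, freqs, 1.0)
    with pytest.raises(ValueError):
        k.transition_matrix(1.0, 1.0, -0.2)


def test_gtr_kernel_unit_mean_rate_and_rows():
    pi = np.array([0.3, 0.2, 0.25, 0.25])
    k = GTRKernel(default_theta(), pi)
    assert float(pi @ (-np.diag(k.q))) == pytest.approx(1.0)
    p = k.transition_stack(np.array([0.1, 1.0]))
    assert np.abs(p.sum(axis=2) - 1.0).max() < 1e-10


def test_equilibrium_consistent_between_kernel_and_frequencies(code, kernel):
    assert np.allclose(
        kernel.pi, equilibrium_codon_frequencies(default_freqs(), code)
    )
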