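import os

# Single-threaded linear algebra: the matrices here are 61x61, where BLAS
# threading only adds contention. Must run before numpy is imported.
for _v in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np  # noqa: E402
import pytest  # noqa: E402

from memesel.genetic_code import get_genetic_code  # noqa: E402
from memesel.global_fit import fit_global_mg94, fit_nucleotide_gtr  # noqa: E402
from memesel.rate_matrix import CodonModelKernel  # noqa: E402
from memesel.simulate import (  # noqa: E402
    ConstantSite,
    EpisodicSite,
    SimulationScenario,
    balanced_tree,
    default_freqs,
    default_theta,
    simulate_alignment,
)
from memesel.site_tests import analyze_sites  # noqa: E402


@pytest.fixture(scope="session")
def code():
    return get_genetic_code(1)


@pytest.fixture(scope="session")
def kernel(code):
    return CodonModelKernel(code, default_theta(), default_freqs(), 1.0)


@pytest.fixture(scope="session")
def unit_kernel(code):
    """Kernel normalized to unit mean rate at alpha = beta = 1."""
    raw = CodonModelKernel(code, default_theta(), default_freqs(), 1.0)
    return CodonModelKernel(
        code, default_theta(), default_freqs(), 1.0 / raw.mean_rate(1.0, 1.0)
    )


def _simulate_and_analyze(tree, sites, sim_seed):
    aln, truth = simulate_alignment(
        SimulationScenario(tree=tree, sites=sites, seed=sim_seed)
    )
    init = fit_nucleotide_gtr(aln, tree)
    gfit = fit_global_mg94(aln, tree, init=init)
    results = analyze_sites(aln, gfit)
    return aln, truth, gfit, results


@pytest.fixture(scope="session")
def neutral16_analysis():
    """Strict-neutral study: 300 sites, 16-taxon tree, full pipeline.

    Shared by the type-I-error check and the per-site invariant sweeps.
    """
    tree = balanced_tree(16, seed=21)
    return _simulate_and_analyze(
        tree, [ConstantSite(alpha=1.0, omega=1.0)] * 300, sim_seed=13
    )


@pytest.fixture(scope="session")
def episodic32_analysis():
    """Episodic study: omega_minus=0, omega_plus=36, q_plus=0.1 on a
    32-taxon tree, 60 sites."""
    tree = balanced_tree(32, seed=11)
    return _simulate_and_analyze(
        tree,
        [EpisodicSite(alpha=1.0, omega_minus=0.0, omega_plus=36.0,
                      q_plus=0.1)] * 60,
        sim_seed=17,
    )
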