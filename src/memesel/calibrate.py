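"""Parametric-bootstrap calibration of the LRT null distribution.

The MEME null pins beta_plus to the boundary of the alternative's
parameter space, so the LRT statistic is not asymptotically a single
chi-square. Simulating sites under the strict-neutral null (alpha =
beta = 1 on every branch), refitting both models, and collecting the
LRT sample lets one check — or refit — the weight of the default
chi-square(1)/chi-square(2) mixture: chi-square(1) alone is too liberal
in the testing-relevant tail, chi-square(2) alone too conservative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .frequencies import FrequencyModel
from .genetic_code import get_genetic_code
from .global_fit import GlobalFit
from .likelihood import SitePruner
from .phylo import Phylogeny
from .rate_matrix import CodonModelKernel, NucleotideExchangeabilities
from .simulate import ConstantSite, default_freqs, default_theta, simulate_site
from .site_tests import (
    MixtureNull,
    fit_fel_site,
    fit_meme_alternative,
    fit_meme_null,
)

#: Tail of test-relevant p-values over which the mixture is calibrated.
TAIL_P_RANGE = (0.001, 0.1)


@dataclass
class CalibrationResult:
    mixture: MixtureNull
    weight_1df: float
    lrts: np.ndarray
    table: pd.DataFrame  # LRT grid with empirical and asymptotic tails
    degenerate: bool = False


def fit_tail_weight(
    lrts: np.ndarray,
    p_range: tuple[float, float] = TAIL_P_RANGE,
    grid_size: int = 200,
) -> tuple[float, pd.DataFrame]:
    """Weight on the chi-square(1) component minimizing the sup distance
    between the mixture tail and the empirical LRT tail.

    The comparison is restricted to the testing-relevant region, i.e.
    LRT values whose mixture p-value falls in ``p_range``; the point mass
    at LRT = 0 (sites whose alternative fit already satisfies the null
    constraint) is irrelevant there by construction.
    """
    lrts = np.asarray(lrts, dtype=float)
    lo = chi2.isf(p_range[1], 1)  # smallest relevant LRT under chi2_1
    hi = chi2.isf(p_range[0], 2)  # largest relevant LRT under chi2_2
    grid = np.linspace(lo, hi, grid_size)
    emp_tail = (lrts[None, :] >= grid[:, None]).mean(axis=1)
    s1 = chi2.sf(grid, 1)
    s2 = chi2.sf(grid, 2)
    weights = np.linspace(0.0, 1.0, 401)
    sup = np.array(
        [np.max(np.abs(w * s1 + (1 - w) * s2 - emp_tail)) for w in weights]
    )
    w = float(weights[int(np.argmin(sup))])
    table = pd.DataFrame(
        {
            "lrt": grid,
            "empirical_tail": emp_tail,
            "chi2_1_tail": s1,
            "chi2_2_tail": s2,
            "mixture_tail": w * s1 + (1 - w) * s2,
        }
    )
    return w, table


def calibrate_null_mixture(
    tree: Phylogeny,
    theta: NucleotideExchangeabilities | None = None,
    freqs: FrequencyModel | None = None,
    n_reps: int = 500,
    seed: int = 0,
    code=None,
) -> CalibrationResult:
    """Bootstrap the strict-neutral LRT null and refit the mixture weight.

    Sites are simulated with alpha = beta = 1 on every branch of ``tree``
    (lengths required), then put through the full MEME alternative/null
    fits with the generating parameters as the stage-1 conditioning —
    the parametric bootstrap of the test statistic.
    """
    if n_reps < 500:
        warnings.warn("fewer than 500 replicates gives a noisy tail estimate")
    code = code or get_genetic_code()
    theta = theta or default_theta()
    freqs = freqs or default_freqs()
    raw = CodonModelKernel(code, theta, freqs, 1.0)
    scale = 1.0 / raw.mean_rate(1.0, 1.0)
    kernel = CodonModelKernel(code, theta, freqs, scale)
    gfit = GlobalFit(
        theta=theta, freqs=freqs, omega_global=1.0, tree=tree,
        scale=scale, lnL=np.nan, code=code,
    )
    spec = ConstantSite(alpha=1.0, omega=1.0)
    lrts = np.empty(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        col, _ = simulate_site(spec, tree, kernel, rng, site_index=r + 1)
        pruner = SitePruner(col, tree, kernel)
        fel = fit_fel_site(pruner, gfit)
        alt, lnl_alt = fit_meme_alternative(pruner, gfit, fel=fel)
        _, lnl_null = fit_meme_null(pruner, gfit, alt, lnl_alt)
        lrts[r] = max(0.0, 2.0 * (lnl_alt - lnl_null))
    if np.all(lrts == 0.0):
        warnings.warn("all bootstrap LRTs are zero (point mass); "
                      "mixture weight not identifiable")
        return CalibrationResult(
            mixture=MixtureNull(), weight_1df=1.0 / 3.0,
            lrts=lrts, table=pd.DataFrame(), degenerate=True,
        )
    w, table = fit_tail_weight(lrts)
    return CalibrationResult(
        mixture=MixtureNull(components=[(1, w), (2, 1.0 - w)]),
        weight_1df=w,
        lrts=lrts,
        table=table,
    )
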