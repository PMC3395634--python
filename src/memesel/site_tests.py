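"""Per-site tests for diversifying selection: MEME and the FEL reference.

FEL fits a single (alpha, beta) rate pair per site and tests beta = alpha
with a chi-square(1) LRT; positive selection requires beta > alpha.

MEME's alternative model gives each site four fixed effects — a
synonymous rate alpha, a restricted nonsynonymous rate beta_minus <=
alpha with weight 1 - p_plus, and an unrestricted beta_plus with weight
p_plus — while each branch draws its category independently (the random
effect, marginalized by mixture pruning). The null constrains beta_plus
<= alpha as well, so the LRT is one-sided for episodes of
diversification; when the alternative MLE already satisfies the
constraint the LRT is exactly zero. Because the constrained parameter
sits on the boundary under the null, the LRT statistic is compared with
a mixture of chi-square distributions rather than a single chi-square;
the default mixture puts weight 1/3 on 1 df and 2/3 on 2 df, between the
too-liberal pure chi-square(1) and too-conservative chi-square(2), and
can be recalibrated by parametric bootstrap
(:func:`memesel.calibrate.calibrate_null_mixture`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .alignment import CodonAlignment
from .global_fit import GlobalFit
from .likelihood import SiteColumn, SitePruner

RATE_BOUNDS = (0.0, 1e4)  # beta+ CIs in real data reach the thousands
DEFAULT_P_THRESHOLD = 0.05


@dataclass
class MemeSiteParams:
    """Fixed effects of the branch-site mixture at one site."""

    alpha: float
    beta_minus: float
    beta_plus: float
    p_plus: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_plus <= 1.0:
            raise ValueError("p_plus must lie in [0, 1]")
        if self.beta_minus > self.alpha + 1e-9:
            raise ValueError("beta_minus must not exceed alpha")

    @property
    def p_minus(self) -> float:
        return 1.0 - self.p_plus


@dataclass
class MixtureNull:
    """Asymptotic null for the boundary-constrained LRT: a weighted
    mixture of central chi-square components."""

    components: list[tuple[int, float]] = field(
        default_factory=lambda: [(1, 1.0 / 3.0), (2, 2.0 / 3.0)]
    )

    def __post_init__(self) -> None:
        w = np.array([wt for _, wt in self.components])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be nonnegative and sum to 1")

    def pvalue(self, lrt: float) -> float:
        if lrt < 0:
            raise ValueError("LRT must be nonnegative")
        return float(
            sum(w * chi2.sf(lrt, df) for df, w in self.components)
        )


def meme_pvalue(lrt: float, null: MixtureNull | None = None) -> float:
    """p-value of the MEME LRT under the mixture-chi-square null."""
    return (null or MixtureNull()).pvalue(lrt)


def meme_vs_fel_test(lnl_meme_alt: float, lnl_fel_uncon: float) -> float:
    """2-df LRT comparing MEME's alternative against the FEL fit.

    FEL is nested in MEME's alternative (two extra parameters), so a
    small p indicates branch-to-branch rate variation at the site.
    """
    if lnl_meme_alt < lnl_fel_uncon - 1e-6:
        raise ValueError("MEME alternative lnL below FEL lnL violates nesting")
    lrt = max(0.0, 2.0 * (lnl_meme_alt - lnl_fel_uncon))
    return float(chi2.sf(lrt, 2))


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------
# per-site fits
# ---------------------------------------------------------------------


@dataclass
class FelSiteResult:
    alpha: float
    beta: float
    lnl_uncon: float
    lnl_constrained: float
    lrt: float
    p: float
    classification: str  # positive | negative | neutral


_BIG = 1e12


def _finite(neg_lnl: float) -> float:
    """Clamp -inf/NaN objective values so finite differences stay valid."""
    return neg_lnl if np.isfinite(neg_lnl) else _BIG


def _fel_neg_loglike(pruner: SitePruner):
    def neg(x: np.ndarray) -> float:
        return _finite(-pruner.loglike_single(float(x[0]), float(x[1])))

    return neg


def _bracketed_scalar_max(f, grid=(1e-4, 0.01, 0.1, 0.3, 1.0, 3.0, 10.0, 50.0)):
    """Maximize a unimodal-but-plateaued rate profile: coarse grid scan,
    then bounded Brent between the neighbors of the best grid point.

    The likelihood flattens for large rates (transition matrices reach
    equilibrium), so an unbracketed bounded search over the full rate
    range can stall on the plateau.
    """
    vals = [f(g) for g in grid]
    k = int(np.argmax(vals))
    lo = 0.0 if k == 0 else grid[k - 1]
    hi = grid[min(len(grid) - 1, k + 1)] * (2.0 if k == len(grid) - 1 else 1.0)
    res = minimize_scalar(
        lambda r: _finite(-f(r)), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    if -res.fun >= vals[k]:
        return float(res.x), float(-res.fun)
    return float(grid[k]), float(vals[k])


def fit_fel_site(
    col: SiteColumn | SitePruner,
    gfit: GlobalFit,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    invariant: bool | None = None,
) -> FelSiteResult:
    """FEL at one site: unconstrained (alpha, beta) vs constrained beta = alpha."""
    pruner = _as_pruner(col, gfit)
    if invariant:
        # No substitutions: the likelihood is maximized at zero rates and
        # the constrained fit attains the same value.
        lnl0 = pruner.loglike_single(0.0, 0.0)
        return FelSiteResult(0.0, 0.0, lnl0, lnl0, 0.0, 1.0, "neutral")

    neg = _fel_neg_loglike(pruner)
    r_con, lnl_con = _bracketed_scalar_max(
        lambda r: pruner.loglike_single(r, r)
    )
    best = None
    for start in ((1.0, 1.0), (1.0, 0.3), (1.0, 3.0), (r_con, r_con)):
        res = minimize(
            neg, np.array(start), method="L-BFGS-B",
            bounds=[RATE_BOUNDS, RATE_BOUNDS],
            options={"maxiter": 150, "ftol": 1e-11},
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta = (float(v) for v in best.x)
    lnl_uncon = -float(best.fun)
    if lnl_con > lnl_uncon:  # constrained point beats unconstrained search
        alpha = beta = r_con
        lnl_uncon = lnl_con
    lrt = max(0.0, 2.0 * (lnl_uncon - lnl_con))
    p = float(chi2.sf(lrt, 1))
    if p <= p_threshold and beta > alpha:
        cls = "positive"
    elif p <= p_threshold and beta < alpha:
        cls = "negative"
    else:
        cls = "neutral"
    return FelSiteResult(alpha, beta, lnl_uncon, lnl_con, lrt, p, cls)


def _meme_neg_loglike(pruner: SitePruner):
    """Alternative-model objective over (alpha, f, beta_plus, p_plus)
    with beta_minus = f * alpha, f in [0, 1]."""

    def neg(x: np.ndarray) -> float:
        alpha, f, beta_plus, p_plus = (float(v) for v in x)
        return _finite(-pruner.loglike_mixture(alpha, f * alpha, beta_plus, p_plus))

    return neg


def _fel_equivalent_point(fel: FelSiteResult) -> np.ndarray:
    """MEME parameter vector reproducing the FEL fit exactly."""
    if fel.beta >= fel.alpha:
        return np.array([fel.alpha, 1.0, fel.beta, 1.0])
    f = fel.beta / fel.alpha if fel.alpha > 0 else 0.0
    return np.array([fel.alpha, f, fel.beta, 0.0])


def fit_meme_alternative(
    col: SiteColumn | SitePruner,
    gfit: GlobalFit,
    fel: FelSiteResult | None = None,
    n_local_starts: int = 1,
) -> tuple[MemeSiteParams, float]:
    """Fit the four-parameter MEME alternative at one site.

    Starts from a deterministic grid over (p_plus, beta_plus) warm-started
    at the FEL estimates; the grid is ranked by likelihood and local
    optimization is run from the top points plus the FEL-equivalent point,
    which guarantees the nesting invariant lnL_alt >= lnL_FEL.
    """
    pruner = _as_pruner(col, gfit)
    if fel is None:
        fel = fit_fel_site(pruner, gfit)
    neg = _meme_neg_loglike(pruner)
    bounds = [RATE_BOUNDS, (0.0, 1.0), RATE_BOUNDS, (0.0, 1.0)]

    a0 = fel.alpha
    f0 = min(1.0, fel.beta / a0) if a0 > 0 else 0.0
    grid = [
        np.array([a0, f0, bp, pp])
        for pp in (0.05, 0.25, 0.5, 1.0)
        for bp in (fel.beta, 2.0 * a0 + 1.0, 10.0)
    ]
    fel_point = _fel_equivalent_point(fel)
    scored = sorted(grid, key=neg)
    starts = scored[:n_local_starts] + [fel_point]

    best_x, best_f = fel_point, neg(fel_point)
    for x0 in starts:
        res = minimize(
            neg, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 120, "ftol": 1e-10},
        )
        better = res.fun < best_f - 1e-9
        tie = abs(res.fun - best_f) <= 1e-9 and res.x[3] < best_x[3]
        if better or tie:
            best_x, best_f = res.x, min(res.fun, best_f)
    lnl_alt = -float(best_f)
    if lnl_alt < fel.lnl_uncon:  # numerical safety: FEL point is feasible
        best_x, lnl_alt = fel_point, fel.lnl_uncon
    alpha, f, beta_plus, p_plus = (float(v) for v in best_x)
    params = MemeSiteParams(
        alpha=alpha, beta_minus=f * alpha, beta_plus=beta_plus, p_plus=p_plus
    )
    return params, lnl_alt


def fit_meme_null(
    col: SiteColumn | SitePruner,
    gfit: GlobalFit,
    alt: MemeSiteParams,
    lnl_alt: float,
) -> tuple[MemeSiteParams, float]:
    """Fit the MEME null (beta_plus <= alpha), warm-started at the
    alternative MLE.

    If the alternative already satisfies the constraint the null fit is
    the alternative fit and the LRT is zero.
    """
    pruner = _as_pruner(col, gfit)
    if alt.beta_plus <= alt.alpha:
        return alt, lnl_alt

    def neg(x: np.ndarray) -> float:
        alpha, f, f2, p_plus = (float(v) for v in x)
        return _finite(-pruner.loglike_mixture(alpha, f * alpha, f2 * alpha, p_plus))

    bounds = [RATE_BOUNDS, (0.0, 1.0), (0.0, 1.0), (0.0, 1.0)]
    a = alt.alpha
    f_warm = alt.beta_minus / a if a > 0 else 0.0
    starts = [
        np.array([a, f_warm, 1.0, alt.p_plus]),  # constraint active (KKT)
        np.array([max(a, alt.beta_plus * 0.5), f_warm, 1.0, alt.p_plus]),
    ]
    best = None
    for x0 in starts:
        res = minimize(
            neg, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 120, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha, f, f2, p_plus = (float(v) for v in best.x)
    lnl_null = -float(best.fun)
    if lnl_null > lnl_alt:
        # The constrained optimum dominates: adopt it as the alternative
        # too (it is feasible there), making the LRT exactly zero.
        lnl_null = min(lnl_null, lnl_alt)
    params = MemeSiteParams(
        alpha=alpha, beta_minus=f * alpha, beta_plus=f2 * alpha, p_plus=p_plus
    )
    return params, lnl_null


def _as_pruner(col: SiteColumn | SitePruner, gfit: GlobalFit) -> SitePruner:
    if isinstance(col, SitePruner):
        return col
    return SitePruner(col, gfit.tree, gfit.kernel())


# ---------------------------------------------------------------------
# whole-alignment driver
# ---------------------------------------------------------------------


@dataclass
class SiteTestResult:
    site: int  # 1-based codon coordinate
    meme_alt: MemeSiteParams
    meme_null: MemeSiteParams
    lnl_alt: float
    lnl_null: float
    lrt: float
    p_meme: float
    q_meme: float
    fel: FelSiteResult
    q_fel: float
    p_meme_vs_fel: float
    invariant: bool


RESULT_COLUMNS = [
    "site", "alpha", "beta_minus", "p_minus", "beta_plus", "p_plus",
    "lnL_alt", "lnL_null", "LRT", "p_meme", "q_meme",
    "fel_alpha", "fel_beta", "p_fel", "fel_class", "p_meme_vs_fel",
]


def results_to_frame(results: list[SiteTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "site": r.site,
                "alpha": r.meme_alt.alpha,
                "beta_minus": r.meme_alt.beta_minus,
                "p_minus": r.meme_alt.p_minus,
                "beta_plus": r.meme_alt.beta_plus,
                "p_plus": r.meme_alt.p_plus,
                "lnL_alt": r.lnl_alt,
                "lnL_null": r.lnl_null,
                "LRT": r.lrt,
                "p_meme": r.p_meme,
                "q_meme": r.q_meme,
                "fel_alpha": r.fel.alpha,
                "fel_beta": r.fel.beta,
                "p_fel": r.fel.p,
                "fel_class": r.fel.classification,
                "p_meme_vs_fel": r.p_meme_vs_fel,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def analyze_sites(
    aln: CodonAlignment,
    gfit: GlobalFit,
    null_mixture: MixtureNull | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    sites: list[int] | None = None,
    progress: callable | None = None,
) -> list[SiteTestResult]:
    """Run MEME and FEL on every requested site of an alignment.

    Duplicate columns are fitted once and shared; invariant columns
    short-circuit to LRT = 0, p = 1. q-values are computed across the
    analyzed sites by Benjamini-Hochberg.
    """
    from .global_fit import compress_columns

    null_mixture = null_mixture or MixtureNull()
    site_idx = sites if sites is not None else list(range(aln.n_sites))
    columns = [aln.columns[s] for s in site_idx]
    patterns, _, site_of = compress_columns(columns, aln.names)
    kernel = gfit.kernel()

    pattern_cols = [dict(zip(aln.names, pat)) for pat in patterns]
    pattern_results: list[dict] = []
    for k, pcol in enumerate(pattern_cols):
        invariant = _pattern_invariant(pcol)
        pruner = SitePruner(pcol, gfit.tree, kernel)
        fel = fit_fel_site(pruner, gfit, p_threshold=p_threshold,
                           invariant=invariant)
        if invariant:
            params = MemeSiteParams(0.0, 0.0, 0.0, 0.0)
            pattern_results.append(
                dict(meme_alt=params, meme_null=params,
                     lnl_alt=fel.lnl_uncon, lnl_null=fel.lnl_uncon,
                     lrt=0.0, p_meme=1.0, fel=fel,
                     p_meme_vs_fel=1.0, invariant=True)
            )
        else:
            alt, lnl_alt = fit_meme_alternative(pruner, gfit, fel=fel)
            nul, lnl_null = fit_meme_null(pruner, gfit, alt, lnl_alt)
            lrt = max(0.0, 2.0 * (lnl_alt - lnl_null))
            pattern_results.append(
                dict(meme_alt=alt, meme_null=nul,
                     lnl_alt=lnl_alt, lnl_null=lnl_null, lrt=lrt,
                     p_meme=null_mixture.pvalue(lrt), fel=fel,
                     p_meme_vs_fel=meme_vs_fel_test(lnl_alt, fel.lnl_uncon),
                     invariant=False)
            )
        if progress is not None:
            progress(k + 1, len(pattern_cols))

    p_meme = np.array([pattern_results[site_of[i]]["p_meme"]
                       for i in range(len(site_idx))])
    p_fel = np.array([pattern_results[site_of[i]]["fel"].p
                      for i in range(len(site_idx))])
    q_meme = bh_qvalues(p_meme)
    q_fel = bh_qvalues(p_fel)
    results = []
    for i, s in enumerate(site_idx):
        pr = pattern_results[site_of[i]]
        results.append(
            SiteTestResult(
                site=s + 1,
                meme_alt=pr["meme_alt"], meme_null=pr["meme_null"],
                lnl_alt=pr["lnl_alt"], lnl_null=pr["lnl_null"],
                lrt=pr["lrt"], p_meme=pr["p_meme"], q_meme=float(q_meme[i]),
                fel=pr["fel"], q_fel=float(q_fel[i]),
                p_meme_vs_fel=pr["p_meme_vs_fel"],
                invariant=pr["invariant"],
            )
        )
    return results


def analyze_sites_fel(
    aln: CodonAlignment,
    gfit: GlobalFit,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    sites: list[int] | None = None,
) -> pd.DataFrame:
    """FEL-only scan of an alignment (no branch-site mixture fits)."""
    from .global_fit import compress_columns

    site_idx = sites if sites is not None else list(range(aln.n_sites))
    columns = [aln.columns[s] for s in site_idx]
    patterns, _, site_of = compress_columns(columns, aln.names)
    kernel = gfit.kernel()
    fits = []
    for pat in patterns:
        pcol = dict(zip(aln.names, pat))
        pruner = SitePruner(pcol, gfit.tree, kernel)
        fits.append(
            fit_fel_site(pruner, gfit, p_threshold=p_threshold,
                         invariant=_pattern_invariant(pcol))
        )
    p = np.array([fits[site_of[i]].p for i in range(len(site_idx))])
    q = bh_qvalues(p)
    return pd.DataFrame(
        {
            "site": [s + 1 for s in site_idx],
            "fel_alpha": [fits[site_of[i]].alpha for i in range(len(site_idx))],
            "fel_beta": [fits[site_of[i]].beta for i in range(len(site_idx))],
            "LRT": [fits[site_of[i]].lrt for i in range(len(site_idx))],
            "p_fel": p,
            "q_fel": q,
            "fel_class": [
                fits[site_of[i]].classification for i in range(len(site_idx))
            ],
        }
    )


def _pattern_invariant(col: dict) -> bool:
    shared = None
    for states in col.values():
        shared = states if shared is None else shared & states
        if not shared:
            return False
    singles = [s for s in col.values() if len(s) == 1]
    return bool(shared) and all(next(iter(s)) in shared for s in singles)
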