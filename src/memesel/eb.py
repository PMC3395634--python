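"""Empirical-Bayes identification of branches under selection at a site.

Given the alternative MEME fit at a site, the posterior probability that
branch b drew the unrestricted rate beta_plus is obtained from Bayes'
theorem using two constrained pruning passes: one with branch b forced
to the pure beta_plus transition matrix and one forced to beta_minus,
with every other branch keeping its fitted mixture matrix. The
empirical Bayes factor (posterior odds over prior odds) summarizes how
much the data at that single branch-site pair move the prior p_plus.

This evidence rests on a single realization of the substitution process
(one codon along one branch) and is exploratory only; it carries no
error-rate control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .global_fit import GlobalFit
from .likelihood import SiteColumn, SitePruner
from .site_tests import MemeSiteParams

DEFAULT_EBF_THRESHOLD = 20.0


@dataclass
class BranchSelectionEvidence:
    branch_id: int
    branch_name: str
    posterior: float  # Pr(beta_plus | data, site MLEs)
    prior: float      # fitted p_plus
    ebf: float | None  # None when prior or posterior is degenerate

    @property
    def ebf_defined(self) -> bool:
        return self.ebf is not None


def branch_posteriors(
    col: SiteColumn | SitePruner,
    gfit: GlobalFit,
    alt: MemeSiteParams,
) -> list[BranchSelectionEvidence]:
    """Per-branch posterior Pr(beta_plus | data) and empirical Bayes factor.

    Non-focal branches keep the mixture matrices of the alternative fit;
    no per-branch re-optimization is performed (O(B) pruning passes).
    """
    pruner = (
        col
        if isinstance(col, SitePruner)
        else SitePruner(col, gfit.tree, gfit.kernel())
    )
    p_plus = alt.p_plus
    out: list[BranchSelectionEvidence] = []
    for b in pruner.tree.branches:
        if p_plus <= 0.0 or p_plus >= 1.0:
            out.append(
                BranchSelectionEvidence(b.id, b.name, p_plus, p_plus, None)
            )
            continue
        lnl_plus = pruner.loglike_focal_branch(
            alt.alpha, alt.beta_minus, alt.beta_plus, p_plus, b.id, alt.beta_plus
        )
        lnl_minus = pruner.loglike_focal_branch(
            alt.alpha, alt.beta_minus, alt.beta_plus, p_plus, b.id, alt.beta_minus
        )
        # posterior = p+ L+ / (p+ L+ + p- L-), computed in log space
        la = np.log(p_plus) + lnl_plus
        lb = np.log1p(-p_plus) + lnl_minus
        m = max(la, lb)
        posterior = float(np.exp(la - m) / (np.exp(la - m) + np.exp(lb - m)))
        if posterior <= 0.0 or posterior >= 1.0:
            ebf = None
        else:
            ebf = float(
                (posterior / (1.0 - posterior)) / (p_plus / (1.0 - p_plus))
            )
        out.append(
            BranchSelectionEvidence(b.id, b.name, posterior, p_plus, ebf)
        )
    return out


def flag_selected_branches(
    evidence: list[BranchSelectionEvidence],
    site_p: float,
    ebf_threshold: float = DEFAULT_EBF_THRESHOLD,
    p_threshold: float = 0.05,
) -> list[BranchSelectionEvidence]:
    """Branches with EBF >= threshold at a MEME-significant site.

    Returns the empty list when the site's p-value exceeds the threshold.
    Exploratory output only — see the module docstring.
    """
    if site_p > p_threshold:
        return []
    return [
        e for e in evidence if e.ebf is not None and e.ebf >= ebf_threshold
    ]


def evidence_to_json_dict(
    evidence_by_site: dict[int, list[BranchSelectionEvidence]],
) -> dict:
    """site -> branch -> {posterior, ebf} mapping for JSON output."""
    return {
        str(site): {
            e.branch_name: {
                "posterior": e.posterior,
                "ebf": e.ebf,
                "ebf_defined": e.ebf_defined,
            }
            for e in ev
        }
        for site, ev in evidence_by_site.items()
    }
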