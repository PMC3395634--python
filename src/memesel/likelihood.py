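"""Felsenstein pruning with per-branch mixtures of transition matrices.

The branch-site random effects model treats the nonsynonymous rate on
each branch as an independent draw from a small set of categories.
Marginalizing the site likelihood over all ``c^B`` joint category
assignments is equivalent to running the ordinary pruning algorithm with
each branch's transition matrix replaced by the category-weighted mixture

    P_b(t_b) = sum_k p_k exp(Q(alpha, beta_k) t_b).

``brute_force_mixture_likelihood`` performs the explicit ``c^B``
enumeration and serves as the independent correctness oracle for the
mixture-pruning path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .phylo import Phylogeny
from .rate_matrix import CodonModelKernel

RESCALE_THRESHOLD = 1e-100

#: A site column: mapping leaf name -> frozenset of compatible state indices.
SiteColumn = dict


@dataclass
class CategoryMixture:
    """Rate categories (alpha_k, beta_k) with weights p_k summing to one."""

    categories: list[tuple[float, float]]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.categories) < 1 or len(self.categories) != len(self.weights):
            raise ValueError("need >= 1 category with matching weights")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be nonnegative and sum to 1")


def branch_mixture_matrix(
    mix: CategoryMixture, kernel: CodonModelKernel, t: float
) -> np.ndarray:
    """Category-weighted mixture transition matrix for one branch."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    p = np.zeros((kernel.code.n_states,) * 2)
    for (alpha, beta), w in zip(mix.categories, mix.weights):
        if w > 0:
            p += w * kernel.transition_matrix(alpha, beta, t)
    return p


def leaf_state_vector(states: frozenset, n_states: int) -> np.ndarray:
    v = np.zeros(n_states)
    if states:
        v[list(states)] = 1.0
    return v


def site_log_likelihood(
    col: SiteColumn,
    tree: Phylogeny,
    matrices: list[np.ndarray],
    root_freqs: np.ndarray,
) -> float:
    """Pruning log-likelihood of one column given per-branch matrices.

    ``matrices[b]`` is the transition matrix for branch id ``b`` (pure or
    mixture). Underflow is handled by per-node rescaling accumulated in
    log space; a column of probability zero returns ``-inf``.
    """
    n = len(root_freqs)
    partial: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for v in tree.postorder:
        if tree.is_leaf[v]:
            partial[v] = leaf_state_vector(col[tree.names[v]], n)
        else:
            acc = np.ones(n)
            for c in tree.children[v]:
                b = tree.branch_of_child(c)
                acc = acc * (matrices[b.id] @ partial[c])
            m = acc.max()
            if 0.0 < m < RESCALE_THRESHOLD:
                acc = acc / m
                log_scale += np.log(m)
            partial[v] = acc
    lik = float(root_freqs @ partial[tree.root])
    if lik <= 0.0:
        return -np.inf
    return float(np.log(lik) + log_scale)


def brute_force_mixture_likelihood(
    col: SiteColumn,
    tree: Phylogeny,
    mix: CategoryMixture,
    kernel: CodonModelKernel,
    guard: int = 10**6,
) -> float:
    """Explicit marginalization over all ``c^B`` branch-category vectors.

    Exponential-time oracle for :func:`site_log_likelihood` run with
    :func:`branch_mixture_matrix` inputs; guarded against instances with
    more than ``guard`` configurations.
    """
    c = len(mix.categories)
    B = tree.n_branches
    if c**B > guard:
        raise ValueError(
            f"{c}^{B} configurations exceed the {guard} guard; "
            "shrink the tree or category count"
        )
    times = [b.length for b in tree.branches]
    pure = [
        [kernel.transition_matrix(alpha, beta, t) for (alpha, beta) in mix.categories]
        for t in times
    ]
    total = 0.0
    log_offset = None
    for config in itertools.product(range(c), repeat=B):
        w = float(np.prod([mix.weights[k] for k in config]))
        if w == 0.0:
            continue
        mats = [pure[b][k] for b, k in enumerate(config)]
        lnl = site_log_likelihood(col, tree, mats, kernel.pi)
        if lnl == -np.inf:
            continue
        if log_offset is None:
            log_offset = lnl
        total += w * np.exp(lnl - log_offset)
    if log_offset is None or total <= 0:
        return -np.inf
    return float(np.log(total) + log_offset)


class SitePruner:
    """Fast repeated evaluation of one column under two-category mixtures.

    The hot path of the per-site fits. Rather than materializing a full
    transition matrix per branch per call, messages are propagated in the
    spectral basis of the (cached) symmetric eigendecomposition:
    ``P(t) @ v = A (e^{lam t} * (B v))``, with all leaf-branch messages of
    one category computed in a single matrix product.
    """

    def __init__(self, col: SiteColumn, tree: Phylogeny, kernel: CodonModelKernel):
        if not tree.has_all_lengths():
            raise ValueError("tree must have branch lengths for likelihood use")
        self.tree = tree
        self.kernel = kernel
        n = kernel.code.n_states
        self.times = np.array([b.length for b in tree.branches])
        self.leaf_vec = {
            v: leaf_state_vector(col[tree.names[v]], n)
            for v in tree.postorder
            if tree.is_leaf[v]
        }
        leaf_branches = [b for b in tree.branches if tree.is_leaf[b.child]]
        self._leaf_times = np.array([b.length for b in leaf_branches])
        self._leaf_col = {b.id: k for k, b in enumerate(leaf_branches)}
        self._vleaf = np.column_stack(
            [self.leaf_vec[b.child] for b in leaf_branches]
        )
        self._proj_cache: dict[int, np.ndarray] = {}

    # ---- spectral message machinery -----------------------------------

    def _parts(self, specs) -> list:
        """Resolve (weight, alpha, beta) category specs to spectral parts."""
        parts = []
        for w, a, b in specs:
            if w <= 0.0:
                continue
            dec = self.kernel._decomposition(a, b)
            if dec is None:
                parts.append((w, None))
            else:
                (lam, amat, bmat, token), s = dec
                parts.append((w, (lam, amat, bmat, token, s * self.kernel.scale)))
        return parts

    def _leaf_projection(self, token: int, bmat: np.ndarray) -> np.ndarray:
        u = self._proj_cache.get(token)
        if u is None:
            u = bmat @ self._vleaf
            if len(self._proj_cache) > 1024:
                self._proj_cache.clear()
            self._proj_cache[token] = u
        return u

    def _loglike_parts(self, parts, overrides: dict | None = None) -> float:
        """Pruning lnL where every branch uses the mixture defined by
        ``parts``; branches in ``overrides`` use their own part lists."""
        tree = self.tree
        # Batched leaf-branch messages, summed over mixture parts.
        leaf_msgs = None
        exps = []  # per part: e^{lam * t_b} for every branch, or None
        for w, p in parts:
            if p is None:
                m = w * self._vleaf
                exps.append(None)
            else:
                lam, amat, bmat, token, mult = p
                u = self._leaf_projection(token, bmat)
                wl = np.exp(np.outer(lam, self._leaf_times * mult))
                m = w * (amat @ (wl * u))
                exps.append(np.exp(np.outer(lam, self.times * mult)))
            leaf_msgs = m if leaf_msgs is None else leaf_msgs + m

        def branch_message(bid: int, vec: np.ndarray, use_parts, use_exps):
            msg = None
            for (w, p), ex in zip(use_parts, use_exps):
                if p is None:
                    contrib = w * vec
                else:
                    lam, amat, bmat, token, mult = p
                    if ex is not None:
                        e = ex[:, bid]
                    else:
                        e = np.exp(lam * (self.times[bid] * mult))
                    contrib = w * (amat @ (e * (bmat @ vec)))
                msg = contrib if msg is None else msg + contrib
            return msg

        partial: dict[int, np.ndarray] = {}
        log_scale = 0.0
        for v in tree.postorder:
            if tree.is_leaf[v]:
                continue
            acc = None
            for c in tree.children[v]:
                b = tree.branch_of_child(c)
                if overrides is not None and b.id in overrides:
                    ov = self._parts(overrides[b.id])
                    vec = self.leaf_vec[c] if tree.is_leaf[c] else partial[c]
                    msg = branch_message(b.id, vec, ov, [None] * len(ov))
                elif tree.is_leaf[c]:
                    msg = leaf_msgs[:, self._leaf_col[b.id]]
                else:
                    msg = branch_message(b.id, partial[c], parts, exps)
                acc = msg if acc is None else acc * msg
            m = acc.max()
            if 0.0 < m < RESCALE_THRESHOLD:
                acc = acc / m
                log_scale += np.log(m)
            partial[v] = acc
        lik = float(self.kernel.pi @ partial[tree.root])
        if lik <= 0.0:
            return -np.inf
        return float(np.log(lik) + log_scale)

    # ---- public evaluation API ----------------------------------------

    def loglike_single(self, alpha: float, beta: float) -> float:
        """lnL under a single (alpha, beta) pair on every branch (FEL)."""
        return self._loglike_parts(self._parts([(1.0, alpha, beta)]))

    def loglike_mixture(
        self,
        alpha: float,
        beta_minus: float,
        beta_plus: float,
        p_plus: float,
    ) -> float:
        """lnL under the two-category branch-site mixture."""
        return self._loglike_parts(
            self._parts(
                [(1.0 - p_plus, alpha, beta_minus), (p_plus, alpha, beta_plus)]
            )
        )

    def loglike_focal_branch(
        self,
        alpha: float,
        beta_minus: float,
        beta_plus: float,
        p_plus: float,
        focal_branch: int,
        focal_beta: float,
    ) -> float:
        """lnL with one branch forced to a pure (alpha, focal_beta) matrix
        while all others keep their mixture matrices (empirical Bayes
        conditioning)."""
        parts = self._parts(
            [(1.0 - p_plus, alpha, beta_minus), (p_plus, alpha, beta_plus)]
        )
        return self._loglike_parts(
            parts, overrides={focal_branch: [(1.0, alpha, focal_beta)]}
        )
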