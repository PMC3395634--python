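"""Alignment-wide (stage 1) fit of the MG94xGTR nuisance parameters.

Site tests condition on shared quantities estimated once per alignment:
branch lengths, GTR exchangeabilities, CF3x4 frequency parameters, and a
single alignment-wide omega. Branch lengths are measured in expected
substitutions per codon site at the global MLEs; the normalization
constant achieving this (``scale``) is frozen and reused by every
site-level matrix, so per-site alpha/beta are relative multipliers on a
globally calibrated tree.

Optimization alternates one-dimensional branch-length passes (Brent per
branch, using inside-outside partial caching so each branch costs a
single small matrix product per trial length) with bounded quasi-Newton
passes over (theta, omega). The codon fit is initialized from a GTR
nucleotide fit, whose branch lengths are multiplied by three and then
re-estimated — nucleotide models can substantially underestimate codon
branch lengths, so they serve only as starting values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment import CodonAlignment
from .frequencies import (
    FrequencyModel,
    estimate_cf3x4,
)
from .genetic_code import GeneticCode, get_genetic_code
from .phylo import Phylogeny, parse_newick, validate_tree_alignment
from .rate_matrix import (
    CodonModelKernel,
    GTRKernel,
    NucleotideExchangeabilities,
)

BRANCH_LENGTH_BOUNDS = (0.0, 25.0)
OMEGA_BOUNDS = (1e-8, 100.0)
RESCALE = 1e-120


# ---------------------------------------------------------------------
# pattern compression and multi-pattern pruning
# ---------------------------------------------------------------------


def compress_columns(
    columns: list[dict[str, frozenset[int]]], names: list[str]
) -> tuple[list[tuple], np.ndarray, np.ndarray]:
    """Unique site patterns, their counts, and the site -> pattern map."""
    seen: dict[tuple, int] = {}
    counts: list[int] = []
    site_of: list[int] = []
    patterns: list[tuple] = []
    for col in columns:
        key = tuple(col[n] for n in names)
        idx = seen.get(key)
        if idx is None:
            idx = len(patterns)
            seen[key] = idx
            patterns.append(key)
            counts.append(0)
        counts[idx] += 1
        site_of.append(idx)
    return patterns, np.asarray(counts, dtype=float), np.asarray(site_of)


def leaf_pattern_matrices(
    patterns: list[tuple], names: list[str], tree: Phylogeny, n_states: int
) -> dict[int, np.ndarray]:
    """Per-leaf (n_patterns, n_states) indicator matrices."""
    name_pos = {n: i for i, n in enumerate(names)}
    mats: dict[int, np.ndarray] = {}
    for v in tree.postorder:
        if not tree.is_leaf[v]:
            continue
        k = name_pos[tree.names[v]]
        m = np.zeros((len(patterns), n_states))
        for p, pat in enumerate(patterns):
            m[p, list(pat[k])] = 1.0
        mats[v] = m
    return mats


class AlignmentPruner:
    """Pruning over all site patterns at once, with inside-outside caching.

    ``pstack`` arguments are (n_branches, n, n) transition-matrix stacks
    indexed by branch id.
    """

    def __init__(
        self,
        tree: Phylogeny,
        leaf_mats: dict[int, np.ndarray],
        counts: np.ndarray,
        n_states: int,
    ) -> None:
        self.tree = tree
        self.leaf_mats = leaf_mats
        self.counts = counts
        self.n_states = n_states
        self.n_patterns = len(counts)

    def _downpass(self, pstack: np.ndarray):
        tree = self.tree
        down: dict[int, np.ndarray] = {}
        dscale: dict[int, np.ndarray] = {}
        zeros = np.zeros(self.n_patterns)
        for v in tree.postorder:
            if tree.is_leaf[v]:
                down[v] = self.leaf_mats[v]
                dscale[v] = zeros
                continue
            acc = None
            sc = np.zeros(self.n_patterns)
            for c in tree.children[v]:
                b = tree.branch_of_child(c)
                msg = down[c] @ pstack[b.id].T
                acc = msg if acc is None else acc * msg
                sc += dscale[c]
            m = acc.max(axis=1)
            small = (m > 0) & (m < RESCALE)
            if small.any():
                acc = acc.copy()
                acc[small] /= m[small, None]
                sc = sc + np.where(small, np.log(np.where(small, m, 1.0)), 0.0)
            down[v] = acc
            dscale[v] = sc
        return down, dscale

    def loglike(self, pstack: np.ndarray, root_freqs: np.ndarray) -> float:
        down, dscale = self._downpass(pstack)
        lik = down[self.tree.root] @ root_freqs
        if np.any(lik <= 0):
            return -np.inf
        return float(self.counts @ (np.log(lik) + dscale[self.tree.root]))

    def site_loglikes(self, pstack: np.ndarray, root_freqs: np.ndarray) -> np.ndarray:
        """Per-pattern log-likelihood vector."""
        down, dscale = self._downpass(pstack)
        lik = down[self.tree.root] @ root_freqs
        with np.errstate(divide="ignore"):
            return np.log(lik) + dscale[self.tree.root]

    def branch_contexts(self, pstack: np.ndarray, root_freqs: np.ndarray):
        """Inside-outside decomposition for per-branch length optimization.

        For each branch b = (parent u -> child c), produces ``G_b`` such
        that the pattern likelihood equals ``sum_ij G_b[i] P_b(t)[i, j]
        down_c[j]`` (times exp of the stored log-scalers), with every
        quantity other than ``P_b(t)`` held fixed.
        """
        tree = self.tree
        down, dscale = self._downpass(pstack)
        up: dict[int, np.ndarray] = {}
        uscale: dict[int, np.ndarray] = {}
        up[tree.root] = np.broadcast_to(
            root_freqs, (self.n_patterns, self.n_states)
        )
        uscale[tree.root] = np.zeros(self.n_patterns)
        contexts: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for v in reversed(tree.postorder):
            if tree.is_leaf[v]:
                continue
            kids = tree.children[v]
            msgs = []
            scs = []
            for c in kids:
                b = tree.branch_of_child(c)
                msgs.append(down[c] @ pstack[b.id].T)
                scs.append(dscale[c])
            k = len(kids)
            prefix = [None] * (k + 1)
            prefix[0] = (np.ones((self.n_patterns, self.n_states)),
                         np.zeros(self.n_patterns))
            for i in range(k):
                prefix[i + 1] = (prefix[i][0] * msgs[i], prefix[i][1] + scs[i])
            suffix = [None] * (k + 1)
            suffix[k] = (np.ones((self.n_patterns, self.n_states)),
                         np.zeros(self.n_patterns))
            for i in range(k - 1, -1, -1):
                suffix[i] = (suffix[i + 1][0] * msgs[i], suffix[i + 1][1] + scs[i])
            for i, c in enumerate(kids):
                b = tree.branch_of_child(c)
                sib = prefix[i][0] * suffix[i + 1][0]
                sib_sc = prefix[i][1] + suffix[i + 1][1]
                g = up[v] * sib
                gs = uscale[v] + sib_sc
                m = g.max(axis=1)
                small = (m > 0) & (m < RESCALE)
                if small.any():
                    g = g.copy()
                    g[small] /= m[small, None]
                    gs = gs + np.where(small, np.log(np.where(small, m, 1.0)), 0.0)
                contexts[b.id] = (g, gs)
                up[c] = g @ pstack[b.id]
                uscale[c] = gs
        return down, dscale, contexts

    def branch_loglike(
        self,
        branch_id: int,
        p: np.ndarray,
        down: dict,
        dscale: dict,
        contexts: dict,
    ) -> float:
        """lnL as a function of one branch's transition matrix."""
        b = self.tree.branches[branch_id]
        g, gs = contexts[branch_id]
        lik = np.sum((g @ p) * down[b.child], axis=1)
        if np.any(lik <= 0):
            return -np.inf
        return float(self.counts @ (np.log(lik) + gs + dscale[b.child]))


# ---------------------------------------------------------------------
# nucleotide GTR initialization fit
# ---------------------------------------------------------------------


@dataclass
class GtrFit:
    theta: NucleotideExchangeabilities
    base_freqs: np.ndarray
    branch_lengths: np.ndarray
    lnL: float


def _nucleotide_columns(aln: CodonAlignment) -> list[dict[str, frozenset[int]]]:
    """Project codon ambiguity sets to per-position nucleotide sets."""
    from .genetic_code import NUC_INDEX

    sense = aln.code.sense_codons
    cols: list[dict[str, frozenset[int]]] = []
    for col in aln.columns:
        per_pos: list[dict[str, frozenset[int]]] = [{}, {}, {}]
        for name, states in col.items():
            for k in range(3):
                per_pos[k][name] = frozenset(
                    NUC_INDEX[sense[s][k]] for s in states
                )
        cols.extend(per_pos)
    return cols


def empirical_base_frequencies(aln: CodonAlignment) -> np.ndarray:
    counts = np.zeros(4)
    for col in _nucleotide_columns(aln):
        for states in col.values():
            if len(states) == 1:
                counts[next(iter(states))] += 1
    if counts.sum() == 0:
        raise ValueError("alignment contains no unambiguous nucleotides")
    return counts / counts.sum()


def _branch_length_pass(
    pruner: AlignmentPruner,
    times: np.ndarray,
    pstack_fn,
    matrix_fn,
    root_freqs: np.ndarray,
    current_lnl: float,
) -> tuple[np.ndarray, float]:
    """One Jacobi-style sweep of per-branch Brent optimizations.

    Contexts are computed once at the sweep's starting lengths; each
    branch is optimized against them, and the joint update is accepted
    only if it improves the full lnL (with step-halving fallback).
    """
    pstack = pstack_fn(times)
    down, dscale, contexts = pruner.branch_contexts(pstack, root_freqs)
    new_times = times.copy()
    for b in range(pruner.tree.n_branches):
        def neg(t: float, b=b) -> float:
            return -pruner.branch_loglike(b, matrix_fn(t), down, dscale, contexts)

        res = minimize_scalar(
            neg, bounds=BRANCH_LENGTH_BOUNDS, method="bounded",
            options={"xatol": 1e-7},
        )
        cand = float(res.x)
        if neg(cand) <= neg(times[b]):
            new_times[b] = cand
    for _ in range(4):
        lnl = pruner.loglike(pstack_fn(new_times), root_freqs)
        if lnl >= current_lnl:
            return new_times, lnl
        new_times = (new_times + times) / 2  # step halving safeguard
    return times, current_lnl


def fit_nucleotide_gtr(
    aln: CodonAlignment,
    tree: Phylogeny,
    tol: float = 1e-8,
    max_sweeps: int = 30,
) -> GtrFit:
    """ML fit of the GTR nucleotide model on the nucleotide-ized alignment.

    Used to initialize the codon fit; exchangeabilities are identified by
    theta(A, G) = 1 and base frequencies are empirical.
    """
    if aln.n_sequences < 3:
        warnings.warn("fewer than 3 sequences: GTR fit is weakly identified")
    report = validate_tree_alignment(tree, aln)
    if not report.ok:
        raise ValueError(f"tree/alignment name mismatch: {report}")
    columns = _nucleotide_columns(aln)
    patterns, counts, _ = compress_columns(columns, aln.names)
    leaf_mats = leaf_pattern_matrices(patterns, aln.names, tree, 4)
    pruner = AlignmentPruner(tree, leaf_mats, counts, 4)
    pi = empirical_base_frequencies(aln)

    times = np.array(
        [b.length if b.length is not None else 0.1 for b in tree.branches]
    )
    times = np.clip(times, 1e-6, BRANCH_LENGTH_BOUNDS[1])
    theta_free = np.ones(5)

    def make_kernel(free: np.ndarray) -> GTRKernel:
        return GTRKernel(NucleotideExchangeabilities.from_vector(free), pi)

    kernel = make_kernel(theta_free)
    lnl = pruner.loglike(kernel.transition_stack(times), pi)
    for _ in range(max_sweeps):
        prev = lnl
        kernel = make_kernel(theta_free)
        times, lnl = _branch_length_pass(
            pruner, times, kernel.transition_stack,
            lambda t: kernel.transition_stack(np.array([t]))[0], pi, lnl,
        )

        def neg_theta(logfree: np.ndarray) -> float:
            k = make_kernel(np.exp(logfree))
            return -pruner.loglike(k.transition_stack(times), pi)

        res = minimize(
            neg_theta, np.log(np.clip(theta_free, 1e-6, None)),
            method="L-BFGS-B",
            bounds=[(np.log(1e-5), np.log(100.0))] * 5,
            options={"maxiter": 40},
        )
        if -res.fun >= lnl:
            theta_free = np.exp(res.x)
            lnl = -res.fun
        if lnl - prev < tol:
            break
    if float(np.max(times)) < 1e-5:
        warnings.warn("all fitted branch lengths are ~0 (identical sequences?)")
    return GtrFit(
        theta=NucleotideExchangeabilities.from_vector(theta_free),
        base_freqs=pi,
        branch_lengths=times,
        lnL=float(lnl),
    )


# ---------------------------------------------------------------------
# global MG94xGTR codon fit
# ---------------------------------------------------------------------


@dataclass
class GlobalFit:
    """Shared nuisance parameters conditioning all site tests."""

    theta: NucleotideExchangeabilities
    freqs: FrequencyModel
    omega_global: float
    tree: Phylogeny  # carries the fitted branch lengths
    scale: float
    lnL: float
    code: GeneticCode

    @property
    def branch_lengths(self) -> dict[str, float]:
        return {b.name: b.length for b in self.tree.branches}

    def kernel(self) -> CodonModelKernel:
        return CodonModelKernel(self.code, self.theta, self.freqs, self.scale)

    def to_json(self) -> str:
        return json.dumps(
            {
                "theta": self.theta.as_dict(),
                "pos_freqs": self.freqs.pos_freqs.tolist(),
                "omega_global": self.omega_global,
                "newick": self.tree.to_newick(digits=12),
                "scale": self.scale,
                "lnL": self.lnL,
                "code_table": self.code.table_id,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GlobalFit":
        d = json.loads(text)
        th = d["theta"]
        return cls(
            theta=NucleotideExchangeabilities(
                ac=th["AC"], ag=th["AG"], at=th["AT"],
                cg=th["CG"], ct=th["CT"], gt=th["GT"],
            ),
            freqs=FrequencyModel(np.array(d["pos_freqs"]), corrected=True),
            omega_global=d["omega_global"],
            tree=parse_newick(d["newick"]),
            scale=d["scale"],
            lnL=d["lnL"],
            code=get_genetic_code(d["code_table"]),
        )


def observed_codon_position_frequencies(aln: CodonAlignment) -> FrequencyModel:
    """Raw position-specific frequencies counted from unambiguous bases."""
    from .genetic_code import NUC_INDEX  # local import to avoid cycle noise

    sense = aln.code.sense_codons
    counts = np.zeros((3, 4))
    for col in aln.columns:
        for states in col.values():
            for k in range(3):
                bases = {sense[s][k] for s in states}
                if len(bases) == 1:
                    counts[k, NUC_INDEX[next(iter(bases))]] += 1
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("no unambiguous nucleotides at some codon position")
    return FrequencyModel(counts / counts.sum(axis=1, keepdims=True))


def fit_global_mg94(
    aln: CodonAlignment,
    tree: Phylogeny,
    init: GtrFit | None = None,
    tol: float = 1e-8,
    max_sweeps: int = 12,
) -> GlobalFit:
    """Joint ML fit of branch lengths, theta, and an alignment-wide omega.

    Frequencies are fixed at CF3x4 estimates from the observed counts
    rather than optimized (nine extra free dimensions for negligible
    gain). On return ``scale`` makes the mean substitution rate per codon
    site equal one at the MLEs.
    """
    report = validate_tree_alignment(tree, aln)
    if not report.ok:
        raise ValueError(f"tree/alignment name mismatch: {report}")
    code = aln.code
    if init is None:
        init = fit_nucleotide_gtr(aln, tree)
    freqs = estimate_cf3x4(observed_codon_position_frequencies(aln), code)

    patterns, counts, _ = compress_columns(aln.columns, aln.names)
    leaf_mats = leaf_pattern_matrices(patterns, aln.names, tree, code.n_states)
    pruner = AlignmentPruner(tree, leaf_mats, counts, code.n_states)

    # Nucleotide branch lengths underestimate codon lengths; x3 maps
    # substitutions/nucleotide-site to substitutions/codon-site as a
    # starting point, then lengths are re-optimized.
    times = np.clip(3.0 * init.branch_lengths, 1e-6, BRANCH_LENGTH_BOUNDS[1])
    theta_free = init.theta.free_vector()

    def kernel_for(free: np.ndarray) -> CodonModelKernel:
        return CodonModelKernel(
            code, NucleotideExchangeabilities.from_vector(free), freqs, 1.0
        )

    def normalized_rates(kernel: CodonModelKernel, omega: float):
        m = kernel.mean_rate(1.0, omega)
        return 1.0 / m, omega / m

    def loglike(kernel: CodonModelKernel, omega: float, t: np.ndarray) -> float:
        a, b = normalized_rates(kernel, omega)
        return pruner.loglike(kernel.transition_stack(a, b, t), kernel.pi)

    kernel = kernel_for(theta_free)

    # Multi-start on omega, holding the GTR-derived lengths fixed: seed a
    # bounded 1-d search from several starting ratios and keep the best.
    grid = (0.02, 0.1, 0.5, 1.0, 1.5, 4.0, 15.0)
    grid_lnl = [loglike(kernel, w, times) for w in grid]
    k_best = int(np.argmax(grid_lnl))
    lo = grid[max(0, k_best - 1)] / 2
    hi = grid[min(len(grid) - 1, k_best + 1)] * 2
    res = minimize_scalar(
        lambda lw: -loglike(kernel, float(np.exp(lw)), times),
        bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-7},
    )
    omega = float(np.clip(np.exp(res.x), *OMEGA_BOUNDS))
    lnl = max(-res.fun, max(grid_lnl))
    if -res.fun < max(grid_lnl):
        omega = grid[k_best]

    for _ in range(max_sweeps):
        prev = lnl
        kernel = kernel_for(theta_free)
        a, b = normalized_rates(kernel, omega)
        times, lnl = _branch_length_pass(
            pruner,
            times,
            lambda t: kernel.transition_stack(a, b, t),
            lambda t1: kernel.transition_stack(a, b, np.array([t1]))[0],
            kernel.pi,
            lnl,
        )

        def neg_params(x: np.ndarray) -> float:
            k = kernel_for(np.exp(x[:5]))
            return -loglike(k, float(np.exp(x[5])), times)

        x0 = np.log(np.concatenate([np.clip(theta_free, 1e-6, None), [omega]]))
        res = minimize(
            neg_params, x0, method="L-BFGS-B",
            bounds=[(np.log(1e-5), np.log(100.0))] * 5
            + [(np.log(OMEGA_BOUNDS[0]), np.log(OMEGA_BOUNDS[1]))],
            options={"maxiter": 25},
        )
        if -res.fun >= lnl:
            theta_free = np.exp(res.x[:5])
            omega = float(np.exp(res.x[5]))
            lnl = -res.fun
        if lnl - prev < tol:
            break

    kernel = kernel_for(theta_free)
    scale = 1.0 / kernel.mean_rate(1.0, omega)
    total_length = float(np.sum(times))
    if total_length < 1e-4:
        warnings.warn(
            "near-zero total tree length: site tests will have no power"
        )
    return GlobalFit(
        theta=NucleotideExchangeabilities.from_vector(theta_free),
        freqs=freqs,
        omega_global=omega,
        tree=tree.with_branch_lengths(times),
        scale=scale,
        lnL=float(lnl),
        code=code,
    )
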