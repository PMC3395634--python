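"""MG94xGTR codon rate matrices and their transition probabilities.

The instantaneous rate of substituting sense codon ``i`` with ``j`` is
nonzero only for single-nucleotide changes. For a change at codon position
``k`` replacing nucleotide ``x`` with ``y``::

    q_ij = scale * r * theta(x, y) * F_k[y]

where ``r`` is the synonymous rate ``alpha`` when the codons encode the
same amino acid and the nonsynonymous rate ``beta`` otherwise, ``theta``
are the symmetric GTR nucleotide exchangeabilities, and ``F_k`` the
position-specific target-nucleotide frequencies. The chain is reversible
with respect to the product-form equilibrium over sense codons, so the
matrix exponential is computed through a symmetric eigendecomposition
(Q is similar to a symmetric matrix under the sqrt-pi scaling); the
decomposition depends only on the direction of (alpha, beta), which lets
one decomposition serve every branch length and every overall rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .frequencies import FrequencyModel, equilibrium_codon_frequencies
from .genetic_code import NUC_INDEX, GeneticCode, codon_nucleotide_diffs

NUC_PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass(frozen=True)
class NucleotideExchangeabilities:
    """Symmetric GTR exchangeability multipliers over unordered base pairs.

    Identified by fixing theta(A, G) = 1, leaving five free parameters.
    """

    ac: float = 1.0
    ag: float = 1.0
    at: float = 1.0
    cg: float = 1.0
    ct: float = 1.0
    gt: float = 1.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.as_dict().values()):
            raise ValueError("exchangeabilities must be nonnegative")

    def as_dict(self) -> dict[str, float]:
        return {"AC": self.ac, "AG": self.ag, "AT": self.at,
                "CG": self.cg, "CT": self.ct, "GT": self.gt}

    def __call__(self, x: str, y: str) -> float:
        key = "".join(sorted((x, y)))
        return self.as_dict()[key]

    @classmethod
    def from_vector(cls, v) -> "NucleotideExchangeabilities":
        """Build from (AC, AT, CG, CT, GT) with AG fixed at 1."""
        ac, at, cg, ct, gt = (float(x) for x in v)
        return cls(ac=ac, ag=1.0, at=at, cg=cg, ct=ct, gt=gt)

    def free_vector(self) -> np.ndarray:
        return np.array([self.ac, self.at, self.cg, self.ct, self.gt])


@dataclass
class CodonRateMatrix:
    """A concrete MG94xGTR generator over sense codons."""

    q: np.ndarray
    alpha: float
    beta: float
    scale: float
    pi: np.ndarray

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.scale <= 0:
            raise ValueError("alpha, beta must be >= 0 and scale > 0")


_CHANGE_TABLE_CACHE: dict[int, dict[str, np.ndarray]] = {}


def single_nt_change_table(code: GeneticCode) -> dict[str, np.ndarray]:
    """Index arrays describing every single-nucleotide codon change.

    Cached per genetic code; used to rebuild rate matrices quickly when
    exchangeabilities change during optimization.
    """
    tab = _CHANGE_TABLE_CACHE.get(code.table_id)
    if tab is not None:
        return tab
    pair_index = {p: k for k, p in enumerate(NUC_PAIRS)}
    rows, cols, pairs, poss, targets, syn = [], [], [], [], [], []
    for i, ci in enumerate(code.sense_codons):
        for j, cj in enumerate(code.sense_codons):
            if i == j:
                continue
            diffs = codon_nucleotide_diffs(ci, cj)
            if len(diffs) != 1:
                continue
            k, x, y = diffs[0]
            rows.append(i)
            cols.append(j)
            pairs.append(pair_index["".join(sorted((x, y)))])
            poss.append(k)
            targets.append(NUC_INDEX[y])
            syn.append(code.synonymous(ci, cj))
    tab = {
        "i": np.array(rows), "j": np.array(cols),
        "pair": np.array(pairs), "pos": np.array(poss),
        "target": np.array(targets), "syn": np.array(syn, dtype=bool),
    }
    _CHANGE_TABLE_CACHE[code.table_id] = tab
    return tab


def _structural_matrices(
    code: GeneticCode, theta: NucleotideExchangeabilities, freqs: FrequencyModel
) -> tuple[np.ndarray, np.ndarray]:
    """Off-diagonal synonymous and nonsynonymous rate skeletons.

    Entries hold ``theta(x,y) * F_k[y]`` for single-nucleotide changes,
    split by whether the change is synonymous; multi-nucleotide entries
    are zero.
    """
    n = code.n_states
    tab = single_nt_change_table(code)
    theta_vec = np.array([theta.as_dict()[p] for p in NUC_PAIRS])
    vals = theta_vec[tab["pair"]] * freqs.pos_freqs[tab["pos"], tab["target"]]
    syn = np.zeros((n, n))
    nonsyn = np.zeros((n, n))
    s = tab["syn"]
    syn[tab["i"][s], tab["j"][s]] = vals[s]
    nonsyn[tab["i"][~s], tab["j"][~s]] = vals[~s]
    return syn, nonsyn


class CodonModelKernel:
    """Precomputed structure for one (code, theta, freqs, scale) setting.

    Builds rate matrices ``Q(alpha, beta)``, transition matrices, and fast
    matrix-vector products ``P(t) @ v`` through cached symmetric
    eigendecompositions. Because ``Q(alpha, beta) = s * Q(alpha/s, beta/s)``
    with ``s = alpha + beta``, decompositions are cached on the direction
    ``(alpha/s, beta/s)`` and reused with rescaled times.
    """

    def __init__(
        self,
        code: GeneticCode,
        theta: NucleotideExchangeabilities,
        freqs: FrequencyModel,
        scale: float = 1.0,
    ) -> None:
        self.code = code
        self.theta = theta
        self.freqs = freqs
        self.scale = float(scale)
        self.pi = equilibrium_codon_frequencies(freqs, code)
        syn, nonsyn = _structural_matrices(code, theta, freqs)
        self._a_syn = syn - np.diag(syn.sum(axis=1))
        self._a_nonsyn = nonsyn - np.diag(nonsyn.sum(axis=1))
        # Expected flux of each component at unit rate.
        self.mean_syn_rate = float(self.pi @ syn.sum(axis=1))
        self.mean_nonsyn_rate = float(self.pi @ nonsyn.sum(axis=1))
        d = np.sqrt(self.pi)
        self._d = d
        self._dinv = 1.0 / d
        self._s_syn = self._a_syn * d[:, None] * self._dinv[None, :]
        self._s_nonsyn = self._a_nonsyn * d[:, None] * self._dinv[None, :]
        # Enforce exact symmetry against roundoff.
        self._s_syn = (self._s_syn + self._s_syn.T) / 2
        self._s_nonsyn = (self._s_nonsyn + self._s_nonsyn.T) / 2
        self._decomp_cache: dict[tuple[float, float], tuple] = {}
        self._decomp_counter = 0

    # ---- rate matrices -------------------------------------------------

    def mean_rate(self, alpha: float, beta: float) -> float:
        """Expected substitutions per codon site per unit time."""
        return self.scale * (
            alpha * self.mean_syn_rate + beta * self.mean_nonsyn_rate
        )

    def rate_matrix(self, alpha: float, beta: float) -> CodonRateMatrix:
        q = self.scale * (alpha * self._a_syn + beta * self._a_nonsyn)
        return CodonRateMatrix(q=q, alpha=alpha, beta=beta,
                               scale=self.scale, pi=self.pi)

    # ---- spectral machinery -------------------------------------------

    def _decomposition(self, alpha: float, beta: float):
        s = alpha + beta
        if s <= 0:
            return None  # zero generator: P(t) = I
        key = (round(alpha / s, 12), round(beta / s, 12))
        hit = self._decomp_cache.get(key)
        if hit is None:
            a, b = key
            sym = a * self._s_syn + b * self._s_nonsyn
            lam, u = np.linalg.eigh(sym)
            amat = self._dinv[:, None] * u
            bmat = u.T * self._d[None, :]
            self._decomp_counter += 1
            hit = (lam, amat, bmat, self._decomp_counter)
            if len(self._decomp_cache) > 4096:
                self._decomp_cache.clear()
            self._decomp_cache[key] = hit
        return hit, s

    def transition_matrix(self, alpha: float, beta: float, t: float) -> np.ndarray:
        """P = exp(Q(alpha, beta) * t), rows summing to one."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        dec = self._decomposition(alpha, beta)
        n = self.code.n_states
        if dec is None or t == 0.0:
            return np.eye(n)
        (lam, amat, bmat, _), s = dec
        w = np.exp(lam * (s * self.scale * t))
        p = (amat * w[None, :]) @ bmat
        return _clean_probability_matrix(p)

    def transition_stack(
        self, alpha: float, beta: float, times: np.ndarray
    ) -> np.ndarray:
        """Transition matrices for many branch lengths at once: (B, n, n)."""
        times = np.asarray(times, dtype=float)
        dec = self._decomposition(alpha, beta)
        n = self.code.n_states
        if dec is None:
            return np.broadcast_to(np.eye(n), (len(times), n, n)).copy()
        (lam, amat, bmat, _), s = dec
        w = np.exp(np.outer(times * (s * self.scale), lam))  # (B, n)
        p = (amat[None, :, :] * w[:, None, :]) @ bmat
        np.clip(p, 0.0, 1.0, out=p)
        return p


def _clean_probability_matrix(p: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    if p.min() < -1e-8:
        raise FloatingPointError(
            f"transition matrix entry {p.min():.3e} below tolerance; "
            "the eigendecomposition is ill-conditioned"
        )
    np.clip(p, 0.0, 1.0, out=p)
    return p


def build_codon_rate_matrix(
    alpha: float,
    beta: float,
    theta: NucleotideExchangeabilities,
    freqs: FrequencyModel,
    code: GeneticCode,
    scale: float = 1.0,
) -> CodonRateMatrix:
    """Construct the MG94xGTR generator for one (alpha, beta) pair."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be nonnegative")
    if scale <= 0:
        raise ValueError("scale must be positive")
    return CodonModelKernel(code, theta, freqs, scale).rate_matrix(alpha, beta)


def transition_matrix(q: CodonRateMatrix, t: float) -> np.ndarray:
    """P = exp(Q t) for a concrete rate matrix; rows sum to one."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    if t == 0:
        return np.eye(q.q.shape[0])
    p = scipy.linalg.expm(q.q * t)
    if not np.all(np.isfinite(p)):
        raise FloatingPointError("matrix exponential failed (non-finite entries)")
    return _clean_probability_matrix(p)


# ---- nucleotide GTR (used for the initialization fit) -----------------


class GTRKernel:
    """Reversible GTR nucleotide model with unit mean rate.

    ``q_xy = theta(x, y) * pi_y`` off the diagonal, normalized so the
    expected substitution rate is one; branch lengths are then expected
    nucleotide substitutions per site.
    """

    def __init__(self, theta: NucleotideExchangeabilities, base_freqs: np.ndarray):
        pi = np.asarray(base_freqs, dtype=float)
        if pi.shape != (4,) or abs(pi.sum() - 1) > 1e-8 or np.any(pi < 0):
            raise ValueError("base_freqs must be a distribution over ACGT")
        self.pi = pi / pi.sum()
        th = theta.as_dict()
        ex = np.zeros((4, 4))
        for pair, v in th.items():
            i, j = NUC_INDEX[pair[0]], NUC_INDEX[pair[1]]
            ex[i, j] = ex[j, i] = v
        q = ex * self.pi[None, :]
        np.fill_diagonal(q, 0.0)
        mean = float(self.pi @ q.sum(axis=1))
        if mean <= 0:
            raise ValueError("degenerate GTR model (zero total rate)")
        q /= mean
        q -= np.diag(q.sum(axis=1))
        self.q = q
        d = np.sqrt(np.clip(self.pi, 1e-300, None))
        sym = q * d[:, None] / d[None, :]
        lam, u = np.linalg.eigh((sym + sym.T) / 2)
        self._lam = lam
        self._amat = u / d[:, None]
        self._bmat = u.T * d[None, :]

    def transition_stack(self, times: np.ndarray) -> np.ndarray:
        w = np.exp(np.outer(np.asarray(times, dtype=float), self._lam))
        p = (self._amat[None, :, :] * w[:, None, :]) @ self._bmat
        np.clip(p, 0.0, 1.0, out=p)
        return p
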