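"""Position-specific nucleotide frequencies and the CF3x4 correction.

Codon equilibrium frequencies are parameterized by nine position-specific
nucleotide frequency parameters (a 3x4 row-stochastic matrix F): the
frequency of sense codon ``xyz`` is proportional to ``F1[x] F2[y] F3[z]``
with stop codons removed and the distribution renormalized. Because the
removal of stops shifts the position-specific marginals away from F, the
raw empirical frequencies observed in an alignment are *not* the right
parameter values. The CF3x4 estimator inverts this: it finds the F whose
implied sense-codon marginals reproduce the observed position-specific
frequencies (least squares; 12 constraints, 9 free parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .genetic_code import NUC_INDEX, GeneticCode


@dataclass
class FrequencyModel:
    """3x4 position-specific nucleotide frequencies.

    Rows are codon positions 1..3, columns the nucleotides A, C, G, T.
    ``corrected`` records whether the matrix is a CF3x4 parameter estimate
    (True) or raw observed frequencies (False).
    """

    pos_freqs: np.ndarray
    corrected: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.pos_freqs, dtype=float)
        if f.shape != (3, 4):
            raise ValueError("pos_freqs must be 3x4")
        if np.any(f < -1e-15):
            raise ValueError("frequencies must be nonnegative")
        if np.any(np.abs(f.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("each position row must sum to 1")
        self.pos_freqs = np.clip(f, 0.0, None)

    @classmethod
    def uniform(cls) -> "FrequencyModel":
        return cls(np.full((3, 4), 0.25))


def _position_index_arrays(code: GeneticCode) -> np.ndarray:
    """(3, n_sense) array: nucleotide index at each codon position."""
    return np.array(
        [[NUC_INDEX[c[k]] for c in code.sense_codons] for k in range(3)]
    )


def equilibrium_codon_frequencies(
    freqs: FrequencyModel, code: GeneticCode
) -> np.ndarray:
    """Equilibrium distribution over sense codons implied by F.

    Entry for codon ``xyz`` is proportional to ``F1[x] F2[y] F3[z]``,
    renormalized after stop removal.
    """
    pos = _position_index_arrays(code)
    f = freqs.pos_freqs
    w = f[0, pos[0]] * f[1, pos[1]] * f[2, pos[2]]
    total = w.sum()
    if total <= 0:
        raise ValueError("frequency model puts zero mass on every sense codon")
    return w / total


def implied_position_marginals(
    freqs: FrequencyModel, code: GeneticCode
) -> np.ndarray:
    """Position-specific nucleotide marginals of the sense-codon distribution."""
    pi = equilibrium_codon_frequencies(freqs, code)
    pos = _position_index_arrays(code)
    out = np.zeros((3, 4))
    for k in range(3):
        np.add.at(out[k], pos[k], pi)
    return out


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    """Map a 3x3 free-logit matrix to a 3x4 row-stochastic matrix (last
    logit of each row pinned at 0)."""
    full = np.concatenate([z.reshape(3, 3), np.zeros((3, 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def _logits(f: np.ndarray) -> np.ndarray:
    safe = np.clip(f, 1e-10, None)
    z = np.log(safe)
    return (z[:, :3] - z[:, 3:4]).ravel()


def estimate_cf3x4(
    observed: FrequencyModel,
    code: GeneticCode,
    tol: float = 1e-10,
    max_restarts: int = 4,
) -> FrequencyModel:
    """CF3x4 estimate of the frequency parameters from observed frequencies.

    Finds the 3x4 row-stochastic F minimizing the squared distance between
    the position-specific marginals implied by F (product of positions,
    stops removed, renormalized) and the observed frequencies.

    Raises
    ------
    ValueError
        If the observed frequencies put zero mass on all sense codons, or
        the optimizer fails to reach the requested tolerance after bounded
        multi-start restarts.
    """
    obs = np.asarray(observed.pos_freqs, dtype=float)
    if not code.stop_codons:
        return FrequencyModel(obs.copy(), corrected=True)
    # Degenerate input guard: product mass must be positive somewhere.
    equilibrium_codon_frequencies(observed, code)

    def objective(zflat: np.ndarray) -> float:
        f = _softmax_rows(zflat)
        resid = implied_position_marginals(FrequencyModel(f), code) - obs
        return float(np.sum(resid * resid))

    rng = np.random.default_rng(20120712)
    best = None
    x0 = _logits(obs)
    for restart in range(max_restarts):
        start = x0 if restart == 0 else x0 + rng.normal(scale=0.3, size=9)
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 20000})
        res = minimize(objective, res.x, method="BFGS",
                       options={"gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < tol:
            break
    if best is None or best.fun >= 1e-6:
        raise ValueError(
            f"CF3x4 did not converge: residual norm {best.fun if best else 'n/a'}"
        )
    f = _softmax_rows(best.x)
    f /= f.sum(axis=1, keepdims=True)
    return FrequencyModel(f, corrected=True)


def observed_position_frequencies(
    sequences: dict[str, str] | list[str]
) -> FrequencyModel:
    """Raw position-specific nucleotide frequencies from aligned sequences.

    Ambiguity codes and gaps are ignored in the counts.
    """
    counts = np.zeros((3, 4))
    seqs = sequences.values() if isinstance(sequences, dict) else sequences
    for seq in seqs:
        s = seq.upper()
        for i in range(0, len(s) - len(s) % 3, 3):
            for k in range(3):
                b = s[i + k]
                if b in NUC_INDEX:
                    counts[k, NUC_INDEX[b]] += 1
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("no unambiguous nucleotides at some codon position")
    return FrequencyModel(counts / counts.sum(axis=1, keepdims=True))
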