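"""Genetic-code machinery for codon substitution models.

The codon process operates on the *sense* codons of a genetic code (61
states under the universal code); stop codons are excluded from the state
space. Codon state indices are lexicographic over the nucleotide alphabet
A < C < G < T with stops removed, so indexing is stable across runs and
serialized results remain comparable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: IUPAC nucleotide ambiguity codes mapped to the sets they denote.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    "-": "ACGT", "?": "ACGT", ".": "ACGT", "X": "ACGT",
}

ALL_CODONS = tuple("".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3))


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code restricted to its sense-codon state space.

    Parameters
    ----------
    table_id:
        NCBI translation table identifier (1 = universal/standard code).
    sense_codons:
        Sense codons in lexicographic order (A<C<G<T), stops removed.
    stop_codons:
        Stop codons of the table.
    aa_of:
        Mapping codon -> one-letter amino acid for every sense codon.
    """

    table_id: int
    sense_codons: tuple[str, ...]
    stop_codons: tuple[str, ...]
    aa_of: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        covered = set(self.sense_codons) | set(self.stop_codons)
        if covered != set(ALL_CODONS) or len(self.sense_codons) + len(
            self.stop_codons
        ) != 64:
            raise ValueError("sense and stop codons must partition the 64 codons")

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    @property
    def codon_index(self) -> dict[str, int]:
        return _codon_index(self.sense_codons)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def synonymous(self, codon_i: str, codon_j: str) -> bool:
        return self.aa_of[codon_i] == self.aa_of[codon_j]


@lru_cache(maxsize=None)
def _codon_index(sense_codons: tuple[str, ...]) -> dict[str, int]:
    return {c: i for i, c in enumerate(sense_codons)}


@lru_cache(maxsize=None)
def get_genetic_code(table_id: int = 1) -> GeneticCode:
    """Load an NCBI translation table as a :class:`GeneticCode`.

    The default is the standard (universal) code, table 1, with 61 sense
    codons and stops {TAA, TAG, TGA}.
    """
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = tuple(sorted(table.stop_codons))
    sense = tuple(c for c in ALL_CODONS if c not in table.stop_codons)
    aa_of = {c: table.forward_table[c] for c in sense}
    return GeneticCode(table_id=table_id, sense_codons=sense,
                       stop_codons=stops, aa_of=aa_of)


def codon_nucleotide_diffs(ci: str, cj: str) -> list[tuple[int, str, str]]:
    """Positions (0-based) where two codons differ, with the swapped bases."""
    return [(k, x, y) for k, (x, y) in enumerate(zip(ci, cj)) if x != y]


def expand_ambiguous_codon(codon: str, code: GeneticCode) -> frozenset[int]:
    """Expand a codon possibly containing IUPAC ambiguity codes to the set
    of compatible sense-codon state indices.

    Codons that resolve to stops are dropped from the set. A fully
    unresolved codon (e.g. ``---`` or ``NNN``) expands to every sense state.

    Returns the (possibly empty) frozenset of state indices; an empty set
    means the codon is *only* compatible with stop codons.
    """
    try:
        sets = [IUPAC[b] for b in codon.upper()]
    except KeyError as exc:
        raise ValueError(f"unrecognized nucleotide symbol in codon {codon!r}") from exc
    idx = code.codon_index
    states = frozenset(
        idx[c]
        for c in ("".join(t) for t in itertools.product(*sets))
        if c in idx
    )
    return states


def codon_state_vector(states: frozenset[int], code: GeneticCode) -> np.ndarray:
    """Indicator vector over sense codons for an ambiguity set."""
    v = np.zeros(code.n_states)
    v[list(states)] = 1.0
    return v
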