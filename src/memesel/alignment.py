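"""Codon-encoded sequence alignments.

Sequences are stored per site as *ambiguity sets* of sense-codon state
indices: an unambiguous codon is a singleton set, IUPAC ambiguity codes
expand to every compatible sense codon, and gaps/missing data expand to
the full state set. Codons that can only be stops are an input error
under the strict policy or treated as fully missing under
``stops-as-missing``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .genetic_code import GeneticCode, expand_ambiguous_codon


@dataclass
class CodonAlignment:
    """Aligned coding sequences over sense-codon states.

    ``columns[s][name]`` is the frozenset of sense-codon state indices
    compatible with the observation of sequence ``name`` at codon site
    ``s`` (0-based internally; user-facing coordinates are 1-based).
    """

    names: list[str]
    columns: list[dict[str, frozenset[int]]]
    code: GeneticCode
    source: str | None = None

    @property
    def n_sites(self) -> int:
        return len(self.columns)

    @property
    def n_sequences(self) -> int:
        return len(self.names)

    def column(self, site: int) -> dict[str, frozenset[int]]:
        return self.columns[site]

    def is_invariant(self, site: int) -> bool:
        """True when a single codon state is compatible with every leaf.

        Columns where all unambiguous observations agree and ambiguous
        ones include that state carry no substitution signal.
        """
        shared: frozenset[int] | None = None
        for states in self.columns[site].values():
            shared = states if shared is None else shared & states
            if not shared:
                return False
        # Invariant in the useful sense: some state explains all leaves and
        # at least one leaf is unambiguous (otherwise the column is empty).
        singletons = [
            s for s in self.columns[site].values() if len(s) == 1
        ]
        return bool(shared) and all(
            next(iter(s)) in shared for s in singletons
        )

    def subset_sites(self, sites) -> "CodonAlignment":
        return CodonAlignment(
            names=list(self.names),
            columns=[self.columns[s] for s in sites],
            code=self.code,
            source=self.source,
        )


class AlignmentError(ValueError):
    pass


def alignment_from_strings(
    sequences: dict[str, str],
    code: GeneticCode,
    policy: str = "strict",
    source: str | None = None,
) -> CodonAlignment:
    """Encode aligned nucleotide strings into a :class:`CodonAlignment`."""
    if policy not in ("strict", "stops-as-missing"):
        raise ValueError("policy must be 'strict' or 'stops-as-missing'")
    names = list(sequences)
    if len(set(names)) != len(names):
        raise AlignmentError("duplicate sequence names")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise AlignmentError("sequences have unequal lengths")
    (length,) = lengths or {0}
    if length % 3 != 0:
        raise AlignmentError(
            f"alignment length {length} is not divisible by 3"
        )
    n_sites = length // 3
    full = frozenset(range(code.n_states))
    columns: list[dict[str, frozenset[int]]] = []
    for s in range(n_sites):
        col: dict[str, frozenset[int]] = {}
        for name, seq in sequences.items():
            codon = seq[3 * s : 3 * s + 3].upper()
            states = expand_ambiguous_codon(codon, code)
            if not states:
                if policy == "strict":
                    raise AlignmentError(
                        f"stop codon {codon!r} in sequence {name!r} at codon "
                        f"site {s + 1} (use stops-as-missing to mask)"
                    )
                states = full
            col[name] = states
        columns.append(col)
    return CodonAlignment(names=names, columns=columns, code=code, source=source)


def read_codon_fasta(
    path: str | Path, code: GeneticCode, policy: str = "strict"
) -> CodonAlignment:
    """Read an in-frame FASTA alignment into codon states."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise AlignmentError(f"duplicate sequence name {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return alignment_from_strings(records, code, policy=policy, source=str(path))


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
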