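"""Genetic-code bookkeeping shared by all codon-model machinery.

The codon state space excludes stop codons entirely (61 states for the
standard nuclear code). Codon order is lexicographic over A < C < G < T,
fixed once here so that frequency vectors, rate matrices and encoded
alignments always agree on indexing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
PURINES = frozenset("AG")

GAP_CODON = "---"
MISSING_CODON = "NNN"
#: encoded-state value for gap / missing (fully unknown) codons
UNKNOWN_STATE = -1


def is_transition(a: str, b: str) -> bool:
    """True if the nucleotide change a->b is a transition (purine<->purine
    or pyrimidine<->pyrimidine)."""
    return a != b and ((a in PURINES) == (b in PURINES))


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code restricted to its sense codons.

    Attributes
    ----------
    id : NCBI translation-table id (1 = standard nuclear code).
    sense_codons : tuple of codon strings, lexicographic order.
    stop_codons : frozenset of stop codon strings.
    """

    id: int
    sense_codons: tuple[str, ...]
    stop_codons: frozenset[str]
    amino_acids: tuple[str, ...]
    codon_index: dict[str, int] = field(repr=False)

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def translate_codon(self, codon: str) -> str:
        """One-letter amino acid for a sense codon; 'X' if it contains N;
        '*' for a stop codon."""
        if codon in self.stop_codons:
            return "*"
        if "N" in codon:
            return "X"
        return self.amino_acids[self.codon_index[codon]]

    def is_synonymous(self, i: int, j: int) -> bool:
        return self.amino_acids[i] == self.amino_acids[j]


@lru_cache(maxsize=None)
def genetic_code(code_id: int = 1) -> GeneticCode:
    """Return the :class:`GeneticCode` for an NCBI translation-table id."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    stops = frozenset(table.stop_codons)
    sense = tuple(
        "".join(c)
        for c in itertools.product(BASES, repeat=3)
        if "".join(c) not in stops
    )
    aas = tuple(table.forward_table["".join(c)] for c in map(tuple, sense))
    index = {c: k for k, c in enumerate(sense)}
    return GeneticCode(
        id=code_id,
        sense_codons=sense,
        stop_codons=stops,
        amino_acids=aas,
        codon_index=index,
    )


@lru_cache(maxsize=None)
def neighbor_structure(code_id: int = 1):
    """Single-nucleotide neighbor structure of the sense-codon space.

    Returns (rows, cols, is_ts, is_nonsyn): parallel arrays over ordered
    pairs (i, j) of sense codons differing at exactly one position, with
    transition and nonsynonymous indicator flags. Codon pairs differing at
    more than one position, or reachable only through a stop codon, simply
    do not appear (their instantaneous rate is zero).
    """
    code = genetic_code(code_id)
    rows, cols, ts, nonsyn = [], [], [], []
    for i, ci in enumerate(code.sense_codons):
        for j, cj in enumerate(code.sense_codons):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            rows.append(i)
            cols.append(j)
            ts.append(is_transition(*diffs[0]))
            nonsyn.append(not code.is_synonymous(i, j))
    return (
        np.asarray(rows, dtype=np.intp),
        np.asarray(cols, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(nonsyn, dtype=bool),
    )
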