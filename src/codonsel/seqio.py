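"""Coding-sequence IO and protein-guided codon alignment construction.

Workflow mirrored here: coding sequences are translated, sequences with
internal stop codons are rejected, and a protein alignment is used as the
guide to thread codons into a codon alignment (the back-translation step).
Codons containing N or other ambiguity are treated as fully missing states
downstream, not as errors, since genome-derived CDS routinely contain Ns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import (
    GAP_CODON,
    MISSING_CODON,
    UNKNOWN_STATE,
    GeneticCode,
    genetic_code,
)

_VALID_NT = frozenset("ACGTN")
_AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class InternalStopError(ValueError):
    """A coding sequence contains a stop codon before its final codon."""

    def __init__(self, seq_id: str, codon_index: int, codon: str):
        self.seq_id = seq_id
        self.codon_index = codon_index  # 0-based codon position
        self.codon = codon
        super().__init__(
            f"internal stop codon {codon!r} at codon index {codon_index} "
            f"in sequence {seq_id!r}"
        )


class GuideMismatchError(ValueError):
    """Translated CDS disagrees with its guide-alignment row."""

    def __init__(self, seq_id: str, position: int, expected: str, got: str):
        self.seq_id = seq_id
        self.position = position  # 1-based amino-acid position
        super().__init__(
            f"sequence {seq_id!r}: translation {got!r} does not match guide "
            f"residue {expected!r} at position {position}"
        )


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame coding DNA sequence over {A,C,G,T,N}.

    Length must be a multiple of 3 and the sequence must be free of
    internal stop codons; a terminal stop is permitted (and dropped on
    translation).
    """

    id: str
    nucleotides: str

    def __post_init__(self):
        nt = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", nt)
        if len(nt) % 3 != 0:
            raise ValueError(
                f"sequence {self.id!r}: length {len(nt)} is not a multiple of 3"
            )
        bad = set(nt) - _VALID_NT
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid nucleotide(s) {sorted(bad)}"
            )
        gc = genetic_code(1)
        codons = self.codons
        for k, codon in enumerate(codons[:-1]):
            if codon in gc.stop_codons:
                raise InternalStopError(self.id, k, codon)

    @property
    def codons(self) -> list[str]:
        nt = self.nucleotides
        return [nt[i : i + 3] for i in range(0, len(nt), 3)]


def translate(cds: CodingSequence, code: int | GeneticCode = 1) -> str:
    """Translate a coding sequence, one letter per codon.

    A terminal stop codon is stripped silently; an internal stop raises
    :class:`InternalStopError` identifying the offending codon index.
    Codons containing N translate to 'X'.
    """
    gc = code if isinstance(code, GeneticCode) else genetic_code(code)
    codons = cds.codons
    out = []
    for k, codon in enumerate(codons):
        aa = gc.translate_codon(codon)
        if aa == "*":
            if k == len(codons) - 1:
                break  # terminal stop stripped
            raise InternalStopError(cds.id, k, codon)
        out.append(aa)
    return "".join(out)


@dataclass(frozen=True)
class ProteinAlignment:
    """Equal-length amino-acid rows over the 20 letters plus gap '-'."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        for sid, row in zip(self.ids, self.rows):
            bad = set(row) - _AA_LETTERS - {"-", "X"}
            if bad:
                raise ValueError(
                    f"row {sid!r}: invalid residue(s) {sorted(bad)}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, sid: str) -> str:
        return self.rows[self.ids.index(sid)]


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-aware matrix of codon states: per taxon, per site one of a sense
    codon, the gap token '---', or the missing token 'NNN'."""

    ids: tuple[str, ...]
    codons: tuple[tuple[str, ...], ...]  # [taxon][site]
    code_id: int = 1

    def __post_init__(self):
        gc = genetic_code(self.code_id)
        if len(self.ids) != len(self.codons):
            raise ValueError("ids and codon rows differ in length")
        n_sites = {len(r) for r in self.codons}
        if len(n_sites) > 1:
            raise ValueError("rows have differing numbers of codon sites")
        for sid, row in zip(self.ids, self.codons):
            for k, c in enumerate(row):
                if c in (GAP_CODON, MISSING_CODON):
                    continue
                if c in gc.stop_codons:
                    raise ValueError(
                        f"row {sid!r}: stop codon {c} at site {k}"
                    )
                if c not in gc.codon_index:
                    # ambiguity should have been mapped to the missing token
                    raise ValueError(
                        f"row {sid!r}: invalid codon state {c!r} at site {k}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.codons[0]) if self.codons else 0

    def row(self, sid: str) -> tuple[str, ...]:
        return self.codons[self.ids.index(sid)]

    def encode(self) -> np.ndarray:
        """Integer state matrix (n_taxa, n_sites); gap/missing -> -1."""
        gc = genetic_code(self.code_id)
        out = np.full((self.n_taxa, self.n_sites), UNKNOWN_STATE, dtype=np.int64)
        for i, row in enumerate(self.codons):
            for k, c in enumerate(row):
                if c in gc.codon_index:
                    out[i, k] = gc.codon_index[c]
        return out

    def take_columns(self, cols) -> "CodonAlignment":
        cols = list(cols)
        return CodonAlignment(
            ids=self.ids,
            codons=tuple(tuple(row[k] for k in cols) for row in self.codons),
            code_id=self.code_id,
        )


def _codon_state(triplet: str, gc: GeneticCode) -> str:
    triplet = triplet.upper()
    if triplet == GAP_CODON:
        return GAP_CODON
    if triplet in gc.codon_index:
        return triplet
    if triplet in gc.stop_codons:
        raise ValueError(f"stop codon {triplet} inside alignment")
    # N / ambiguity / partial gap -> fully missing
    return MISSING_CODON


def codon_alignment_from_rows(
    ids, nucleotide_rows, code: int = 1
) -> CodonAlignment:
    """Build a CodonAlignment from equal-length aligned nucleotide rows."""
    gc = genetic_code(code)
    rows = []
    for sid, nt in zip(ids, nucleotide_rows):
        if len(nt) % 3 != 0:
            raise ValueError(
                f"row {sid!r}: aligned length {len(nt)} not a multiple of 3"
            )
        rows.append(
            tuple(
                _codon_state(nt[i : i + 3], gc) for i in range(0, len(nt), 3)
            )
        )
    return CodonAlignment(ids=tuple(ids), codons=tuple(rows), code_id=code)


def back_translate(
    guide: ProteinAlignment,
    cds_set: list[CodingSequence],
    code: int = 1,
) -> CodonAlignment:
    """Thread codons onto a protein guide alignment (back-translation).

    For each id the ungapped guide row must equal the CDS translation
    (an 'X' from an N-containing codon matches any guide residue);
    amino-acid gaps become codon gaps. Raises :class:`GuideMismatchError`
    naming the id and first mismatching 1-based position.
    """
    by_id = {c.id: c for c in cds_set}
    missing = [sid for sid in guide.ids if sid not in by_id]
    if missing:
        raise ValueError(f"no CDS provided for guide row(s): {missing}")
    gc = genetic_code(code)
    rows = []
    for sid in guide.ids:
        cds = by_id[sid]
        aa = translate(cds, gc)
        codons = cds.codons[: len(aa)]  # terminal stop already excluded
        guide_row = guide.row(sid)
        ungapped = guide_row.replace("-", "")
        if len(aa) != len(ungapped):
            raise GuideMismatchError(
                sid, min(len(aa), len(ungapped)) + 1, "<length>", "<length>"
            )
        out, k = [], 0
        for col, res in enumerate(guide_row):
            if res == "-":
                out.append(GAP_CODON)
                continue
            if aa[k] != res and aa[k] != "X" and res != "X":
                raise GuideMismatchError(sid, k + 1, res, aa[k])
            out.append(_codon_state(codons[k], gc))
            k += 1
        rows.append(tuple(out))
    return CodonAlignment(ids=tuple(guide.ids), codons=tuple(rows), code_id=code)


def drop_unusable_columns(
    aln: CodonAlignment, policy: str = "all-gap"
) -> tuple[CodonAlignment, list[int]]:
    """Remove uninformative codon columns.

    policy 'all-gap' removes columns with no sense-codon state at all;
    'any-gap' removes columns containing any gap or missing state
    (the conservative, cleandata-style option). Returns the filtered
    alignment and the provenance map: original column index of each kept
    column.
    """
    if policy not in ("all-gap", "any-gap"):
        raise ValueError(f"unknown column policy {policy!r}")
    gc = genetic_code(aln.code_id)
    kept = []
    for k in range(aln.n_sites):
        states = [row[k] for row in aln.codons]
        sense = [s for s in states if s in gc.codon_index]
        if policy == "all-gap":
            if sense:
                kept.append(k)
        else:
            if len(sense) == len(states):
                kept.append(k)
    return aln.take_columns(kept), kept


# ---------------------------------------------------------------------------
# FASTA IO (identifiers = header up to first whitespace; gap '-')
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records, width: int = 60) -> None:
    """Write (id, sequence) pairs as FASTA."""
    recs = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width or None)
        writer.write_file(recs)


def read_coding_fasta(path, code: int = 1) -> list[CodingSequence]:
    return [CodingSequence(sid, seq) for sid, seq in read_fasta(path)]


def read_protein_alignment(path) -> ProteinAlignment:
    pairs = read_fasta(path)
    return ProteinAlignment(
        ids=tuple(p[0] for p in pairs), rows=tuple(p[1].upper() for p in pairs)
    )


def read_codon_alignment(path, code: int = 1) -> CodonAlignment:
    pairs = read_fasta(path)
    return codon_alignment_from_rows(
        [p[0] for p in pairs], [p[1] for p in pairs], code=code
    )


def write_codon_alignment(path, aln: CodonAlignment, width: int = 60) -> None:
    write_fasta(
        path,
        [(sid, "".join(row)) for sid, row in zip(aln.ids, aln.codons)],
        width=width,
    )
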