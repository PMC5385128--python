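"""Five-sites rule spectral-tuning predictor for mammalian L-opsins.

Residues at sites 180, 197, 277, 285 and 308 (human L-opsin numbering)
jointly determine the wavelength of maximal absorption (lambda_max) of the
long-wavelength-sensitive cone pigment. Anchored at the SHYTA genotype
(560 nm), the substitutions S180A, H197Y, Y277F, T285A and A308S shift
lambda_max down by 7, 28, 8, 15 and 16 nm respectively, additively; the
reverse substitutions shift it up by the same amounts. (Prose accounts of
the rule sometimes quote 7 nm for Y277F, but the published per-genotype
predictions — e.g. SHFTA at 552 nm — and the spectral-tuning literature
are consistent with 8 nm, which is used here.)

Site 233 (S/T among ruminants) is also spectrally interesting — it sits in
transmembrane domain 5 near the chloride-binding region — but its shift is
not established, so it is reported alongside the genotype without ever
entering the prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

#: lambda_max of the SHYTA reference genotype, nm
LAMBDA_MAX_BASE = 560.0

#: site -> (high-shift residue, low-shift residue, shift in nm)
FIVE_SITES: dict[int, tuple[str, str, float]] = {
    180: ("S", "A", 7.0),
    197: ("H", "Y", 28.0),
    277: ("Y", "F", 8.0),
    285: ("T", "A", 15.0),
    308: ("A", "S", 16.0),
}

SITE_ORDER = (180, 197, 277, 285, 308)
AUXILIARY_SITE = 233  # reported, never predicted from


@dataclass(frozen=True)
class SpectralGenotype:
    """Residues at the five tuning sites (plus optional site 233) and the
    additive lambda_max prediction; lambda_max is None when any residue is
    outside its allowed alternatives or missing."""

    residues: dict[int, str | None]
    site233: str | None = None
    lambda_max: float | None = None
    note: str = ""

    @property
    def genotype(self) -> str:
        return "".join(
            (self.residues.get(s) or "?") for s in SITE_ORDER
        )


def predict_lambda_max(genotype) -> SpectralGenotype:
    """Additive five-sites prediction of lambda_max.

    `genotype` is a 5-residue string/sequence in site order 180, 197, 277,
    285, 308, or a {site: residue} mapping. A residue outside its two
    allowed alternatives (or missing) yields an unavailable prediction
    naming the offending site rather than a guess.
    """
    if isinstance(genotype, dict):
        residues = {s: genotype.get(s) for s in SITE_ORDER}
        aux = genotype.get(AUXILIARY_SITE)
    else:
        seq = list(genotype)
        if len(seq) != len(SITE_ORDER):
            raise ValueError(
                f"expected {len(SITE_ORDER)} residues, got {len(seq)}"
            )
        residues = dict(zip(SITE_ORDER, (r.upper() for r in seq)))
        aux = None
    total_shift = 0.0
    for site in SITE_ORDER:
        res = residues[site]
        high, low, shift = FIVE_SITES[site]
        if res is None:
            return SpectralGenotype(
                residues, aux, None, f"site {site}: residue missing"
            )
        if res == low:
            total_shift += shift
        elif res != high:
            return SpectralGenotype(
                residues,
                aux,
                None,
                f"site {site}: residue {res!r} outside alternatives "
                f"{{{high}, {low}}}",
            )
    return SpectralGenotype(
        residues, aux, LAMBDA_MAX_BASE - total_shift
    )


# ---------------------------------------------------------------------------
# genotype extraction from aligned sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedReference:
    """A reference L-opsin protein with known site numbering.

    `site_positions` maps site numbers (180, ...) to 0-based indices into
    `sequence`.
    """

    id: str
    sequence: str
    site_positions: dict[int, int]

    def __post_init__(self):
        missing = [s for s in SITE_ORDER if s not in self.site_positions]
        if missing:
            raise ValueError(
                f"reference lacks annotation for site(s) {missing}"
            )
        for s, idx in self.site_positions.items():
            if not 0 <= idx < len(self.sequence):
                raise ValueError(f"site {s} position {idx} out of range")

    def residue(self, site: int) -> str:
        return self.sequence[self.site_positions[site]]


def synthetic_reference() -> AnnotatedReference:
    """A synthetic annotated L-opsin-like reference (not a real sequence).

    Deterministically generated 364-residue sequence carrying the canonical
    SHYTA residues at sites 180/197/277/285/308 and S at site 233, with
    site number n at 0-based index n-1. Suitable for tests and examples;
    for real analyses supply your own annotated reference.
    """
    rng = np.random.default_rng(20170406)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    seq = list(rng.choice(list(alphabet), size=364))
    fixed = {180: "S", 197: "H", 277: "Y", 285: "T", 308: "A", 233: "S"}
    for site, res in fixed.items():
        seq[site - 1] = res
    positions = {s: s - 1 for s in (*SITE_ORDER, AUXILIARY_SITE)}
    return AnnotatedReference(
        id="synthetic_lopsin_reference",
        sequence="".join(seq),
        site_positions=positions,
    )


def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def _column_map(reference: str, query: str, alignment=None) -> dict[int, int]:
    """Map reference 0-based positions to query positions (gapped -> absent).

    `alignment` may be a precomputed pair of equal-length gapped strings
    (ref_row, query_row); otherwise a global BLOSUM62 alignment is made.
    """
    if alignment is None:
        aln = _default_aligner().align(reference, query)[0]
        ref_row, query_row = str(aln[0]), str(aln[1])
    else:
        ref_row, query_row = alignment
        if len(ref_row) != len(query_row):
            raise ValueError("alignment rows differ in length")
    mapping = {}
    ri = qi = 0
    for a, b in zip(ref_row, query_row):
        if a != "-" and b != "-":
            mapping[ri] = qi
        if a != "-":
            ri += 1
        if b != "-":
            qi += 1
    return mapping


def extract_genotype(
    query: str,
    reference: AnnotatedReference | None = None,
    alignment=None,
) -> SpectralGenotype:
    """Read the five-site genotype (and site 233) off a query sequence via
    an alignment to an annotated reference.

    Sites falling in alignment gaps are reported missing, which makes the
    prediction unavailable rather than wrong.
    """
    if reference is None:
        reference = synthetic_reference()
    cmap = _column_map(reference.sequence, query, alignment)
    residues: dict[int, str | None] = {}
    for site in SITE_ORDER:
        qpos = cmap.get(reference.site_positions[site])
        residues[site] = query[qpos].upper() if qpos is not None else None
    aux = None
    if AUXILIARY_SITE in reference.site_positions:
        qpos = cmap.get(reference.site_positions[AUXILIARY_SITE])
        aux = query[qpos].upper() if qpos is not None else None
    full = dict(residues)
    full[AUXILIARY_SITE] = aux
    return predict_lambda_max(full)


def genotype_table(
    panel: list[tuple[str, str]],
    reference: AnnotatedReference | None = None,
    alignments: dict[str, tuple[str, str]] | None = None,
    experimental: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Genotype and predicted lambda_max for a panel of (species, protein
    sequence) pairs; one row per entry, per-row errors collected in the
    'note' column rather than raised. An experimental lambda_max column is
    passed through when supplied."""
    seen = set()
    rows = []
    for species, seq in panel:
        if species in seen:
            warnings.warn(f"duplicated species id {species!r} in panel")
        seen.add(species)
        try:
            g = extract_genotype(
                seq,
                reference,
                (alignments or {}).get(species),
            )
            row = {
                "species": species,
                **{str(s): g.residues.get(s) for s in SITE_ORDER},
                "site233": g.site233,
                "genotype": g.genotype,
                "predicted_lambda_max": g.lambda_max,
                "note": g.note,
            }
        except Exception as exc:  # per-row errors are not fatal
            row = {
                "species": species,
                **{str(s): None for s in SITE_ORDER},
                "site233": None,
                "genotype": "?????",
                "predicted_lambda_max": None,
                "note": f"error: {exc}",
            }
        if experimental:
            row["experimental_lambda_max"] = experimental.get(species)
        rows.append(row)
    columns = (
        ["species"]
        + [str(s) for s in SITE_ORDER]
        + ["site233", "genotype", "predicted_lambda_max"]
        + (["experimental_lambda_max"] if experimental else [])
        + ["note"]
    )
    return pd.DataFrame(rows, columns=columns)
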