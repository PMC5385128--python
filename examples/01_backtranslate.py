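"""Build a codon alignment from coding sequences and a protein guide.

Coding sequences are translated, checked for internal stops, and threaded
onto the gapped protein alignment so that every amino-acid column becomes
one codon column (gaps become '---'). This is the standard preparation
step before any codon-model analysis.
"""

from codonsel import CodingSequence, ProteinAlignment, back_translate, translate

cds = [
    CodingSequence("cow", "ATGGCGCAACGATTT"),
    CodingSequence("giraffe", "ATGGCGCGATTT"),
    CodingSequence("okapi", "ATGGCGCAACGATTC"),
]
for c in cds:
    print(f"{c.id:8s} {c.nucleotides}  ->  {translate(c)}")

guide = ProteinAlignment(
    ids=("cow", "giraffe", "okapi"),
    rows=("MAQRF", "MA-RF", "MAQRF"),
)
aln = back_translate(guide, cds)
print("\ncodon alignment (gap columns follow the protein guide):")
for sid, row in zip(aln.ids, aln.codons):
    print(f"{sid:8s} {' '.join(row)}")
print(
    f"\n{aln.n_taxa} taxa x {aln.n_sites} codon sites; the giraffe row "
    "carries a codon gap exactly where its guide row had an amino-acid gap."
)
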