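"""Detect polyglutamine tracts in a protein and classify their codons.

Builds a small protein/CDS pair carrying two glutamine runs, finds the
maximal tracts of at least four residues, and reports each tract's codon
composition (pure CAG vs mixed) and size bin.
"""

from polyqsel import NamedSequence, codon_composition, find_tracts, size_bin, translate
from polyqsel.repeat_finder import cag_fraction_bin

# a CDS with a pure-CAG run of 5 and a mixed CAG/CAA run of 4
cds = NamedSequence(
    "demo",
    "ATGGCT" + "CAG" * 5 + "TTTAAA" + "CAGCAACAGCAG" + "GGGTGA",
)
protein = translate(cds)
print(f"protein: {protein.residues}")

for tract in find_tracts(protein):
    comp = codon_composition(tract, cds)
    print(
        f"tract [{tract.start},{tract.end}) length={tract.length} "
        f"size_bin={size_bin(tract)} purity={comp.purity} "
        f"frac_cag={comp.frac_cag:.2f} cag_bin={cag_fraction_bin(comp)}"
    )

# The first tract is 5 glutamines all encoded by CAG (slippage-prone at the
# DNA level); the second mixes CAG and CAA, an interrupted structure that is
# less likely to expand by replication slippage.
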