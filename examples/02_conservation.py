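"""Score a human tract's conservation in mouse and rat orthologs.

Builds a codon-aligned trio in which the rodents retain only part of the
human glutamine run, scores residue-level conservation per ortholog, and
assigns the highly-conserved / highly-variable class.
"""

from polyqsel import Tract, TrioAlignment, tract_conservation

human = "ATG" + "CAG" * 6 + "TTT"
mouse = "ATG" + "CAG" * 5 + "---" + "TTT"  # 5 of 6 glutamines kept
rat = "ATG" + "CAA" * 3 + "CAG" * 2 + "---" + "TTT"  # 5 of 6 (CAA counts as Q)
trio = TrioAlignment("demo", rows=(human, mouse, rat))

tract = Tract("demo", "Q", 1, 7)
score = tract_conservation(trio, tract)
print(
    f"pct_mouse={score.pct_mouse:.2f} pct_rat={score.pct_rat:.2f} "
    f"class={score.klass} runs={score.ortholog_run_lengths}"
)

# Both orthologs keep at least 80% of the glutamine columns, so the tract
# falls in the highly conserved (HC) class; a CAA codon opposite a CAG still
# counts as conserved because conservation is scored at the residue level.
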