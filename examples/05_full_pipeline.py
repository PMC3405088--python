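"""Run the full analysis pipeline on simulated data.

Simulates 40 ortholog trios whose flanking regions evolve under weaker
purifying selection (omega=0.9) than the protein background (omega=0.14),
then runs tract detection, conservation scoring, flank extraction, dN/dS
estimation and the group comparisons, and prints the flank-vs-protein
contrast — the analysis's central result surface.
"""

from polyqsel.pipeline import RunConfig, run
from polyqsel.simulate import SimConfig

cfg = RunConfig(
    simulate=SimConfig(
        n_genes=40, n_codons_background=200, omega_background=0.14,
        omega_flank=0.9, kappa=4.0, slippage_rate=0.05, seed=7,
    ),
    out_dir="scratch/example_run",
    seed=7,
)
res = run(cfg)

print("size histogram (tracts per bin, pure-CAG subset):")
print(res.size_histogram.to_string(index=False))
print()
s = res.comparison_summaries
print(s[s["comparison"] == "flank_vs_protein"].to_string(index=False))
t = res.comparison_tests
row = t[t["comparison"] == "flank_vs_protein"].iloc[0]
print(f"\nMann-Whitney U={row.U:.1f}  two-tailed p={row.p_two_tailed:.2e}")

# Mean flank omega sits far above mean whole-protein omega and the rank test
# is decisive: the flanks evolve under weaker purifying selection, the
# direction this pipeline is built to detect. Full TSV tables are in
# scratch/example_run/.
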