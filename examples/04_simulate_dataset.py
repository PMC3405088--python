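"""Generate a synthetic ortholog-trio dataset on disk.

Writes PHYLIP alignments, the detected human tract table and the ground
truth TSV for ten genes whose flanks evolve faster (omega=0.9) than the
protein background (omega=0.14), with tract slippage. The same seed
always produces byte-identical files.
"""

from pathlib import Path

from polyqsel.simulate import SimConfig, generate_dataset

out = Path("scratch/example_dataset")
cfg = SimConfig(
    n_genes=10, n_codons_background=150, tract_len0=8,
    omega_background=0.14, omega_flank=0.9, kappa=4.0,
    slippage_rate=0.1, seed=42,
)
trios, truths = generate_dataset(cfg, out)

print(f"wrote {len(trios)} trios to {out}/")
for t in truths[:5]:
    print(
        f"{t.gene_id}: tract lengths human={t.tract_len['human']} "
        f"mouse={t.tract_len['mouse']} rat={t.tract_len['rat']}"
    )

# Tract lengths differ between species where slippage inserted or deleted
# repeat units; the alignments carry those events as codon-sized gaps.
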