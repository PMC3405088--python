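# Methods

## Analysis model

The package quantifies selective constraint on polyglutamine (polyQ) tracts
and their surroundings via pairwise dN/dS (ω) between orthologous coding
sequences in a human–mouse–rat trio. The analysis surfaces are:

1. a tract inventory — maximal runs of ≥ 4 glutamines, with codon purity
   (pure CAG / pure CAA / mixed), size bins (4 / 5 / 6–9 / 10+, and the
   coarser 4–5 / 6–9 / 10+ used for comparisons) and CAG/CAA-fraction bins
   (≤ 0.5 / 0.5–1 / 1);
2. per-gene whole-protein ω (tract included) and per-tract flank ω (the 33
   codons on each side, tract and any other polyQ tract excluded);
3. group contrasts: flank vs protein, highly-conserved vs highly-variable
   tracts, pure-CAG vs mixed tracts, size bins, CAG-fraction bins with a
   CAA-fraction control, N- vs C-terminal flank, and a re-run with flanks
   containing other amino-acid repeats excluded. Each contrast reports mean
   ± SEM per group and a two-tailed Mann–Whitney U p-value.

Coordinates are 0-based half-open internally. One protein isoform per gene
(the longest) is assumed at ingest.

## Conservation

A tract's conservation in an ortholog is the fraction of its codon columns at
which the ortholog's codon still translates to glutamine; gap codons count as
non-Q and the fraction is capped at 1 even when the rodent run is longer
(expansions are reported separately as the ortholog run length). Scoring is
at the residue level: a CAA opposite a CAG is conserved; codon purity is a
separate axis. Highly conserved (HC) requires ≥ 0.8 in **both** orthologs and
highly variable (HV) requires ≤ 0.4 in both — the strictest reading of
"conserved in mouse and rat"; both thresholds are parameters. The fractions
define "percent conserved" by column matches; an alternative reading
(min(ortholog run, human run)/human run) is available as
`metric="run_ratio"` since published usage of "X% conserved" is ambiguous.
Tracts crossing frame-breaking human gaps are flagged unscorable.

## Flanking windows

Windows are the ≤ 33 codons immediately adjacent on each side, truncated at
the protein ends. Positions inside another polyQ tract (or, for the
repeat-bias control, inside any other single-residue repeat of ≥ 4) are
dropped without extending the window further out: the 33-codon span is
anchored at the tract, and extension past an excluded neighbour is nowhere
justified. The combined flank estimate uses the union of both windows as one
region; N- and C-terminal estimates are also computed separately.

## dN/dS estimators

Both estimators are counting methods implemented from first principles over
codon columns selected by a region mask.

**NG86.** Each of a codon's nine single-nucleotide neighbours carries weight
1/3 at its position; neighbours that are stop codons are excluded from both
the synonymous/nonsynonymous classification *and* the site total, so a codon
may hold fewer than 3 counted sites. Observed differences between two codons
are averaged over all orderings of the differing positions, skipping
pathways that pass through a stop and re-averaging over the remainder;
`s_d + n_d` equals the number of differing positions whenever a stop-free
pathway exists. Proportions p = D/S are corrected with the Jukes–Cantor
formula d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is reported as saturated.

**YN00-style.** The same counting skeleton, with each single-nucleotide
change weighted by κ (transitions) times the position-specific target
nucleotide frequency (the F3x4 ingredients, pooled over both sequences).
Stop-codon targets stay in the per-position normalisation but score
nothing, which makes the estimator reduce *exactly* to NG86 when κ = 1 and
frequencies are uniform — the limit the tests pin to 1e-9. κ is estimated
from transition/transversion proportions at nondegenerate and
fourfold-degenerate site classes (positions classified identically in both
codons), corrected per class with the K80 model and combined weighted by
class size; empty or saturated classes fall back to κ = 1 with a warning.
Distances correct the transition/transversion split of the weighted
difference counts with the K80 formula (an HKY-flavoured correction — the
frequency information enters through the weighted counting). The κ/site-count
loop iterates to a relative tolerance of 1e-6 (maximum 100 iterations); with
this estimator κ depends only on the raw site-class proportions, so the loop
stabilises after the first update.

**Conventions.** Codon columns with a gap, an ambiguity (N) or a stop in
either compared sequence are dropped for that pair only (pairwise deletion).
ω is dN/dS when dS > 0; dN = 0 with dS > 0 gives ω = 0; dS = 0 or saturation
gives an NA status, never a value. A gene/region value is the arithmetic
mean of ω over the species pairs with status ok (human–mouse, human–rat,
mouse–rat by default; a human-pairs-only mode exists and is recorded in
report headers). All-NA regions propagate as NA and are excluded from group
means and tests, with NA counts reported per table.

## Statistics

Group dispersion is reported as the standard error of the mean (the column
is labelled `sem` explicitly; ddof = 1, a single value has SEM 0). The
Mann–Whitney U test uses exact enumeration when n₁ + n₂ ≤ 20 with no ties,
otherwise the normal approximation with continuity and tie corrections
(`scipy.stats.mannwhitneyu`); U is reported as min(U₁, U₂) and identical
constant groups give p = 1. Raw p-values are reported without
multiple-testing correction; the comparison table records how many tests a
run performed.

## Synthetic-data generator

The simulator emulates the data regime the pipeline is built for: ortholog
CDS trios with a glutamine tract, 33-codon flanks and ordinary coding
background, where slippage produces tract-length variation and selection
acts with different strength per region.

*Point process.* Along each branch, single-nucleotide HKY(κ) proposals
(position uniform, target nucleotide ∝ κ for transitions) are accepted with
probability 1 if synonymous and ω_region if nonsynonymous; stop-creating
proposals are always rejected. The number of proposals is calibrated so that
the branch length is the expected number of *accepted* substitutions per
codon, using the ancestor's average acceptance probability. This
acceptance-rejection scheme (ω as the fixation probability of nonsynonymous
proposals) replaces a full 61×61 rate-matrix exponentiation; it is exact
enough for validating counting estimators and is the documented generating
model. The proposal kernel matches the mutational weighting the YN00
counting assumes, so parameter recovery is a genuine consistency check.

*Slippage.* Per branch, Poisson(rate × tract length) events each insert a
copy of a repeat codon or delete one (never below one unit), so tract length
varies while the residue class (Q) and the reading frame are preserved.
Indels are codon-sized gaps; alignments are codon-aware by construction.

*Defaults* (one value each, chosen once as a realistic regime for
human–rodent divergence): rodent-sister topology ((mouse, rat), human) with
branch lengths 0.2/0.2/0.4 substitutions per codon site and a zero-length
internal branch; κ = 4; background ω = 0.14 and flank ω = 0.9, mirroring the
contrast the pipeline measures (whole-protein constraint strong, flank
constraint weak); tract ω = 0 (the tract stays glutamine; CAG↔CAA synonymous
changes still occur, so pure tracts can become mixed); initial tract length
6; slippage rate 0.05 per branch per repeat unit; 300 background codons.
Every random draw derives from `(seed, gene_index)`, so datasets are
byte-reproducible.

*What it does not emulate:* indels outside the tract, rate heterogeneity
beyond the two-region ω, codon-usage bias in the ancestor (codons are drawn
uniformly from the 61 sense codons), isoform structure, and alignment error.
Passing tests therefore demonstrate correctness of the estimators and
pipeline under a clean codon model, not robustness to real-data artefacts
such as misalignment or annotation noise.

## Problem sizes and tolerances

Simulation-based checks use sizes at which counting estimators are
informative but runs stay light: ω recovery uses 50 genes of 10,000
background codons (κ = 4) in the test suite and 20 genes of 3,000 codons in
the acceptance script — both recover ω ∈ {0.1, 0.5, 1.0} within a few
percent, against a ±20% acceptance band. The null calibration uses 20 (tests)
or 10 (script) replicates of 30 genes at 200 background codons with every
region at ω = 0.3; the direction check uses 200 (tests) or 100 (script)
genes. Numerical tolerances: κ/site-count convergence 1e-6; the κ estimate
is capped at 99 when transversions are absent; estimator limit agreement is
asserted at 1e-9 on site counts.

## Known limitations

- The YN00-style estimator follows the counting logic of the published
  method but is not a line-by-line reimplementation of the reference
  program; small numerical differences from it are expected, and its
  correctness is established against the enumeration oracle, the NG86
  limit and simulation recovery instead.
- Flank ω, estimated from ≤ 66 codons, is noisy and right-skewed as a ratio
  estimator; group means of flank ω therefore sit slightly above the
  generating ω even when estimation is consistent. Comparisons are
  rank-based partly for this reason.
- Conservation scoring assumes codon-aware alignments; frame-breaking gaps
  make a tract unscorable rather than guessed at.
- PHYLIP gene identity is recovered from taxon-name suffixes
  (`human_<gene>`); files with unrelated naming need an explicit
  `gene_ids` argument or tract table keyed to positional ids.
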