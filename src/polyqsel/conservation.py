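"""Conservation of human polyQ tracts in rodent orthologs.

For each tract on the human row of a trio alignment, the fraction of its
codon columns at which the mouse (resp. rat) codon still encodes glutamine
is the tract's conservation in that ortholog; gap codons count as non-Q.
Tracts at least ``hc`` conserved in *both* orthologs are highly conserved
(HC); tracts at most ``hv`` conserved in both are highly variable (HV).
Conservation is residue-level — CAA opposite CAG is conserved; codon
purity is scored separately by :mod:`polyqsel.repeat_finder`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .repeat_finder import Tract
from .seq_io import GeneticCode, STANDARD_CODE, TrioAlignment

__all__ = ["ConservationScore", "tract_conservation", "classify_conservation"]

HC_THRESHOLD = 0.8
HV_THRESHOLD = 0.4


@dataclass
class ConservationScore:
    """Per-ortholog conservation fractions and the HC/HV class."""

    pct_mouse: float
    pct_rat: float
    klass: str  # fully_conserved | HC | HV | absent | intermediate | unscorable
    ortholog_run_lengths: dict[str, int] | None = None

    @property
    def pct_combined(self) -> float:
        return (self.pct_mouse + self.pct_rat) / 2.0

    @property
    def scorable(self) -> bool:
        return self.klass != "unscorable"


def classify_conservation(
    pct_mouse: float,
    pct_rat: float,
    hc: float = HC_THRESHOLD,
    hv: float = HV_THRESHOLD,
) -> str:
    """HC/HV class from the two per-ortholog fractions.

    ``fully_conserved`` (both 1) and ``absent`` (both 0) are the extreme
    sub-classes of HC and HV respectively; anything matching neither
    both-above-hc nor both-below-hv is ``intermediate``.
    """
    if not 0.0 <= hv < hc <= 1.0:
        raise ValueError(f"need 0 <= hv < hc <= 1, got hv={hv}, hc={hc}")
    for p in (pct_mouse, pct_rat):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"conservation fraction {p} outside [0, 1]")
    if pct_mouse == pct_rat == 1.0:
        return "fully_conserved"
    if pct_mouse == pct_rat == 0.0:
        return "absent"
    if pct_mouse >= hc and pct_rat >= hc:
        return "HC"
    if pct_mouse <= hv and pct_rat <= hv:
        return "HV"
    return "intermediate"


def _q_run_through_span(row: str, columns: list[int], code: GeneticCode) -> int:
    """Longest run of Q codons in an ortholog row that touches the tract's
    codon columns (reported descriptively; rodent expansions can exceed
    the human tract length)."""
    if not columns:
        return 0
    n_cols = len(row) // 3
    is_q = [
        code.amino_acid(row[3 * c : 3 * c + 3]) == "Q"
        if "-" not in row[3 * c : 3 * c + 3]
        else False
        for c in range(n_cols)
    ]
    span = set(columns)
    best = 0
    run_start = None
    for c in range(n_cols + 1):
        if c < n_cols and is_q[c]:
            if run_start is None:
                run_start = c
        elif run_start is not None:
            if any(cc in span for cc in range(run_start, c)):
                best = max(best, c - run_start)
            run_start = None
    return best


def tract_conservation(
    trio: TrioAlignment,
    tract: Tract,
    code: GeneticCode = STANDARD_CODE,
    hc: float = HC_THRESHOLD,
    hv: float = HV_THRESHOLD,
    metric: str = "column_match",
) -> ConservationScore:
    """Score one human tract against the rodent rows of its trio.

    ``metric="column_match"`` (default): fraction of the tract's codon
    columns at which the ortholog codon translates to Q (gaps are non-Q;
    a fraction is never above 1 even when the ortholog run is longer).
    ``metric="run_ratio"``: min(ortholog Q-run through the span, human
    tract length) / human tract length — an alternative reading of
    "percent conserved".

    Tracts whose span crosses frame-breaking human gaps are flagged
    ``unscorable``.
    """
    codon_map = trio.human_codon_map()
    if tract.end > len(codon_map):
        raise ValueError(
            f"{tract.protein_id}: tract [{tract.start},{tract.end}) beyond "
            f"human row ({len(codon_map)} codons)"
        )
    columns = [codon_map[p] for p in range(tract.start, tract.end)]
    if any(c is None for c in columns):
        return ConservationScore(0.0, 0.0, "unscorable")
    columns = [c for c in columns if c is not None]

    pcts = {}
    run_lengths = {}
    for sp in ("mouse", "rat"):
        row = trio.row(sp)
        n_q = 0
        for col in columns:
            codon = trio.codon(sp, col)
            if "-" in codon:
                continue
            if code.amino_acid(codon) == "Q":
                n_q += 1
        run = _q_run_through_span(row, columns, code)
        run_lengths[sp] = run
        if metric == "column_match":
            pcts[sp] = n_q / tract.length
        elif metric == "run_ratio":
            pcts[sp] = min(run, tract.length) / tract.length
        else:
            raise ValueError(f"unknown conservation metric {metric!r}")
    klass = classify_conservation(pcts["mouse"], pcts["rat"], hc=hc, hv=hv)
    return ConservationScore(
        pct_mouse=pcts["mouse"],
        pct_rat=pcts["rat"],
        klass=klass,
        ortholog_run_lengths=run_lengths,
    )
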