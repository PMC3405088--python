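"""Flanking windows around a tract.

The regions compared against the whole protein are the ``w`` codons
(default 33) immediately upstream (N-terminal) and downstream (C-terminal)
of a tract, truncated at the protein ends. Positions falling inside any
*other* polyQ tract — and, for the repeat-bias control, inside any other
amino-acid repeat — are dropped from the window without extending it
further out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .repeat_finder import Tract
from .seq_io import TrioAlignment

__all__ = ["FlankRegion", "extract_flanks", "windows_to_columns"]

DEFAULT_WINDOW = 33


@dataclass
class FlankRegion:
    """N- and C-terminal window indices (0-based protein/codon positions)
    for one tract, with a record of excluded positions."""

    tract: Tract
    n_window: tuple[int, ...]
    c_window: tuple[int, ...]
    excluded: tuple[tuple[int, str], ...] = ()  # (index, reason)

    @property
    def all_indices(self) -> tuple[int, ...]:
        return self.n_window + self.c_window

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def extract_flanks(
    tract: Tract,
    all_tracts: Sequence[Tract],
    protein_len: int,
    w: int = DEFAULT_WINDOW,
    exclude_other_aars: bool = False,
    aar_list: Sequence[Tract] = (),
) -> FlankRegion:
    """Windows of up to ``w`` codons on each side of ``tract``.

    ``all_tracts`` are the protein's polyQ tracts (the focal tract may be
    included; it is ignored); indices inside any other tract are removed,
    as are indices inside ``aar_list`` repeats when ``exclude_other_aars``
    is on. Removed indices are dropped, not replaced — the window span
    stays anchored at the tract.
    """
    if w < 1:
        raise ValueError("window size must be >= 1")
    if not (0 <= tract.start < tract.end <= protein_len):
        raise ValueError(
            f"tract [{tract.start},{tract.end}) outside protein [0,{protein_len})"
        )
    others = [t for t in all_tracts if t != tract]
    blockers: list[tuple[Tract, str]] = [(t, "in_other_tract") for t in others]
    if exclude_other_aars:
        blockers += [
            (t, "in_other_AAR")
            for t in aar_list
            if t != tract and not (t.start >= tract.start and t.end <= tract.end)
        ]

    def build(indices: Iterable[int]) -> tuple[list[int], list[tuple[int, str]]]:
        kept, dropped = [], []
        for i in indices:
            reason = next(
                (r for t, r in blockers if t.start <= i < t.end), None
            )
            if reason is None:
                kept.append(i)
            else:
                dropped.append((i, reason))
        return kept, dropped

    n_kept, n_drop = build(range(max(0, tract.start - w), tract.start))
    c_kept, c_drop = build(range(tract.end, min(protein_len, tract.end + w)))
    return FlankRegion(
        tract=tract,
        n_window=tuple(n_kept),
        c_window=tuple(c_kept),
        excluded=tuple(n_drop + c_drop),
    )


def windows_to_columns(
    indices: Iterable[int], trio: TrioAlignment
) -> list[int]:
    """Alignment codon columns carrying the given human protein positions.

    Positions whose human codon crosses a frame-breaking gap are skipped;
    columns gapped in an ortholog are handled downstream by pairwise
    deletion, not here.
    """
    codon_map = trio.human_codon_map()
    cols = []
    for i in indices:
        if 0 <= i < len(codon_map) and codon_map[i] is not None:
            cols.append(codon_map[i])
    return cols
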