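"""Detection and classification of single-amino-acid tandem repeats.

A tract is a *maximal* run of one residue (default glutamine, Q) of at
least ``min_len`` residues (default 4). PolyQ tracts are further classified
by codon composition — pure CAG, pure CAA, or mixed — and by size bin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .seq_io import GeneticCode, NamedSequence, STANDARD_CODE, codon_at

__all__ = [
    "Tract",
    "CodonComposition",
    "find_tracts",
    "codon_composition",
    "size_bin",
    "cag_fraction_bin",
    "caa_fraction_bin",
    "longest_isoform_per_gene",
    "tract_table",
    "write_tract_table",
    "read_tract_table",
]

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")

SIZE_BINS_4WAY = ("4", "5", "6-9", "10+")
SIZE_BINS_3WAY = ("4-5", "6-9", "10+")


@dataclass(frozen=True)
class Tract:
    """A maximal single-residue run, 0-based half-open protein coordinates."""

    protein_id: str
    residue: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class CodonComposition:
    """Codon usage of a polyQ tract and the derived purity class."""

    counts: Mapping[str, int]
    n_cag: int
    n_caa: int
    n_other: int
    frac_cag: float
    frac_caa: float
    purity: str  # pure_CAG | pure_CAA | mixed

    @property
    def is_pure_cag(self) -> bool:
        return self.purity == "pure_CAG"


def find_tracts(
    protein: NamedSequence, residue: str = "Q", min_len: int = 4
) -> list[Tract]:
    """All maximal runs of ``residue`` of length >= ``min_len``, left to right.

    A run of 8 is a single tract of 8, never two of 4 (maximality).
    """
    if len(residue) != 1 or residue.upper() not in _AA_LETTERS:
        raise ValueError(f"invalid residue letter {residue!r}")
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    residue = residue.upper()
    pattern = re.compile(f"{re.escape(residue)}{{{min_len},}}")
    return [
        Tract(protein.id, residue, m.start(), m.end())
        for m in pattern.finditer(protein.residues)
    ]


def codon_composition(
    tract: Tract, cds: NamedSequence, code: GeneticCode = STANDARD_CODE
) -> CodonComposition:
    """Codon counts over the tract span, with the CAG/CAA purity class.

    Raises if a codon under the tract does not translate to the tract
    residue (a CDS/protein mismatch).
    """
    counts: dict[str, int] = {}
    for p in range(tract.start, tract.end):
        codon = codon_at(cds, p)
        if code.amino_acid(codon) != tract.residue:
            raise ValueError(
                f"{tract.protein_id}: codon {codon} at protein position {p} "
                f"does not encode {tract.residue} (CDS/protein mismatch)"
            )
        counts[codon] = counts.get(codon, 0) + 1
    n_cag = counts.get("CAG", 0)
    n_caa = counts.get("CAA", 0)
    length = tract.length
    if n_cag == length:
        purity = "pure_CAG"
    elif n_caa == length:
        purity = "pure_CAA"
    else:
        purity = "mixed"
    return CodonComposition(
        counts=counts,
        n_cag=n_cag,
        n_caa=n_caa,
        n_other=length - n_cag - n_caa,
        frac_cag=n_cag / length,
        frac_caa=n_caa / length,
        purity=purity,
    )


def size_bin(tract_or_length: Tract | int, scheme: str = "4way") -> str:
    """Size-bin label for a tract of >= 4 residues.

    ``4way``: 4 / 5 / 6-9 / 10+ (histogram bins); ``3way``: 4-5 / 6-9 / 10+
    (comparison bins).
    """
    length = (
        tract_or_length if isinstance(tract_or_length, int) else tract_or_length.length
    )
    if length < 4:
        raise ValueError(f"tract length {length} < 4")
    if scheme == "4way":
        if length == 4:
            return "4"
        if length == 5:
            return "5"
        return "6-9" if length <= 9 else "10+"
    if scheme == "3way":
        if length <= 5:
            return "4-5"
        return "6-9" if length <= 9 else "10+"
    raise ValueError(f"unknown size-bin scheme {scheme!r}")


def _fraction_bin(frac: float) -> str:
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"fraction {frac} outside [0, 1]")
    if frac == 1.0:
        return "1"
    return "<=0.5" if frac <= 0.5 else "0.5-1"


def cag_fraction_bin(comp: CodonComposition) -> str:
    """Bin by CAG fraction: '<=0.5' / '0.5-1' (exclusive) / '1' (pure)."""
    return _fraction_bin(comp.frac_cag)


def caa_fraction_bin(comp: CodonComposition) -> str:
    """The analogous binning by CAA fraction (CAA-richness control)."""
    return _fraction_bin(comp.frac_caa)


def longest_isoform_per_gene(
    proteins: Iterable[NamedSequence],
    gene_of: Mapping[str, str] | None = None,
) -> list[NamedSequence]:
    """Keep one protein per gene: the longest isoform (ties: first seen).

    ``gene_of`` maps protein id -> gene id; by default each protein id is
    its own gene.
    """
    best: dict[str, NamedSequence] = {}
    order: list[str] = []
    for prot in proteins:
        gene = gene_of.get(prot.id, prot.id) if gene_of else prot.id
        cur = best.get(gene)
        if cur is None:
            best[gene] = prot
            order.append(gene)
        elif len(prot) > len(cur):
            best[gene] = prot
    return [best[g] for g in order]


def tract_table(
    tracts_with_cds: Iterable[tuple[Tract, NamedSequence]],
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Tabulate tracts with codon composition and size bins (the stand-in
    interchange format for an externally supplied tract table)."""
    rows = []
    for tract, cds in tracts_with_cds:
        comp = codon_composition(tract, cds, code)
        codon_string = "".join(
            codon_at(cds, p) for p in range(tract.start, tract.end)
        )
        rows.append(
            {
                "protein_id": tract.protein_id,
                "residue": tract.residue,
                "start": tract.start,
                "end": tract.end,
                "length": tract.length,
                "codon_string": codon_string,
                "n_cag": comp.n_cag,
                "n_caa": comp.n_caa,
                "frac_cag": comp.frac_cag,
                "purity": comp.purity,
                "size_bin": size_bin(tract),
            }
        )
    columns = [
        "protein_id", "residue", "start", "end", "length", "codon_string",
        "n_cag", "n_caa", "frac_cag", "purity", "size_bin",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_tract_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tract_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    for col in ("residue", "codon_string", "purity", "size_bin"):
        if col in table.columns:
            table[col] = table[col].astype(str)
    required = {"protein_id", "residue", "start", "end"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"tract table missing columns: {sorted(missing)}")
    return table
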