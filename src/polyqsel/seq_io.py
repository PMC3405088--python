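"""Sequence and alignment I/O.

FASTA and PHYLIP readers/writers (backed by Biopython), the standard genetic
code, CDS translation, and the protein-position <-> codon mapping that the
repeat and dN/dS machinery relies on.

Coordinates are 0-based, half-open throughout; 1-based closed coordinates
appear only in human-readable report columns.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO, SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NamedSequence",
    "TrioAlignment",
    "GeneticCode",
    "STANDARD_CODE",
    "SPECIES",
    "read_fasta",
    "write_fasta",
    "read_phylip",
    "write_phylip",
    "translate",
    "codon_at",
]

SPECIES = ("human", "mouse", "rat")

#: Default taxon-name prefixes used to map PHYLIP rows to species.
DEFAULT_SPECIES_PREFIXES: Mapping[str, tuple[str, ...]] = {
    "human": ("hum", "hsa", "homo", "hs"),
    "mouse": ("mou", "mus", "mmu", "mm"),
    "rat": ("rat", "rno", "rn"),
}


@dataclass(frozen=True)
class NamedSequence:
    """A labelled sequence (nucleotide or amino acid), upper-cased."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino acid map for the 61 sense codons, plus the stop set."""

    table: Mapping[str, str]
    stops: frozenset[str]

    @classmethod
    def standard(cls) -> "GeneticCode":
        bio = CodonTable.unambiguous_dna_by_id[1]
        return cls(table=dict(bio.forward_table), stops=frozenset(bio.stop_codons))

    def amino_acid(self, codon: str) -> str:
        """Translate one codon; stop -> '*', any-N codon -> 'X'."""
        codon = codon.upper()
        if codon in self.stops:
            return "*"
        aa = self.table.get(codon)
        if aa is None:
            if "N" in codon:
                return "X"
            raise ValueError(f"not a codon: {codon!r}")
        return aa

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stops


STANDARD_CODE = GeneticCode.standard()


@dataclass
class TrioAlignment:
    """Three aligned orthologous CDSs (human, mouse, rat order).

    Rows may contain gaps; row lengths are equal and, for codon-aware
    alignments, a multiple of 3 so that columns group into codon columns
    ``[3k, 3k+3)``.
    """

    gene_id: str
    species: tuple[str, str, str] = SPECIES
    rows: tuple[str, str, str] = ()

    def __post_init__(self) -> None:
        if len(self.rows) != 3:
            raise ValueError(f"{self.gene_id}: trio alignment needs exactly 3 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_id}: unequal row lengths {sorted(lengths)}")
        self.rows = tuple(r.upper() for r in self.rows)

    def __len__(self) -> int:
        return len(self.rows[0])

    @property
    def n_codon_columns(self) -> int:
        return len(self) // 3

    def row(self, species: str) -> str:
        return self.rows[self.species.index(species)]

    def codon(self, species: str, column: int) -> str:
        """The codon (possibly gap-containing) of `species` at codon column."""
        r = self.row(species)
        return r[3 * column : 3 * column + 3]

    def human_codon_map(self) -> list[int | None]:
        """Map human protein/codon index -> alignment codon column.

        Entry ``p`` is the codon column carrying the human row's ``p``-th
        ungapped codon, or ``None`` for frame-breaking columns (the human
        codon mixes bases and gaps); those positions are unscorable.
        """
        mapping: list[int | None] = []
        for col in range(self.n_codon_columns):
            codon = self.codon("human", col)
            if codon == "---":
                continue
            if "-" in codon:
                mapping.append(None)
            else:
                mapping.append(col)
        return mapping


def read_fasta(path: str | Path) -> list[NamedSequence]:
    """Read a multi-record FASTA file, preserving order.

    Raises ``ValueError`` on an empty file or a record with no residues.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty input: no FASTA records in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq).replace(" ", "").upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        out.append(NamedSequence(rec.id, seq))
    return out


def write_fasta(seqs: Iterable[NamedSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def _species_for_name(name: str, prefixes: Mapping[str, tuple[str, ...]]) -> str | None:
    low = name.lower()
    for sp, prefs in prefixes.items():
        if any(low.startswith(p) for p in prefs):
            return sp
    return None


def _parse_phylip_text(text: str) -> list[list[tuple[str, str]]]:
    """Parse concatenated PHYLIP blocks; try relaxed/sequential dialects."""
    blocks: list[list[tuple[str, str]]] = []
    handle = io.StringIO(text)
    last_err: Exception | None = None
    for fmt in ("phylip-relaxed", "phylip-sequential", "phylip"):
        handle.seek(0)
        blocks.clear()
        try:
            for aln in AlignIO.parse(handle, fmt):
                blocks.append([(rec.id, str(rec.seq)) for rec in aln])
            if blocks:
                return blocks
        except Exception as err:  # malformed under this dialect; try next
            last_err = err
    raise ValueError(f"could not parse PHYLIP input: {last_err}")


def read_phylip(
    path: str | Path,
    species_prefixes: Mapping[str, tuple[str, ...]] = DEFAULT_SPECIES_PREFIXES,
    gene_ids: Sequence[str] | None = None,
) -> list[TrioAlignment]:
    """Read one or more 3-taxon alignments from a PHYLIP file.

    Sequential and interleaved dialects are both accepted, as are multiple
    concatenated alignment blocks. Taxon names are mapped to
    human/mouse/rat by configurable name prefixes; rows whose names match
    no prefix are assigned the remaining species in file order.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"empty input: {path}")
    blocks = _parse_phylip_text(text)
    headers = [
        (int(m.group(1)), int(m.group(2)))
        for m in re.finditer(r"^\s*(\d+)\s+(\d+)\s*$", text, flags=re.M)
    ]
    if len(headers) == len(blocks):
        for i, ((ntax, length), block) in enumerate(zip(headers, blocks)):
            if len(block) != ntax or any(len(seq) != length for _, seq in block):
                raise ValueError(
                    f"alignment block {i}: rows do not match header "
                    f"({ntax} x {length})"
                )
    trios = []
    for i, block in enumerate(blocks):
        if len(block) != 3:
            raise ValueError(
                f"alignment block {i} has {len(block)} taxa; trio mode needs 3"
            )
        assigned: dict[str, tuple[str, str]] = {}
        unmatched = []
        for name, seq in block:
            sp = _species_for_name(name, species_prefixes)
            if sp is not None and sp not in assigned:
                assigned[sp] = (name, seq)
            else:
                unmatched.append((name, seq))
        for sp in SPECIES:
            if sp not in assigned and unmatched:
                assigned[sp] = unmatched.pop(0)
        if gene_ids is not None:
            gid = gene_ids[i]
        else:
            # taxon names like "human_GENE" carry the gene id as a suffix
            name = block[0][0]
            gid = name.split("_", 1)[1] if "_" in name else f"trio{i:04d}"
        trios.append(
            TrioAlignment(gene_id=gid, rows=tuple(assigned[sp][1] for sp in SPECIES))
        )
    return trios


def write_phylip(trios: Iterable[TrioAlignment], path: str | Path) -> None:
    """Write trios as concatenated sequential PHYLIP blocks (relaxed names)."""
    with open(path, "w") as fh:
        for trio in trios:
            fh.write(f" 3 {len(trio)}\n")
            for sp, row in zip(trio.species, trio.rows):
                fh.write(f"{sp}_{trio.gene_id}  {row}\n")


def translate(
    cds: NamedSequence,
    code: GeneticCode = STANDARD_CODE,
    allow_internal_stop: bool = False,
) -> NamedSequence:
    """Translate a gap-free CDS with the standard code.

    A terminal stop codon is dropped; an internal stop raises unless
    ``allow_internal_stop`` (then it becomes ``*``). Codons containing N
    translate to ``X``.
    """
    seq = cds.residues
    if len(seq) % 3 != 0:
        raise ValueError(f"{cds.id}: CDS length {len(seq)} not a multiple of 3")
    if "-" in seq:
        raise ValueError(f"{cds.id}: CDS contains gaps; translate ungapped sequences")
    aas = []
    n_codons = len(seq) // 3
    for p in range(n_codons):
        codon = seq[3 * p : 3 * p + 3]
        aa = code.amino_acid(codon)
        if aa == "*":
            if p == n_codons - 1:
                break  # terminal stop dropped
            if not allow_internal_stop:
                raise ValueError(
                    f"{cds.id}: internal stop codon {codon} at codon {p}"
                )
        aas.append(aa)
    return NamedSequence(cds.id, "".join(aas))


def codon_at(cds: NamedSequence, protein_pos: int) -> str:
    """Codon encoding the 0-based protein position ``protein_pos``."""
    n = len(cds.residues) // 3
    if not 0 <= protein_pos < n:
        raise IndexError(f"protein position {protein_pos} out of range [0, {n})")
    return cds.residues[3 * protein_pos : 3 * protein_pos + 3]
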