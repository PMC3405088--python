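"""Synthetic ortholog-trio generator.

Simulates human/mouse/rat coding sequences descending from a common
ancestor that carries a glutamine tract flanked by two fixed-width flank
regions inside a background of ordinary coding sequence. Point evolution
is an acceptance-rejection codon process: single-nucleotide HKY(kappa)
proposals are accepted with probability 1 when synonymous and with
probability omega (region-specific) when nonsynonymous; proposals that
would create a stop codon are always rejected. The tract additionally
evolves by replication slippage — insertion or deletion of single repeat
units (codon copies) — so tract length varies between species while the
reading frame is preserved. Output trios are codon-aligned by
construction, with slippage indels as codon-sized gaps.

The generator is the ground truth for every downstream stage: the truth
record keeps the generating parameters, the per-species tract lengths and
the codon-column span of each region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import repeat_finder
from .dnds import CODONS, NT, is_transition
from .seq_io import NamedSequence, STANDARD_CODE, TrioAlignment, write_phylip

__all__ = ["SimConfig", "SimTruth", "simulate_trio", "generate_dataset"]

DEFAULT_BRANCH_LENGTHS: Mapping[str, float] = {
    "human": 0.4,
    "mouse": 0.2,
    "rat": 0.2,
    "internal": 0.0,
}

REGIONS = ("bg_left", "flank_n", "tract", "flank_c", "bg_right")


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for a set of ortholog trios.

    Rates are per branch; branch lengths are expected accepted
    substitutions per codon site. ``slippage_rate`` is the expected number
    of slippage events per branch per repeat unit of the tract.
    """

    n_genes: int = 100
    n_codons_background: int = 300
    flank_len: int = 33
    tract_len0: int = 6
    tract_purity: str = "pure_CAG"  # pure_CAG | mixed
    frac_cag: float = 1.0  # CAG fraction for mixed tracts
    omega_background: float = 0.14
    omega_flank: float = 0.9
    omega_tract: float = 0.0  # tract stays glutamine: synonymous changes only
    kappa: float = 4.0
    branch_lengths: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_LENGTHS)
    )
    slippage_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tract_len0 < 4:
            raise ValueError("tract_len0 must be >= 4")
        if self.tract_purity == "mixed" and not 0.0 < self.frac_cag <= 1.0:
            raise ValueError("frac_cag must be in (0, 1] for mixed tracts")
        for name, val in [
            ("omega_background", self.omega_background),
            ("omega_flank", self.omega_flank),
            ("omega_tract", self.omega_tract),
            ("slippage_rate", self.slippage_rate),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


@dataclass
class SimTruth:
    """Ground truth for one simulated trio."""

    gene_id: str
    config: SimConfig
    tract_len: dict[str, int]
    region_columns: dict[str, tuple[int, int]]  # label -> [start, end) codon cols
    substitutions: dict[str, dict[str, int]]  # region -> {syn, nonsyn}

    def mask_columns(self, *labels: str) -> list[int]:
        cols: list[int] = []
        for label in labels:
            lo, hi = self.region_columns[label]
            cols.extend(range(lo, hi))
        return cols

    @property
    def flank_columns(self) -> list[int]:
        return self.mask_columns("flank_n", "flank_c")

    @property
    def whole_columns(self) -> list[int]:
        return self.mask_columns(*REGIONS)


class _CodonProcess:
    """Precomputed HKY(kappa) proposal tables over the 61 sense codons."""

    def __init__(self, kappa: float):
        self.kappa = kappa
        self._acc_cache: dict[tuple[str, float], float] = {}
        # codon -> per position: (targets, syn flags, stop flags, cumulative probs)
        self.tables: dict[str, list[tuple[list[str], list[bool], list[bool], np.ndarray]]] = {}
        for codon in CODONS:
            aa = STANDARD_CODE.amino_acid(codon)
            per_pos = []
            for pos in range(3):
                targets, syn, stop, w = [], [], [], []
                for nt in NT:
                    if nt == codon[pos]:
                        continue
                    t = codon[:pos] + nt + codon[pos + 1 :]
                    targets.append(t)
                    is_stop = STANDARD_CODE.is_stop(t)
                    stop.append(is_stop)
                    syn.append((not is_stop) and STANDARD_CODE.amino_acid(t) == aa)
                    w.append(kappa if is_transition(codon[pos], nt) else 1.0)
                w = np.asarray(w)
                per_pos.append((targets, syn, stop, np.cumsum(w / w.sum())))
            self.tables[codon] = per_pos

    def acceptance_prob(self, codon: str, omega: float) -> float:
        """Expected acceptance probability of one HKY proposal at this codon."""
        cached = self._acc_cache.get((codon, omega))
        if cached is not None:
            return cached
        total = 0.0
        for targets, syn, stop, cum in self.tables[codon]:
            probs = np.diff(np.concatenate([[0.0], cum]))
            for p, s, st in zip(probs, syn, stop):
                if st:
                    continue
                total += p * (1.0 if s else omega)
        total /= 3.0
        self._acc_cache[(codon, omega)] = total
        return total

    def evolve(
        self,
        codons: list[str],
        t: float,
        omega: float,
        rng: np.random.Generator,
    ) -> tuple[list[str], dict[str, int]]:
        """Evolve a codon list for branch length ``t`` (expected accepted
        substitutions per codon site) under region omega."""
        n = len(codons)
        if n == 0 or t <= 0.0:
            return list(codons), {"syn": 0, "nonsyn": 0}
        p_acc = float(np.mean([self.acceptance_prob(c, omega) for c in codons]))
        p_acc = max(p_acc, 1e-9)
        n_prop = rng.poisson(t * n / p_acc)
        out = list(codons)
        counts = {"syn": 0, "nonsyn": 0}
        for _ in range(n_prop):
            idx = rng.integers(n)
            pos = rng.integers(3)
            targets, syn, stop, cum = self.tables[out[idx]][pos]
            k = int(np.searchsorted(cum, rng.random()))
            if stop[k]:
                continue
            if syn[k]:
                out[idx] = targets[k]
                counts["syn"] += 1
            elif rng.random() < omega:
                out[idx] = targets[k]
                counts["nonsyn"] += 1
        return out, counts


def _draw_ancestor(config: SimConfig, rng: np.random.Generator) -> dict[str, list[str]]:
    n_left = config.n_codons_background // 2
    n_right = config.n_codons_background - n_left

    def bg(n: int) -> list[str]:
        return [CODONS[i] for i in rng.integers(len(CODONS), size=n)]

    if config.tract_purity == "pure_CAG":
        tract = ["CAG"] * config.tract_len0
    else:
        tract = [
            "CAG" if rng.random() < config.frac_cag else "CAA"
            for _ in range(config.tract_len0)
        ]
    return {
        "bg_left": bg(n_left),
        "flank_n": bg(config.flank_len),
        "tract": tract,
        "flank_c": bg(config.flank_len),
        "bg_right": bg(n_right),
    }


def _slip(tract: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    """Slippage on one branch: Poisson(rate x length) unit insertions or
    deletions, each copying or removing one repeat codon (frame-safe,
    residue-class-preserving). The tract never shrinks below one unit."""
    out = list(tract)
    n_events = rng.poisson(rate * len(out)) if out else 0
    for _ in range(n_events):
        if not out:
            break
        i = int(rng.integers(len(out)))
        if rng.random() < 0.5:
            out.insert(i, out[i])  # duplicate a unit
        elif len(out) > 1:
            out.pop(i)
    return out


def _evolve_branch(
    regions: dict[str, list[str]],
    t: float,
    config: SimConfig,
    process: _CodonProcess,
    rng: np.random.Generator,
    counts: dict[str, dict[str, int]] | None = None,
) -> dict[str, list[str]]:
    omegas = {
        "bg_left": config.omega_background,
        "flank_n": config.omega_flank,
        "tract": config.omega_tract,
        "flank_c": config.omega_flank,
        "bg_right": config.omega_background,
    }
    out = {}
    for label, codons in regions.items():
        evolved, c = process.evolve(codons, t, omegas[label], rng)
        if label == "tract":
            evolved = _slip(evolved, config.slippage_rate, rng)
        out[label] = evolved
        if counts is not None:
            counts[label]["syn"] += c["syn"]
            counts[label]["nonsyn"] += c["nonsyn"]
    return out


def simulate_trio(
    config: SimConfig, gene_index: int
) -> tuple[TrioAlignment, SimTruth]:
    """One ortholog trio under the configured codon/slippage model.

    Reproducible: the per-gene random stream is derived from
    ``(config.seed, gene_index)`` only. Tree: rodent-sister topology
    ((mouse, rat), human) with branch lengths from ``config``.
    """
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, gene_index])
    process = _CodonProcess(config.kappa)
    ancestor = _draw_ancestor(config, rng)
    bl = dict(DEFAULT_BRANCH_LENGTHS) | dict(config.branch_lengths)
    counts = {r: {"syn": 0, "nonsyn": 0} for r in REGIONS}

    human = _evolve_branch(ancestor, bl["human"], config, process, rng, counts)
    rodent = _evolve_branch(ancestor, bl["internal"], config, process, rng, counts)
    mouse = _evolve_branch(rodent, bl["mouse"], config, process, rng, counts)
    rat = _evolve_branch(rodent, bl["rat"], config, process, rng, counts)

    species_regions = {"human": human, "mouse": mouse, "rat": rat}
    tract_len = {sp: len(r["tract"]) for sp, r in species_regions.items()}
    max_tract = max(tract_len.values())

    rows = []
    for sp in ("human", "mouse", "rat"):
        parts = []
        for label in REGIONS:
            codons = species_regions[sp][label]
            if label == "tract":
                codons = codons + ["---"] * (max_tract - len(codons))
            parts.append("".join(codons))
        rows.append("".join(parts))

    gene_id = f"gene{gene_index:04d}"
    region_columns = {}
    cursor = 0
    for label in REGIONS:
        n = len(ancestor[label]) if label != "tract" else max_tract
        region_columns[label] = (cursor, cursor + n)
        cursor += n
    trio = TrioAlignment(gene_id=gene_id, rows=tuple(rows))
    truth = SimTruth(
        gene_id=gene_id,
        config=config,
        tract_len=tract_len,
        region_columns=region_columns,
        substitutions=counts,
    )
    return trio, truth


def generate_dataset(
    config: SimConfig, out_dir: str | Path
) -> tuple[list[TrioAlignment], list[SimTruth]]:
    """Simulate ``config.n_genes`` trios and write them to ``out_dir``:
    ``trios.phy`` (sequential PHYLIP blocks), ``tracts.tsv`` (human polyQ
    tracts detected on the simulated human rows) and ``truth.tsv``.
    Identical config and seed give byte-identical files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trios, truths = [], []
    tract_rows = []
    for g in range(config.n_genes):
        trio, truth = simulate_trio(config, g)
        trios.append(trio)
        truths.append(truth)
        human_cds = NamedSequence(trio.gene_id, trio.row("human").replace("-", ""))
        protein = NamedSequence(
            trio.gene_id,
            "".join(
                STANDARD_CODE.amino_acid(human_cds.residues[i : i + 3])
                for i in range(0, len(human_cds.residues), 3)
            ),
        )
        for tract in repeat_finder.find_tracts(protein):
            tract_rows.append((tract, human_cds))
    write_phylip(trios, out_dir / "trios.phy")
    table = repeat_finder.tract_table(tract_rows)
    repeat_finder.write_tract_table(table, out_dir / "tracts.tsv")

    truth_df = pd.DataFrame(
        [
            {
                "gene_id": t.gene_id,
                "tract_len_human": t.tract_len["human"],
                "tract_len_mouse": t.tract_len["mouse"],
                "tract_len_rat": t.tract_len["rat"],
                "omega_background": t.config.omega_background,
                "omega_flank": t.config.omega_flank,
                "kappa": t.config.kappa,
                "slippage_rate": t.config.slippage_rate,
                **{
                    f"{r}_cols": f"{lo}-{hi}"
                    for r, (lo, hi) in t.region_columns.items()
                },
                **{
                    f"{r}_{k}": t.substitutions[r][k]
                    for r in REGIONS
                    for k in ("syn", "nonsyn")
                },
            }
            for t in truths
        ]
    )
    truth_df.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return trios, truths
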