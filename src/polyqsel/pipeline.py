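"""End-to-end orchestration.

From ortholog trio alignments (read or simulated) the pipeline produces
the analysis surfaces: the tract inventory with size bins and codon
purity, per-protein whole-protein omega and per-tract flank omega, and
the group comparisons (flank vs protein, highly-conserved vs
highly-variable, pure vs mixed codons, size bins, CAG/CAA-fraction bins,
N- vs C-terminal flank, and the re-run with flanks containing other
amino-acid repeats excluded). All outputs are TSV; every table carries
the run's config hash and NA counts as leading ``#`` comment lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import repeat_finder
from .conservation import tract_conservation
from .dnds import GeneDnDs, RegionMask, gene_dnds
from .flanks import extract_flanks, windows_to_columns
from .repeat_finder import Tract, find_tracts
from .seq_io import NamedSequence, STANDARD_CODE, TrioAlignment, read_phylip
from .simulate import SimConfig, generate_dataset, simulate_trio
from .stats import compare_groups

__all__ = ["RunConfig", "PipelineResult", "run"]

logger = logging.getLogger("polyqsel")

_AA_NON_Q = [a for a in "ACDEFGHIKLMNPRSTVWY"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serialisable)."""

    alignments: str | None = None  # PHYLIP trios
    tract_table: str | None = None  # optional externally supplied tract table
    simulate: SimConfig | None = None
    window: int = 33
    min_tract_len: int = 4
    hc: float = 0.8
    hv: float = 0.4
    estimator: str = "yn00"
    species_pairs: str = "all"  # all | human_only
    exclude_other_aars: bool = False
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded, so identical analyses hash identically)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return hashlib.sha256(repr(d).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    tract_inventory: pd.DataFrame
    protein_omega: pd.DataFrame
    tract_omega: pd.DataFrame
    size_histogram: pd.DataFrame
    comparison_summaries: pd.DataFrame
    comparison_tests: pd.DataFrame
    na_counts: dict[str, int] = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "tract_inventory": self.tract_inventory,
            "protein_omega": self.protein_omega,
            "tract_omega": self.tract_omega,
            "size_histogram": self.size_histogram,
            "comparison_summaries": self.comparison_summaries,
            "comparison_tests": self.comparison_tests,
        }


def _human_protein(trio: TrioAlignment) -> NamedSequence:
    cds = trio.row("human").replace("-", "")
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = STANDARD_CODE.amino_acid(cds[i : i + 3])
        if aa == "*":
            if i == len(cds) - 3:
                break
            aa = "X"  # tolerate annotation noise in real alignments
        aas.append(aa)
    return NamedSequence(trio.gene_id, "".join(aas)) if aas else None


def _tracts_for(
    trio: TrioAlignment,
    protein: NamedSequence,
    table: pd.DataFrame | None,
    min_len: int,
) -> list[Tract]:
    if table is None:
        return find_tracts(protein, "Q", min_len)
    sub = table[table["protein_id"] == trio.gene_id]
    return [
        Tract(str(r.protein_id), str(r.residue), int(r.start), int(r.end))
        for r in sub.itertuples()
    ]


def _omega_of(est: GeneDnDs) -> float:
    return np.nan if est.omega_mean is None else est.omega_mean


def run(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Any stage failure is re-raised with the stage name and the offending
    gene id. An input with no tracts yields empty tables and a warning.
    """
    out_dir = Path(config.out_dir)
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.simulate.seed or config.seed)
        if write:
            trios, _truths = generate_dataset(sim_cfg, out_dir / "simulated")
        else:  # in-memory run: no files touched
            trios = [simulate_trio(sim_cfg, g)[0] for g in range(sim_cfg.n_genes)]
    elif config.alignments is not None:
        trios = read_phylip(config.alignments)
    else:
        raise ValueError("config must provide either alignments or a simulate block")

    table = (
        repeat_finder.read_tract_table(config.tract_table)
        if config.tract_table
        else None
    )

    inv_rows, prot_rows, tract_rows = [], [], []
    for trio in trios:
        stage = "ingest"
        try:
            protein = _human_protein(trio)
            if protein is None:
                continue
            human_cds = NamedSequence(
                trio.gene_id, trio.row("human").replace("-", "")[: 3 * len(protein)]
            )
            stage = "repeat_finder"
            tracts = _tracts_for(trio, protein, table, config.min_tract_len)

            stage = "dnds_whole_protein"
            codon_map = trio.human_codon_map()
            whole_cols = [c for c in codon_map if c is not None]
            whole = gene_dnds(
                trio,
                RegionMask.from_indices(whole_cols, "whole_protein_including_repeat"),
                estimator=config.estimator,
                pairs=config.species_pairs,
            )
            aars = [
                t
                for res in _AA_NON_Q
                for t in find_tracts(protein, res, 4)
            ]

            prot = {
                "gene_id": trio.gene_id,
                "omega_protein": _omega_of(whole),
                "n_pairs_ok": whole.n_pairs_ok,
                "n_codons": len(whole_cols),
                "n_tracts": len(tracts),
            }
            klasses, purities = set(), set()

            for tract in tracts:
                stage = "conservation"
                score = tract_conservation(
                    trio, tract, hc=config.hc, hv=config.hv
                )
                stage = "codon_composition"
                comp = repeat_finder.codon_composition(tract, human_cds)
                stage = "flanks"
                flank = extract_flanks(
                    tract, tracts, len(protein), w=config.window
                )
                flank_noaar = extract_flanks(
                    tract,
                    tracts,
                    len(protein),
                    w=config.window,
                    exclude_other_aars=True,
                    aar_list=aars,
                )
                stage = "dnds_flanks"

                def flank_omega(indices) -> tuple[float, str, int]:
                    cols = windows_to_columns(indices, trio)
                    if not cols:
                        return np.nan, "NA_empty", 0
                    est = gene_dnds(
                        trio,
                        RegionMask.from_indices(cols, "flank"),
                        estimator=config.estimator,
                        pairs=config.species_pairs,
                    )
                    status = "ok" if est.n_pairs_ok else "NA"
                    return _omega_of(est), status, est.n_pairs_ok

                om_flank, st_flank, np_flank = flank_omega(flank.all_indices)
                om_n, _, _ = flank_omega(flank.n_window)
                om_c, _, _ = flank_omega(flank.c_window)
                om_noaar, _, _ = flank_omega(flank_noaar.all_indices)

                klasses.add(score.klass)
                purities.add(comp.purity)
                inv_rows.append(
                    {
                        "protein_id": tract.protein_id,
                        "start": tract.start,
                        "end": tract.end,
                        "length": tract.length,
                        "size_bin": repeat_finder.size_bin(tract),
                        "size_bin3": repeat_finder.size_bin(tract, "3way"),
                        "purity": comp.purity,
                        "frac_cag": comp.frac_cag,
                        "cag_bin": repeat_finder.cag_fraction_bin(comp),
                        "caa_bin": repeat_finder.caa_fraction_bin(comp),
                        "pct_mouse": score.pct_mouse,
                        "pct_rat": score.pct_rat,
                        "conservation_class": score.klass,
                    }
                )
                tract_rows.append(
                    {
                        "protein_id": tract.protein_id,
                        "start": tract.start,
                        "end": tract.end,
                        "purity": comp.purity,
                        "cag_bin": repeat_finder.cag_fraction_bin(comp),
                        "caa_bin": repeat_finder.caa_fraction_bin(comp),
                        "size_bin3": repeat_finder.size_bin(tract, "3way"),
                        "conservation_class": score.klass,
                        "omega_flank": om_flank,
                        "status_flank": st_flank,
                        "n_pairs_ok": np_flank,
                        "omega_flank_n": om_n,
                        "omega_flank_c": om_c,
                        "omega_flank_no_other_aars": om_noaar,
                        "n_window_size": len(flank.n_window),
                        "c_window_size": len(flank.c_window),
                        "n_excluded": flank.n_excluded,
                    }
                )
            prot["has_hc"] = bool(klasses & {"HC", "fully_conserved"})
            prot["has_hv"] = bool(klasses & {"HV", "absent"})
            prot["has_pure_cag"] = "pure_CAG" in purities
            prot["has_mixed"] = "mixed" in purities
            if tracts:
                prot_rows.append(prot)
        except Exception as err:
            raise RuntimeError(
                f"pipeline stage {stage!r} failed on gene {trio.gene_id!r}: {err}"
            ) from err

    inventory = pd.DataFrame(inv_rows)
    protein_df = pd.DataFrame(prot_rows)
    tract_df = pd.DataFrame(tract_rows)
    if inventory.empty:
        warnings.warn("no tracts found; result tables are empty")

    size_hist = _size_histogram(inventory)
    summaries, tests = _comparisons(protein_df, tract_df)

    na_counts = {
        "protein_omega_na": int(protein_df["omega_protein"].isna().sum())
        if not protein_df.empty
        else 0,
        "flank_omega_na": int(tract_df["omega_flank"].isna().sum())
        if not tract_df.empty
        else 0,
    }
    result = PipelineResult(
        config=config,
        tract_inventory=inventory,
        protein_omega=protein_df,
        tract_omega=tract_df,
        size_histogram=size_hist,
        comparison_summaries=summaries,
        comparison_tests=tests,
        na_counts=na_counts,
    )
    if write:
        _write_tables(result, out_dir)
    return result


def _size_histogram(inventory: pd.DataFrame) -> pd.DataFrame:
    """Tract counts per size bin, total and pure-CAG (the histogram surface)."""
    rows = []
    for b in repeat_finder.SIZE_BINS_4WAY:
        if inventory.empty:
            rows.append({"size_bin": b, "n_tracts": 0, "n_pure_cag": 0})
            continue
        sub = inventory[inventory["size_bin"] == b]
        rows.append(
            {
                "size_bin": b,
                "n_tracts": len(sub),
                "n_pure_cag": int((sub["purity"] == "pure_CAG").sum()),
            }
        )
    return pd.DataFrame(rows)


def _ok(series: pd.Series) -> list[float]:
    return [float(v) for v in series.dropna()]


def _comparisons(
    protein_df: pd.DataFrame, tract_df: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    specs: list[tuple[str, dict[str, list[float]], list[tuple[str, str]]]] = []

    def add(name, groups, pairs=None):
        groups = {k: v for k, v in groups.items() if len(v) > 0}
        if pairs is None:
            pairs = list(combinations(groups.keys(), 2))
        pairs = [(a, b) for a, b in pairs if a in groups and b in groups]
        if groups:
            specs.append((name, groups, pairs))

    if not protein_df.empty and not tract_df.empty:
        add(
            "flank_vs_protein",
            {
                "flank": _ok(tract_df["omega_flank"]),
                "protein": _ok(protein_df["omega_protein"]),
            },
            [("flank", "protein")],
        )
    if not protein_df.empty:
        add(
            "protein_HC_vs_HV",
            {
                "HC": _ok(protein_df.loc[protein_df["has_hc"], "omega_protein"]),
                "HV": _ok(protein_df.loc[protein_df["has_hv"], "omega_protein"]),
            },
            [("HC", "HV")],
        )
        add(
            "protein_pure_vs_mixed",
            {
                "pure_CAG": _ok(
                    protein_df.loc[protein_df["has_pure_cag"], "omega_protein"]
                ),
                "mixed": _ok(protein_df.loc[protein_df["has_mixed"], "omega_protein"]),
            },
            [("pure_CAG", "mixed")],
        )
    if not tract_df.empty:
        hc_mask = tract_df["conservation_class"].isin(["HC", "fully_conserved"])
        hv_mask = tract_df["conservation_class"].isin(["HV", "absent"])
        add(
            "flank_HC_vs_HV",
            {
                "HC": _ok(tract_df.loc[hc_mask, "omega_flank"]),
                "HV": _ok(tract_df.loc[hv_mask, "omega_flank"]),
            },
            [("HC", "HV")],
        )
        add(
            "flank_pure_vs_mixed",
            {
                "pure_CAG": _ok(
                    tract_df.loc[tract_df["purity"] == "pure_CAG", "omega_flank"]
                ),
                "mixed": _ok(
                    tract_df.loc[tract_df["purity"] == "mixed", "omega_flank"]
                ),
            },
            [("pure_CAG", "mixed")],
        )
        add(
            "flank_size_bins",
            {
                b: _ok(tract_df.loc[tract_df["size_bin3"] == b, "omega_flank"])
                for b in repeat_finder.SIZE_BINS_3WAY
            },
        )
        add(
            "flank_cag_fraction",
            {
                b: _ok(tract_df.loc[tract_df["cag_bin"] == b, "omega_flank"])
                for b in ("1", "0.5-1", "<=0.5")
            },
        )
        caa_high = tract_df["caa_bin"].isin(["0.5-1", "1"])
        add(
            "flank_caa_control",
            {
                ">0.5": _ok(tract_df.loc[caa_high, "omega_flank"]),
                "<=0.5": _ok(tract_df.loc[~caa_high, "omega_flank"]),
            },
            [(">0.5", "<=0.5")],
        )
        add(
            "flank_N_vs_C",
            {
                "N_terminal": _ok(tract_df["omega_flank_n"]),
                "C_terminal": _ok(tract_df["omega_flank_c"]),
            },
            [("N_terminal", "C_terminal")],
        )
        add(
            "flank_pure_vs_mixed_no_other_aars",
            {
                "pure_CAG": _ok(
                    tract_df.loc[
                        tract_df["purity"] == "pure_CAG", "omega_flank_no_other_aars"
                    ]
                ),
                "mixed": _ok(
                    tract_df.loc[
                        tract_df["purity"] == "mixed", "omega_flank_no_other_aars"
                    ]
                ),
            },
            [("pure_CAG", "mixed")],
        )

    all_summaries, all_tests = [], []
    for name, groups, pairs in specs:
        summary, test = compare_groups(groups, pairs)
        summary.insert(0, "comparison", name)
        test.insert(0, "comparison", name)
        all_summaries.append(summary)
        all_tests.append(test)
    all_summaries = [df for df in all_summaries if not df.empty]
    all_tests = [df for df in all_tests if not df.empty]
    summaries = (
        pd.concat(all_summaries, ignore_index=True) if all_summaries else pd.DataFrame()
    )
    tests = pd.concat(all_tests, ignore_index=True) if all_tests else pd.DataFrame()
    return summaries, tests


def _write_tables(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    header = (
        f"# config_hash={result.config.config_hash()}\n"
        f"# na_counts={result.na_counts}\n"
    )
    for name, df in result.tables().items():
        path = out_dir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
        logger.info("wrote %s (%d rows)", path, len(df))
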