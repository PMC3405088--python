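import filecmp

import numpy as np
import pytest

from polyqsel.dnds import RegionMask, gene_dnds
from polyqsel.seq_io import STANDARD_CODE, read_phylip
from polyqsel.simulate import SimConfig, generate_dataset, simulate_trio


def _translate_region(trio, truth, species, label):
    lo, hi = truth.region_columns[label]
    row = trio.row(species)
    return "".join(
        STANDARD_CODE.amino_acid(row[3 * c : 3 * c + 3])
        for c in range(lo, hi)
        if "-" not in row[3 * c : 3 * c + 3]
    )


def test_zero_branch_lengths_give_identical_rows():
    cfg = SimConfig(
        n_genes=1, n_codons_background=60,
        branch_lengths={"human": 0, "mouse": 0, "rat": 0, "internal": 0},
        slippage_rate=0.0, seed=1,
    )
    trio, truth = simulate_trio(cfg, 0)
    assert trio.rows[0] == trio.rows[1] == trio.rows[2]
    res = gene_dnds(trio, RegionMask.from_indices(truth.whole_columns, "whole"))
    assert res.omega_mean is None
    assert all(e.status == "NA_zero_dS" for e in res.per_pair.values())


def test_zero_omega_means_no_amino_acid_changes_outside_tract():
    cfg = SimConfig(
        n_genes=1, n_codons_background=200, omega_background=0.0,
        omega_flank=0.0, slippage_rate=0.0, seed=2,
    )
    for g in range(5):
        trio, truth = simulate_trio(cfg, g)
        for label in ("bg_left", "flank_n", "flank_c", "bg_right"):
            human = _translate_region(trio, truth, "human", label)
            for sp in ("mouse", "rat"):
                assert _translate_region(trio, truth, sp, label) == human
        assert all(
            truth.substitutions[r]["nonsyn"] == 0
            for r in ("bg_left", "flank_n", "flank_c", "bg_right")
        )


def test_slippage_varies_tract_length_across_species():
    cfg = SimConfig(
        n_genes=100, n_codons_background=12, tract_len0=6,
        tract_purity="pure_CAG", slippage_rate=0.3, seed=3,
    )
    varied = 0
    for g in range(100):
        _trio, truth = simulate_trio(cfg, g)
        if len(set(truth.tract_len.values())) > 1:
            varied += 1
    assert varied >= 90


def test_slippage_preserves_glutamine():
    cfg = SimConfig(n_genes=1, n_codons_background=12, slippage_rate=0.5, seed=4)
    for g in range(20):
        trio, truth = simulate_trio(cfg, g)
        for sp in ("human", "mouse", "rat"):
            aa = _translate_region(trio, truth, sp, "tract")
            assert set(aa) <= {"Q"}
            assert len(aa) == truth.tract_len[sp]


def test_mixed_tract_purity():
    cfg = SimConfig(
        n_genes=1, n_codons_background=12, tract_len0=20,
        tract_purity="mixed", frac_cag=0.5, slippage_rate=0.0,
        branch_lengths={"human": 0, "mouse": 0, "rat": 0, "internal": 0}, seed=5,
    )
    trio, truth = simulate_trio(cfg, 0)
    lo, hi = truth.region_columns["tract"]
    codons = {trio.row("human")[3 * c : 3 * c + 3] for c in range(lo, hi)}
    assert codons == {"CAG", "CAA"}


def test_generate_dataset_deterministic_and_readable(tmp_path):
    cfg = SimConfig(n_genes=5, n_codons_background=40, seed=6)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    trios1, _ = generate_dataset(cfg, d1)
    trios2, _ = generate_dataset(cfg, d2)
    for name in ("trios.phy", "tracts.tsv", "truth.tsv"):
        assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name
    back = read_phylip(d1 / "trios.phy")
    assert len(back) == 5
    assert [t.rows for t in back] == [t.rows for t in trios1]


def test_different_seeds_differ():
    cfg_a = SimConfig(n_genes=1, n_codons_background=60, seed=7)
    cfg_b = SimConfig(n_genes=1, n_codons_background=60, seed=8)
    ta, _ = simulate_trio(cfg_a, 0)
    tb, _ = simulate_trio(cfg_b, 0)
    assert ta.rows != tb.rows


def test_neutral_null_calibration():
    """At omega=1, kappa=1 the realized dN/dS should be close to 1."""
    cfg = SimConfig(
        n_genes=50, n_codons_background=400, omega_background=1.0,
        omega_flank=1.0, omega_tract=1.0, kappa=1.0, slippage_rate=0.0, seed=9,
    )
    omegas = []
    for g in range(50):
        trio, truth = simulate_trio(cfg, g)
        res = gene_dnds(
            trio, RegionMask.from_indices(truth.whole_columns, "whole"),
            estimator="ng86",
        )
        if res.omega_mean is not None:
            omegas.append(res.omega_mean)
    assert np.mean(omegas) == pytest.approx(1.0, rel=0.10)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(tract_len0=3)
    with pytest.raises(ValueError):
        SimConfig(kappa=0)
    with pytest.raises(ValueError):
        SimConfig(omega_background=-0.1)
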