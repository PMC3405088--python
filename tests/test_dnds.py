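import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from polyqsel.dnds import (
    CODONS,
    RegionMask,
    dnds_ng86,
    dnds_yn00,
    gene_dnds,
    ng86_differences,
    ng86_sites,
    yn00_kappa,
)
from polyqsel.seq_io import TrioAlignment
from polyqsel.simulate import SimConfig, simulate_trio

# ---------------------------------------------------------------------------
# Independent oracles (Biopython translation, explicit enumeration)
# ---------------------------------------------------------------------------

STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str) -> tuple[float, float]:
    s = n = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            target = codon[:pos] + nt + codon[pos + 1 :]
            if target in STOPS:
                continue
            if _aa(target) == _aa(codon):
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def oracle_differences(c1: str, c2: str) -> tuple[float, float]:
    """Enumerate every ordering of the differing positions explicitly."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(positions):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return 0.0, 0.0
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "codon,s,n",
    [("TTT", 1 / 3, 8 / 3), ("GGG", 1.0, 2.0), ("ATG", 0.0, 3.0)],
)
def test_ng86_sites_examples(codon, s, n):
    got_s, got_n = ng86_sites(codon)
    assert got_s == pytest.approx(s)
    assert got_n == pytest.approx(n)


def test_ng86_sites_rejects_stop_and_ambiguous():
    with pytest.raises(ValueError):
        ng86_sites("TAA")
    with pytest.raises(ValueError):
        ng86_sites("ANG")


@pytest.mark.parametrize(
    "c1,c2,sd,nd",
    [("AAA", "AAG", 1, 0), ("TTT", "TTA", 0, 1), ("TTT", "GTA", 0.5, 1.5)],
)
def test_ng86_differences_examples(c1, c2, sd, nd):
    got = ng86_differences(c1, c2)
    assert got[0] == pytest.approx(sd)
    assert got[1] == pytest.approx(nd)


def test_ng86_counting_agrees_with_enumeration_sample():
    rng = np.random.default_rng(42)
    for c in CODONS:
        assert ng86_sites(c) == pytest.approx(oracle_sites(c))
    for _ in range(300):
        c1, c2 = (CODONS[i] for i in rng.integers(61, size=2))
        assert ng86_differences(c1, c2) == pytest.approx(oracle_differences(c1, c2))


def test_ng86_differences_symmetric_and_complete():
    rng = np.random.default_rng(1)
    for _ in range(100):
        c1, c2 = (CODONS[i] for i in rng.integers(61, size=2))
        sd, nd = ng86_differences(c1, c2)
        sd2, nd2 = ng86_differences(c2, c1)
        assert (sd, nd) == pytest.approx((sd2, nd2))
        k = sum(a != b for a, b in zip(c1, c2))
        if sd + nd > 0:
            assert sd + nd == pytest.approx(k)


def test_dnds_identical_sequences_is_na():
    est = dnds_ng86("AAATTTGGG", "AAATTTGGG")
    assert est.Sd == est.Nd == 0
    assert est.dS == est.dN == 0
    assert est.status == "NA_zero_dS"
    assert est.omega is None


def test_dnds_single_synonymous_difference():
    est = dnds_ng86("AAA", "AAG")
    assert est.Sd == pytest.approx(1)
    assert est.Nd == pytest.approx(0)
    assert est.dN == 0.0


def test_dnds_symmetric_under_sequence_swap():
    rng = np.random.default_rng(3)
    c1 = [CODONS[i] for i in rng.integers(61, size=150)]
    c2 = [c if rng.random() < 0.85 else CODONS[rng.integers(61)] for c in c1]
    for fn in (dnds_ng86, dnds_yn00):
        a, b = fn(c1, c2), fn(c2, c1)
        assert a.S == pytest.approx(b.S)
        assert a.Sd == pytest.approx(b.Sd)
        assert a.omega == pytest.approx(b.omega)


def test_counting_additive_over_concatenation():
    rng = np.random.default_rng(4)
    part_a = [CODONS[i] for i in rng.integers(61, size=60)]
    part_b = [CODONS[i] for i in rng.integers(61, size=60)]
    mut = lambda cs: [c if rng.random() < 0.8 else CODONS[rng.integers(61)] for c in cs]
    a2, b2 = mut(part_a), mut(part_b)
    whole = dnds_ng86(part_a + part_b, a2 + b2)
    ea, eb = dnds_ng86(part_a, a2), dnds_ng86(part_b, b2)
    assert whole.Sd == pytest.approx(ea.Sd + eb.Sd)
    assert whole.Nd == pytest.approx(ea.Nd + eb.Nd)
    assert whole.S == pytest.approx(ea.S + eb.S)


def test_pairwise_deletion_drops_gapped_and_ambiguous_columns():
    est = dnds_ng86(["AAA", "---", "TTN", "GGG"], ["AAA", "CCC", "TTT", "GGG"])
    assert est.n_codons == 2


def test_empty_mask_is_na_empty():
    est = dnds_ng86([], [])
    assert est.status == "NA_empty"


# ---------------------------------------------------------------------------
# YN00
# ---------------------------------------------------------------------------

def test_yn00_limit_matches_ng86_counts():
    rng = np.random.default_rng(5)
    c1 = [CODONS[i] for i in rng.integers(61, size=300)]
    c2 = [c if rng.random() < 0.9 else CODONS[rng.integers(61)] for c in c1]
    a = dnds_ng86(c1, c2)
    b = dnds_yn00(c1, c2, kappa=1.0, codon_freqs="uniform")
    assert b.S == pytest.approx(a.S, abs=1e-9)
    assert b.N == pytest.approx(a.N, abs=1e-9)
    assert b.Sd == pytest.approx(a.Sd, abs=1e-9)
    assert b.Nd == pytest.approx(a.Nd, abs=1e-9)
    # distances use K80 vs JC corrections; at kappa=1 they nearly coincide
    assert b.omega == pytest.approx(a.omega, rel=0.05)


def test_yn00_identical_sequences_is_na():
    est = dnds_yn00("AAATTTGGG", "AAATTTGGG")
    assert est.status == "NA_zero_dS"
    assert est.dS == est.dN == 0


def test_yn00_kappa_transitions_at_fourfold_sites():
    # GGA <-> GGG differ by an A<->G transition at a fourfold position
    c1 = ["GGA"] * 20 + ["AAA"] * 40
    c2 = ["GGG"] * 5 + ["GGA"] * 15 + ["AAA"] * 40
    assert yn00_kappa(c1, c2) > 1.0


def test_yn00_kappa_falls_back_to_one():
    with pytest.warns(UserWarning, match="kappa"):
        assert yn00_kappa([], []) == 1.0


def test_kappa_recovery_from_simulation():
    cfg = SimConfig(
        n_genes=1, n_codons_background=10000, omega_background=0.3,
        omega_flank=0.3, kappa=4.0, slippage_rate=0.0, seed=21,
    )
    trio, truth = simulate_trio(cfg, 0)
    res = gene_dnds(
        trio, RegionMask.from_indices(truth.mask_columns("bg_left", "bg_right"), "bg")
    )
    kappas = [e.kappa for e in res.per_pair.values()]
    assert np.mean(kappas) == pytest.approx(4.0, rel=0.25)


def test_ng86_omega_recovery_kappa_one():
    cfg = SimConfig(
        n_genes=1, n_codons_background=10000, omega_background=0.2,
        omega_flank=0.2, kappa=1.0, slippage_rate=0.0, seed=22,
    )
    trio, truth = simulate_trio(cfg, 0)
    res = gene_dnds(
        trio,
        RegionMask.from_indices(truth.mask_columns("bg_left", "bg_right"), "bg"),
        estimator="ng86",
    )
    assert res.omega_mean == pytest.approx(0.2, rel=0.15)


# ---------------------------------------------------------------------------
# Per-gene averaging over trios
# ---------------------------------------------------------------------------

def test_gene_dnds_identical_trio_is_na(simple_trio):
    res = gene_dnds(simple_trio, RegionMask.from_indices(range(7), "whole"))
    assert res.omega_mean is None
    assert res.n_pairs_ok == 0


def test_gene_dnds_mean_over_ok_pairs():
    rng = np.random.default_rng(6)
    base = "".join(CODONS[i] for i in rng.integers(61, size=200))
    mut = "".join(
        c if rng.random() < 0.9 else CODONS[rng.integers(61)]
        for c in (base[i : i + 3] for i in range(0, len(base), 3))
    )
    # rat identical to human -> that pair is NA_zero_dS; other two pairs ok
    trio = TrioAlignment("g", rows=(base, mut, base))
    res = gene_dnds(trio, RegionMask.from_indices(range(200), "whole"))
    assert res.n_pairs_ok == 2
    oks = [e.omega for e in res.per_pair.values() if e.ok]
    assert res.omega_mean == pytest.approx(np.mean(oks))
    assert res.per_pair[("human", "rat")].status == "NA_zero_dS"


def test_gene_dnds_human_only_mode(diverged_trio):
    res = gene_dnds(
        diverged_trio, RegionMask.from_indices(range(9), "whole"), pairs="human_only"
    )
    assert set(res.per_pair) == {("human", "mouse"), ("human", "rat")}
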