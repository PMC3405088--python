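import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyqsel.repeat_finder import (
    Tract,
    caa_fraction_bin,
    cag_fraction_bin,
    codon_composition,
    find_tracts,
    longest_isoform_per_gene,
    read_tract_table,
    size_bin,
    tract_table,
    write_tract_table,
)
from polyqsel.seq_io import NamedSequence


def _brute_force_runs(s: str, residue: str, min_len: int):
    """Oracle: scan every position and grow runs one by one."""
    runs = []
    i = 0
    while i < len(s):
        if s[i] == residue:
            j = i
            while j < len(s) and s[j] == residue:
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def test_find_tracts_basic():
    tracts = find_tracts(NamedSequence("p", "AAQQQQAA"))
    assert [(t.start, t.end, t.length) for t in tracts] == [(2, 6, 4)]


def test_find_tracts_below_threshold():
    assert find_tracts(NamedSequence("p", "QQQ")) == []


def test_find_tracts_long_run_is_single_tract():
    # a 17-glutamine run (huntingtin-like) is one tract, never several of 4
    prot = NamedSequence("htt", "MA" + "Q" * 17 + "PA")
    tracts = find_tracts(prot)
    assert len(tracts) == 1
    assert tracts[0].length == 17


def test_find_tracts_invalid_residue():
    with pytest.raises(ValueError, match="residue"):
        find_tracts(NamedSequence("p", "QQQQ"), residue="B")
    with pytest.raises(ValueError, match="min_len"):
        find_tracts(NamedSequence("p", "QQQQ"), min_len=1)


@settings(derandomize=True, max_examples=200)
@given(
    st.text(alphabet="QAR", min_size=1, max_size=50),
    st.integers(min_value=2, max_value=6),
)
def test_find_tracts_matches_brute_force(s, min_len):
    got = [(t.start, t.end) for t in find_tracts(NamedSequence("p", s + "A"), "Q", min_len)]
    assert got == _brute_force_runs(s + "A", "Q", min_len)


@settings(derandomize=True, max_examples=100)
@given(st.text(alphabet="QA", min_size=4, max_size=40))
def test_tracts_disjoint_maximal_and_padding_invariant(s):
    prot = NamedSequence("p", s + "A")
    tracts = find_tracts(prot)
    # disjoint + sorted
    for a, b in zip(tracts, tracts[1:]):
        assert a.end <= b.start
    # maximality: flanking residues differ from Q
    for t in tracts:
        if t.start > 0:
            assert prot.residues[t.start - 1] != "Q"
        if t.end < len(prot):
            assert prot.residues[t.end] != "Q"
    # padding with non-Q shifts coordinates but preserves spans
    padded = find_tracts(NamedSequence("p", "AAA" + prot.residues))
    assert [(t.start - 3, t.end - 3) for t in padded] == [
        (t.start, t.end) for t in tracts
    ]


@pytest.mark.parametrize(
    "codons,purity,n_cag,frac",
    [
        ("CAGCAGCAGCAG", "pure_CAG", 4, 1.0),
        ("CAACAACAACAA", "pure_CAA", 0, 0.0),
        ("CAGCAACAGCAG", "mixed", 3, 0.75),
    ],
)
def test_codon_composition(codons, purity, n_cag, frac):
    cds = NamedSequence("p", codons)
    comp = codon_composition(Tract("p", "Q", 0, 4), cds)
    assert comp.purity == purity
    assert comp.n_cag == n_cag
    assert comp.frac_cag == frac
    assert comp.n_cag + comp.n_caa + comp.n_other == 4


def test_codon_composition_mismatch_errors():
    cds = NamedSequence("p", "CAGCAGTTTCAG")  # TTT is Phe, not Gln
    with pytest.raises(ValueError, match="mismatch"):
        codon_composition(Tract("p", "Q", 0, 4), cds)


@pytest.mark.parametrize(
    "length,four,three",
    [(4, "4", "4-5"), (5, "5", "4-5"), (6, "6-9", "6-9"), (9, "6-9", "6-9"),
     (10, "10+", "10+"), (40, "10+", "10+")],
)
def test_size_bins(length, four, three):
    assert size_bin(length) == four
    assert size_bin(length, "3way") == three


def test_size_bin_rejects_short():
    with pytest.raises(ValueError):
        size_bin(3)


@pytest.mark.parametrize(
    "codons,expected",
    [("CAGCAGCAGCAG", "1"), ("CAGCAACAGCAA", "<=0.5"), ("CAGCAACAGCAG", "0.5-1")],
)
def test_cag_fraction_bin(codons, expected):
    comp = codon_composition(Tract("p", "Q", 0, 4), NamedSequence("p", codons))
    assert cag_fraction_bin(comp) == expected


def test_caa_fraction_bin_control():
    comp = codon_composition(Tract("p", "Q", 0, 4), NamedSequence("p", "CAACAACAACAA"))
    assert caa_fraction_bin(comp) == "1"
    assert cag_fraction_bin(comp) == "<=0.5"


def test_longest_isoform_per_gene():
    prots = [
        NamedSequence("iso1", "MQQ"),
        NamedSequence("iso2", "MQQQQ"),
        NamedSequence("other", "MA"),
    ]
    kept = longest_isoform_per_gene(prots, gene_of={"iso1": "g", "iso2": "g"})
    assert [p.id for p in kept] == ["iso2", "other"]


def test_tract_table_roundtrip(tmp_path):
    cds = NamedSequence("p", "ATG" + "CAG" * 4 + "TTT")
    table = tract_table([(Tract("p", "Q", 1, 5), cds)])
    assert table.loc[0, "codon_string"] == "CAGCAGCAGCAG"
    assert table.loc[0, "purity"] == "pure_CAG"
    path = tmp_path / "tracts.tsv"
    write_tract_table(table, path)
    back = read_tract_table(path)
    pd.testing.assert_frame_equal(back, table)


def test_read_tract_table_missing_columns(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("protein_id\tstart\np\t1\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_tract_table(path)
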