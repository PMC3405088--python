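import pytest

from polyqsel.seq_io import NamedSequence, TrioAlignment
from polyqsel.simulate import SimConfig, simulate_trio


@pytest.fixture
def simple_trio() -> TrioAlignment:
    """Ungapped trio: ATG + 5xCAG tract + TTT tail on every row."""
    row = "ATG" + "CAG" * 5 + "TTT"
    return TrioAlignment("g1", rows=(row, row, row))


@pytest.fixture
def diverged_trio() -> TrioAlignment:
    """Trio with a synonymous and a nonsynonymous difference in the rodents."""
    human = "ATG" + "CAG" * 5 + "TTTAAAGGG"
    mouse = "ATG" + "CAA" + "CAG" * 4 + "TTTAAAGGG"  # CAG->CAA synonymous
    rat = "ATG" + "CAG" * 5 + "TTTAAAGGA"  # GGG->GGA synonymous
    return TrioAlignment("g2", rows=(human, mouse, rat))


@pytest.fixture(scope="session")
def small_sim_trio():
    cfg = SimConfig(
        n_genes=1, n_codons_background=60, tract_len0=6, seed=11, slippage_rate=0.1
    )
    return simulate_trio(cfg, 0)
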