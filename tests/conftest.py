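import pytest

from m6amir import MatureMiRNA, SimulationConfig, normalize_sequence, simulate_all

# canonical mature sequences (miRBase), 5'->3'
MIR133A_3P = "UUUGGUCCCCUUCAACCAGCUG"
MIR499_5P = "UUAAGACUUGCAGUGAUGUUU"


@pytest.fixture(scope="session")
def mir133a():
    return MatureMiRNA(
        name="mmu-miR-133a-3p",
        sequence=normalize_sequence(MIR133A_3P, seq_id="mmu-miR-133a-3p"),
    )


@pytest.fixture(scope="session")
def mir499():
    return MatureMiRNA(
        name="mmu-miR-499-5p",
        sequence=normalize_sequence(MIR499_5P, seq_id="mmu-miR-499-5p"),
    )


@pytest.fixture(scope="session")
def small_simulation():
    """A small but fully structured synthetic study, shared across tests."""
    cfg = SimulationConfig(
        rng_seed=11, n_genes=150, n_mirnas=40, n_full_match=2, n_partial_match=5
    )
    return simulate_all(cfg)
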