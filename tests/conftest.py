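import numpy as np
import pytest

from barcodelib.library_model import Library, make_record
from barcodelib.synthetic_data import SimulationConfig, simulate_library


def rec(sample_id, species, marker="COI", seq="ACGTACGTACGT", **kw):
    """Shorthand record builder for toy libraries."""
    return make_record(sample_id, species, marker, seq, **kw)


@pytest.fixture(scope="session")
def random_seq():
    rng = np.random.default_rng(7)

    def _make(length, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return "".join(r.choice(list("ACGT"), size=length))

    return _make


@pytest.fixture(scope="session")
def clean_sim():
    """Small clean simulated library shared across tests (seed 42)."""
    config = SimulationConfig(seed=42)
    library, panel, truth = simulate_library(config)
    return config, library, panel, truth


@pytest.fixture(scope="session")
def anomalous_sim():
    """Seed-42 library with all three anomalies switched on."""
    config = SimulationConfig(
        seed=42,
        shared_haplotype_pair=True,
        deep_split_species=True,
        orphan_lineage=True,
    )
    library, panel, truth = simulate_library(config)
    return config, library, panel, truth


@pytest.fixture
def toy_library():
    """2 genera x 2 species x 2 samples, distinct sequences."""
    seqs = {
        ("GenusA", 1): "AAAAAAAAAACCCCCCCCCC",
        ("GenusA", 2): "AAAAAAAAAAGGGGGGGGGG",
        ("GenusB", 1): "TTTTTTTTTTCCCCCCCCCC",
        ("GenusB", 2): "TTTTTTTTTTGGGGGGGGGG",
    }
    records = []
    i = 0
    for (genus, sp), base in seqs.items():
        for k in range(2):
            i += 1
            # two samples per species, one substitution apart
            seq = base if k == 0 else base[:-1] + ("A" if base[-1] != "A" else "C")
            records.append(rec(f"T{i:02d}", f"{genus} species{sp}", seq=seq))
    return Library(records)
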