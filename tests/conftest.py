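import numpy as np
import pandas as pd
import pytest

from benthocouple import AsvTable, GeneratorConfig, generate_coupled_communities


@pytest.fixture
def toy_table() -> AsvTable:
    """4 samples x 5 ASVs covering the filter edge cases: an abundant
    prevalent ASV, a 50-in-3 borderline ASV, a single-sample blip, a
    singleton, and a low-count prevalent ASV."""
    counts = pd.DataFrame(
        {
            "ASV_a": [120, 80, 60, 90],
            "ASV_b": [50, 50, 50, 0],
            "ASV_c": [200, 0, 0, 0],
            "ASV_d": [1, 0, 0, 0],
            "ASV_e": [10, 10, 10, 10],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    taxonomy = pd.DataFrame(
        {
            "division": ["Diatomea", "Diatomea", "Dinoflagellata", "Cercozoa", "Cercozoa"],
            "class": ["c1", "c1", "c2", "c3", "c3"],
            "order": ["o1", "o1", "o2", "o3", "o3"],
            "family": ["f1", "f1", "f2", "f3", "f4"],
            "genus": ["g1", "g2", "g3", "g4", "g5"],
            "species": ["sp1", "sp2", "sp3", "sp4", "sp5"],
        },
        index=counts.columns,
    )
    seqs = {a: "ACGT" * 100 for a in counts.columns}
    return AsvTable(counts, taxonomy, seqs)


@pytest.fixture(scope="session")
def synth_study():
    """One default-condition synthetic study shared across tests."""
    return generate_coupled_communities(GeneratorConfig(seed=7))
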