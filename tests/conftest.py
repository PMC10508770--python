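import numpy as np
import pandas as pd
import pytest

from kinleak.datasets import BioactivityTable
from kinleak.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 40 kinases x 120 inhibitors, 4,800 records."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced matrix for fast unit tests (9 kinases x 20 inhibitors)."""
    cfg = GeneratorConfig(n_families=3, kinases_per_family=3,
                          n_scaffolds=5, analogs_per_scaffold=4, seed=7)
    return generate_dataset(cfg)


@pytest.fixture()
def toy_table():
    """Hand-built 12-record table over 4 kinases x 3 inhibitors."""
    kinases = {f"K{i}": "A" * 85 for i in range(4)}
    smiles = {"I0": "CCO", "I1": "CCN", "I2": "c1ccccc1O"}
    rows = []
    label = 5.0
    for k, seq in kinases.items():
        for i, s in smiles.items():
            rows.append({"kinase_id": k, "klifs_sequence": seq,
                         "inhibitor_id": i, "smiles": s,
                         "label": label, "label_type": "pAct"})
            label += 0.25
    return BioactivityTable(pd.DataFrame(rows), name="toy")


def random_table(rng, n_kinases=5, n_inhibitors=8):
    """Random complete table used by split-invariant sweeps."""
    rows = []
    for k in range(n_kinases):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=85))
        for i in range(n_inhibitors):
            rows.append({"kinase_id": f"K{k}", "klifs_sequence": seq,
                         "inhibitor_id": f"I{i}", "smiles": "C" * (i + 1),
                         "label": float(rng.normal()), "label_type": "pAct"})
    return BioactivityTable(pd.DataFrame(rows), name="random")
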