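import numpy as np
import pandas as pd
import pytest

from bmasc.config import SimulationConfig
from bmasc.synthetic import simulate_expression, simulate_repertoire


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_cells=300, n_genes=400, n_clusters=4,
                            n_lineages=60, seed=7)


@pytest.fixture(scope="session")
def small_expression(small_config):
    return simulate_expression(small_config)


@pytest.fixture(scope="session")
def small_repertoire(small_config, small_expression):
    _, truth = small_expression
    return simulate_repertoire(small_config, truth.cluster_labels)


def random_repertoire(rng: np.random.Generator, n_records: int,
                      n_vj: int = 3, cdr3_len_choices=(12, 15)) -> pd.DataFrame:
    """Minimal random rearrangement table for lineage-clustering tests."""
    rows = []
    for i in range(n_records):
        length = int(rng.choice(cdr3_len_choices))
        rows.append({
            "sequence_id": f"r{i:03d}",
            "cell_id": f"c{i:03d}",
            "subject_id": f"S{rng.integers(2)}",
            "v_call": f"IGHV{rng.integers(1, n_vj + 1)}-1*01",
            "j_call": f"IGHJ{rng.integers(1, 3)}*01",
            "cdr3": "".join(rng.choice(list("ACGT"), length)),
        })
    return pd.DataFrame(rows)
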