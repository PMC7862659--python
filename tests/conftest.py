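import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from tuberome import (CountTable, SimulationConfig, StudyMetadata,
                      generate_study)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_counts_path() -> Path:
    return DATA / "toy_counts.tsv"


@pytest.fixture(scope="session")
def toy_metadata_path() -> Path:
    return DATA / "toy_metadata.tsv"


@pytest.fixture(scope="session")
def toy_study(toy_counts_path, toy_metadata_path):
    from tuberome import read_count_table, read_metadata
    table = read_count_table(toy_counts_path)
    return table, read_metadata(toy_metadata_path).aligned_to(table)


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale synthetic study with planted effects (cached per session)."""
    cfg = SimulationConfig(n_otus=150, n_shift_otus=15, n_long_otus=5,
                           n_short_otus=5, seed=11)
    return generate_study(cfg), cfg


def random_count_table(rng: np.random.Generator, n_samples: int = 6,
                       n_otus: int = 8, max_count: int = 50) -> CountTable:
    counts = rng.integers(0, max_count, size=(n_samples, n_otus))
    counts[:, 0] += 1  # keep sample totals positive
    return CountTable([f"S{i}" for i in range(n_samples)],
                      [f"O{j}" for j in range(n_otus)], counts)


def study_metadata_frame(n_cultivars=2, n_soils=2, timepoints=("T2", "T6"),
                         reps=3, days=None) -> pd.DataFrame:
    from tuberome.io_tables import CULTIVARS, SOILS
    rows = []
    b = 0
    for c in CULTIVARS[:n_cultivars]:
        for s in SOILS[:n_soils]:
            d = days[b] if days is not None else 140 + 5 * b
            b += 1
            for tp in timepoints:
                for r in range(1, reps + 1):
                    rows.append(dict(sample_id=f"{c}_{tp}_{s}_{r}",
                                     cultivar=c, soil=s, timepoint=tp,
                                     replicate=r, storage_days=d))
    return pd.DataFrame(rows)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*replicates.*")
        yield
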