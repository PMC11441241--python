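import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lipidflow.nomenclature import parse_shorthand

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from lipidflow.preprocess import IntensityTable


def make_table(values: dict[str, list], samples: pd.DataFrame,
               stage: str = "median_normalized") -> IntensityTable:
    """Build a small IntensityTable from name -> per-sample values."""
    frame = pd.DataFrame(values, index=samples.index).T
    species = {name: parse_shorthand(name) for name in frame.index}
    return IntensityTable(frame.astype(float), samples, species, stage=stage)


def make_samples(n_sets: int = 2, n_reps: int = 3,
                 conditions=("control", "hypoxia")) -> pd.DataFrame:
    rows = []
    for s in range(1, n_sets + 1):
        for cond in conditions:
            for r in range(1, n_reps + 1):
                rows.append({
                    "sample_id": f"set{s}_{cond}_{r}", "condition": cond,
                    "set_id": f"set{s}", "replicate": r, "is_blank": False,
                })
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture(scope="session")
def default_dataset():
    from lipidflow.synthdata import SyntheticConfig, generate

    return generate(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    from lipidflow.pipeline import run_pipeline

    ds = default_dataset
    return run_pipeline(ds.raw, ds.injections, ds.standards)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
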