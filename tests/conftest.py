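import numpy as np
import pandas as pd
import pytest

from xscnd.datamodel import IntensityMatrix
from xscnd.simulate import SimulationConfig, simulate_dataset


def make_matrix(values: dict[str, list[float]], species_reps: list[tuple[str, str, int]],
                probes: list[tuple[str, int]], log_scale: bool = False) -> IntensityMatrix:
    """Small-matrix helper: values keyed by sample id, probes as (pid, idx)."""
    index = pd.MultiIndex.from_tuples(probes, names=["probeset_id", "probe_index"])
    samples = pd.DataFrame(species_reps, columns=["sample_id", "species", "replicate"]).set_index("sample_id")
    frame = pd.DataFrame(values, index=index)[list(samples.index)]
    return IntensityMatrix(frame.astype(float), samples, log_scale=log_scale)


def relabel_species(m: IntensityMatrix, species: str) -> IntensityMatrix:
    """Copy a matrix under a new species label (same values, new sample ids)."""
    new_ids = [f"{species}_r{int(r)}" for r in m.samples["replicate"]]
    values = m.values.copy()
    values.columns = new_ids
    samples = pd.DataFrame(
        {"species": species, "replicate": m.samples["replicate"].to_numpy()},
        index=pd.Index(new_ids, name="sample_id"),
    )
    return IntensityMatrix(values, samples, m.mask.copy(), m.log_scale)


@pytest.fixture(scope="session")
def small_dataset():
    """300-gene synthetic dataset shared by fast unit tests."""
    return simulate_dataset(SimulationConfig(seed=101, n_genes=300))
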