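import numpy as np
import pandas as pd
import pytest

from domcascade.dataset_io import SampleMetadata, build_dataset
from domcascade.synthetic_data import SimulationConfig, generate_library


@pytest.fixture(scope="session")
def default_library():
    """One deterministic 3000-formula library shared across tests."""
    return generate_library(SimulationConfig(seed=2024))


@pytest.fixture()
def toy_dataset():
    """3 samples, 4 formulas spanning several compound classes.

    C16H32O2 (lipid-like) is present everywhere; C9H10O4 and C18H20O8
    (lignin-like) and C6H12O6 (carbohydrate-like) are patchy.
    """
    tables = {
        "s1": pd.Series({"C16H32O2": 0.4, "C9H10O4": 0.3, "C18H20O8": 0.2, "C6H12O6": 0.1}),
        "s2": pd.Series({"C16H32O2": 0.7, "C9H10O4": 0.3}),
        "s3": pd.Series({"C16H32O2": 0.5, "C18H20O8": 0.5}),
    }
    metadata = [
        SampleMetadata("s1", "A", "shoulder", 5.0, "soil"),
        SampleMetadata("s2", "A", "back", 5.0, "soil"),
        SampleMetadata("s3", "A", "stream", None, "stream"),
    ]
    return build_dataset(tables, metadata)
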