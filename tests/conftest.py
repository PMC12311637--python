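import numpy as np
import pandas as pd
import pytest

from fracnet.tables import AsvTable


@pytest.fixture
def toy_counts():
    """12-sample, 4-season count table with hand-checkable structure."""
    rng = np.random.default_rng(42)
    seasons = ["winter", "spring", "summer", "autumn"] * 3
    data = rng.integers(0, 50, size=(12, 8))
    frame = pd.DataFrame(
        data,
        index=[f"s{i}" for i in range(12)],
        columns=[f"asv{j}" for j in range(8)],
    )
    meta = pd.DataFrame(
        {"season": seasons, "layer": ["surface", "bottom"] * 6, "station": "S1"},
        index=frame.index,
    )
    return AsvTable(data=frame, fraction="bacteria", sample_metadata=meta)


def make_table(values, fraction="pico", seasons=None, columns=None, is_relative=False):
    values = np.asarray(values)
    index = [f"s{i}" for i in range(values.shape[0])]
    columns = columns or [f"asv{j}" for j in range(values.shape[1])]
    meta = None
    if seasons is not None:
        meta = pd.DataFrame({"season": seasons}, index=index)
    return AsvTable(
        data=pd.DataFrame(values, index=index, columns=columns),
        fraction=fraction,
        sample_metadata=meta,
        is_relative=is_relative,
    )
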