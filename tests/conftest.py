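import numpy as np
import pandas as pd
import pytest

from rumenage.tables import AGE_GROUP_DAYS, FeatureTable, SampleMetadata

THREE_TIP_TREE = "((A:1,B:2):3,C:4);"


@pytest.fixture
def tiny_table():
    counts = pd.DataFrame(
        [[3, 0], [1, 2]], index=["s1", "s2"], columns=["A", "B"]
    )
    return FeatureTable(counts, "bacteria")


def make_metadata(groups_per_sample: dict[str, str]) -> SampleMetadata:
    rows = [
        {"sample_id": sid, "animal_id": f"an_{sid}", "age_group": g,
         "age_days": AGE_GROUP_DAYS[g]}
        for sid, g in groups_per_sample.items()
    ]
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture
def group_table_and_metadata():
    """Twelve samples in two age groups with hand-set abundance patterns."""
    rng = np.random.default_rng(7)
    samples = [f"s{i}" for i in range(12)]
    groups = {s: ("7d" if i < 6 else "12y") for i, s in enumerate(samples)}
    counts = pd.DataFrame(
        rng.integers(50, 200, size=(12, 4)),
        index=samples, columns=["t1", "t2", "t3", "t4"],
    )
    return FeatureTable(counts, "bacteria"), make_metadata(groups)
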