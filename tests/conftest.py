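import numpy as np
import pandas as pd
import pytest

from esmstaging.descriptives import assign_quartile_groups
from esmstaging.synthetic_esm import (
    GeneratorConfig,
    apply_validity_filter,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size default study, validity-filtered (shared, read-only)."""
    cfg = GeneratorConfig(seed=42)
    ds = generate_dataset(cfg)
    ds, _ = apply_validity_filter(ds, cfg.min_valid)
    return ds


@pytest.fixture(scope="session")
def default_grouping(default_dataset):
    return assign_quartile_groups(default_dataset.person_severity())


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale study for model-fitting tests."""
    cfg = GeneratorConfig(
        n_persons=80, n_days=2, beeps_per_day=6, response_prob=0.95,
        min_valid=6, seed=7,
    )
    ds = generate_dataset(cfg)
    ds, _ = apply_validity_filter(ds, cfg.min_valid)
    return ds


def make_manual_dataset(rows):
    """Tiny hand-written EsmDataset from (family, person, day, beep, na, pa, par, scl)."""
    from esmstaging.synthetic_esm import EsmDataset

    frame = pd.DataFrame(
        rows,
        columns=["family_id", "person_id", "day", "beep", "na", "pa", "par", "scl"],
    )
    return EsmDataset(frame=frame, provenance="manual")
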