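import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import retwatch as rw

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def knowledge():
    return rw.load_knowledge_table()


@pytest.fixture
def three_clone_truth():
    """Noise-free 3-clone patient: responding driver clone, two clones
    emerging at distinct progression days."""
    truth = rw.simulate_tracking_patient(seed=3, n_clones=3, noise_free=True)
    return truth, truth.config


def trajectories_from_pileup(pileup: pd.DataFrame) -> pd.DataFrame:
    """Turn a plasma pileup into a long trajectory table via the caller."""
    rows = []
    for day, sub in pileup.groupby("day"):
        for c in rw.call_plasma_variants(sub):
            rows.append(
                {"variant_id": c.variant_id, "day": day, "af": c.af, "passed": c.passed}
            )
    return pd.DataFrame(rows)


def resistance_trajectories(truth, meta: pd.DataFrame) -> pd.DataFrame:
    """Annotated trajectory table for a planted-mechanism patient."""
    pileup, _ = rw.sample_plasma_series(truth)
    traj = trajectories_from_pileup(pileup)
    return traj.merge(meta, on="variant_id", how="left")
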