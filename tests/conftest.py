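import numpy as np
import pandas as pd
import pytest

from audiotactile import SimConfig, simulate_dataset
from audiotactile.trials import SCHEMA


@pytest.fixture(scope="session")
def default_trials() -> pd.DataFrame:
    """One simulated study under the default configuration."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture()
def tiny_trials() -> pd.DataFrame:
    """Four hand-written schema-valid trials (2 participants, mixed cells)."""
    rows = [
        ("p1", "S", 12, 1, "uncrossed", "auditory_only", "none", "left", "eye_head", "left", 1.2, True),
        ("p1", "S", 12, 3, "uncrossed", "tactile_only", "right", "none", "arm_hand", "right", 2.0, True),
        ("p2", "SVI", 20, 4, "crossed", "at_congruent", "left", "left", "arm_hand", "left", 1.6, True),
        ("p2", "SVI", 20, 5, "crossed", "at_incongruent", "left", "right", "null", "null", np.nan, True),
    ]
    return pd.DataFrame(rows, columns=SCHEMA)


def logistic_cluster_data(
    seed: int,
    n_clusters: int = 20,
    per_cluster: int = 20,
    beta=(0.5, -0.4, 0.3, 0.1, 0.02, 0.0, 0.0, 0.0),
    sigma_u: float = 0.0,
):
    """Binary-outcome clustered data on the group*posture*age design.

    Returns (frame, y, X, true beta) with y drawn from the logistic model
    plus optional N(0, sigma_u^2) cluster intercepts.
    """
    from audiotactile.design import ModelSpec, build_design

    rng = np.random.default_rng(seed)
    n = n_clusters * per_cluster
    df = pd.DataFrame(
        {
            "participant_id": np.repeat([f"p{i:03d}" for i in range(n_clusters)], per_cluster),
            "group": rng.choice(["S", "SVI"], n),
            "posture": rng.choice(["uncrossed", "crossed"], n),
            "age_months": np.repeat(rng.integers(5, 36, n_clusters), per_cluster),
        }
    )
    spec = ModelSpec(response="direction_binary", factors=["group", "posture", "age_months"])
    X = build_design(df, spec).X
    beta = np.asarray(beta, float)
    eta = X @ beta
    if sigma_u > 0:
        u = rng.normal(0.0, sigma_u, n_clusters)
        eta = eta + np.repeat(u, per_cluster)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return df, y, X, beta
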