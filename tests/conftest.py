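"""Shared fixtures: hand-built miniature tables and small generated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gazemark.core_data import Geometry
from gazemark.synthetic_scanpaths import default_config, disjoint_hotspot_config, generate_dataset


@pytest.fixture(scope="session")
def geom() -> Geometry:
    return Geometry()


def make_fixations(rows) -> pd.DataFrame:
    """rows: (participant_id, trial_id, index, x, y, duration_ms, onset_ms)."""
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "trial_id",
            "index",
            "x_screen",
            "y_screen",
            "duration_ms",
            "onset_ms",
        ],
    )


def make_trials(rows) -> pd.DataFrame:
    """rows: (participant_id, trial_id, emotion, condition, identity_id,
    image_center_x, image_center_y, response, rt_s)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "trial_id",
            "emotion",
            "condition",
            "identity_id",
            "image_center_x",
            "image_center_y",
            "response",
            "rt_s",
        ],
    )
    df["correct"] = df["response"] == df["emotion"]
    return df


@pytest.fixture(scope="session")
def small_dataset():
    """Default generative structure at reduced size (4 participants x 2
    identities = 40 trials each)."""
    cfg = default_config(seed=42, n_participants=4, identities=2)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def disjoint_dataset():
    """Fully separable zero-noise data (6 participants x 2 identities)."""
    cfg = disjoint_hotspot_config(seed=7, n_participants=6, identities=2)
    return generate_dataset(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
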