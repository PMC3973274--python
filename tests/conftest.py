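import datetime as dt

import numpy as np
import pandas as pd
import pytest

from moultshift import camouflage as cam
from moultshift import synthetic as syn
from moultshift.observations import (
    DEFAULT_SITES,
    HareObservation,
    frame_to_observations,
)


@pytest.fixture(scope="session")
def sample_records() -> list[HareObservation]:
    """Three hand-written sightings covering present and absent optional fields."""
    return [
        HareObservation(
            hare_id="h1", site="seeley", date=dt.date(2011, 10, 12), sex="female",
            whiteness=40.0, snow1m=0.0, snow10m=20.0, concealment=2,
            fid_m=12.0, fled=True, attempt_index=3,
        ),
        HareObservation(
            hare_id="h1", site="seeley", date=dt.date(2011, 10, 19), sex="female",
            whiteness=60.0, snow1m=20.0, snow10m=20.0, concealment=1,
            fid_m=3.0, fled=False, attempt_index=4,
            slices=(0.0, 20.0, 0.0, 40.0, 0.0, 0.0, 20.0, 0.0),
        ),
        HareObservation(
            hare_id="h2", site="gardiner", date=dt.date(2011, 10, 12), sex="male",
            whiteness=95.0, snow1m=100.0, snow10m=80.0, concealment=4,
            attempt_index=1,
        ),
    ]


@pytest.fixture(scope="session")
def behaviour_frame() -> pd.DataFrame:
    """behaviour_small fixture joined with contrasts and site-local seasons."""
    fx = syn.make_fixture("behaviour_small", seed=7)
    obs = fx.observations
    records = frame_to_observations(obs)
    contrasts = cam.contrast_table(records)
    frame = obs.merge(
        contrasts[["hare_id", "date", "contrast1m", "contrast10m",
                   "mismatch1m", "mismatch10m"]],
        on=["hare_id", "date"], how="left")
    frame["season"] = [
        DEFAULT_SITES[s].season_map[pd.Timestamp(d).month]
        for s, d in zip(frame["site"], frame["date"])
    ]
    return frame


@pytest.fixture(scope="session")
def full_study_fixture() -> syn.Fixture:
    return syn.make_fixture("full_study", seed=9)
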