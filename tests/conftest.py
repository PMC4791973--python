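import numpy as np
import pandas as pd
import pytest

from capcea.synthetic_cohort import CohortSpec, constant_hazards


def make_spec(n=100, seed=0, censor_day=14, stratum="ward", arm="adherent",
              hazards=None, **kw):
    """Small cohort spec with constant daily hazards."""
    if hazards is None:
        hazards = {(1, 2): 0.2, (1, 3): 0.05, (1, 4): 0.05, (2, 3): 0.3}
    return CohortSpec(
        stratum=stratum,
        arm=arm,
        n_subjects=n,
        daily_hazards=constant_hazards(hazards, censor_day),
        censor_day=censor_day,
        seed=seed,
        **kw,
    )


def events_from_tuples(rows, stratum="ward", arm="adherent", covs=None):
    """Build an event history from (sid, origin, dest, entry, exit, status)."""
    recs = []
    for sid, origin, dest, entry, exit_, status in rows:
        rec = dict(
            subject_id=str(sid),
            stratum=stratum,
            arm=arm,
            origin_state=origin,
            dest_state=dest,
            entry_day=entry,
            exit_day=exit_,
            status=status,
        )
        if covs:
            rec.update(covs[str(sid)])
        recs.append(rec)
    df = pd.DataFrame(recs)
    df["dest_state"] = df["dest_state"].astype("Int64")
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20130101)


@pytest.fixture
def small_cohort():
    from capcea.synthetic_cohort import simulate_cohort

    return simulate_cohort(make_spec(n=200, seed=7))
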