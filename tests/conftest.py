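import dataclasses

import numpy as np
import pandas as pd
import pytest

import flunipk as fp
from flunipk.cohort import DATASET_COLUMNS
from flunipk.estimation import FitSettings, fit_population, initial_pop_from_nca

#: trimmed sampling design used by fit-heavy tests (keeps refits affordable
#: while spanning all three disposition phases and the urine window)
SHORT_SCHEDULES = dict(
    plasma_schedule=(0.083, 0.25, 0.5, 1, 2, 4, 8, 12, 24, 36, 48, 72, 96, 120),
    urine_schedule=(24, 36, 48, 72, 96),
)


@pytest.fixture(scope="session")
def published_pop():
    return fp.load_published_prior()


@pytest.fixture(scope="session")
def typical(published_pop):
    return published_pop.typical_individual()


@pytest.fixture(scope="session")
def arms():
    return fp.load_published_arms()


def make_dataset(obs_rows, dose_rows=None, truths=None):
    """Build a minimal dataset from (ID, TIME, MATRIX, DV, LOQ) observation
    tuples and (ID, TIME, AMT) dose tuples (default: one dose at 0 per ID)."""
    rows = []
    ids = {r[0] for r in obs_rows}
    if dose_rows is None:
        dose_rows = [(i, 0.0, 1.1e6) for i in sorted(ids, key=str)]
    for hid, t, amt in dose_rows:
        rows.append(dict(ID=hid, ARM="test", TIME=t, EVID=1, AMT=amt, MATRIX="",
                         DV=np.nan, LOQ=np.nan, BELOW_LOQ=False,
                         AGE=5.0, BW=500.0, SEX="female", BREED="Thoroughbred",
                         COUNTRY="Japan"))
    for hid, t, matrix, dv, loq in obs_rows:
        rows.append(dict(ID=hid, ARM="test", TIME=t, EVID=0, AMT=np.nan,
                         MATRIX=matrix, DV=dv, LOQ=loq, BELOW_LOQ=dv < loq,
                         AGE=5.0, BW=500.0, SEX="female", BREED="Thoroughbred",
                         COUNTRY="Japan"))
    return fp.ConcentrationDataset(pd.DataFrame(rows, columns=DATASET_COLUMNS),
                                   truths or {})


@pytest.fixture(scope="session")
def medium_cohort(published_pop, arms):
    """28 horses over two single-dose arms with the trimmed schedules."""
    designs = [
        dataclasses.replace(arms[0], n_horses=14, **SHORT_SCHEDULES),
        dataclasses.replace(arms[5], n_horses=14, **SHORT_SCHEDULES),
    ]
    data = fp.generate_cohort(designs, published_pop, seed=404)
    data, _ = fp.censor_loq(data)
    return data


@pytest.fixture(scope="session")
def medium_fit(medium_cohort):
    init = initial_pop_from_nca(medium_cohort)
    return fit_population(medium_cohort, init, FitSettings(max_outer=30))
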