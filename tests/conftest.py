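import datetime as dt

import numpy as np
import pytest

from octvf import (
    GHTResult,
    Laterality,
    PDCategory,
    Pattern,
    VFExam,
    VFSeries,
    build_grid,
)


@pytest.fixture(scope="session")
def grid24():
    return build_grid(Pattern.P24_2)


@pytest.fixture(scope="session")
def grid10():
    return build_grid(Pattern.P10_2)


@pytest.fixture(scope="session")
def grid30():
    return build_grid(Pattern.P30_2)


def make_exam(
    thresholds,
    pattern=Pattern.P24_2,
    laterality=Laterality.OD,
    date=dt.date(2021, 1, 1),
    md=0.0,
    rates=(0.05, 0.05, 0.05),
    pd_prob=None,
    psd_prob=PDCategory.NS,
    ght=GHTResult.WITHIN_NORMAL,
    eye_id="E1",
    patient_id="P1",
):
    grid = build_grid(pattern)
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim == 0:
        thr = np.full(grid.n_points, float(thr))
    return VFExam(
        patient_id=patient_id,
        eye_id=eye_id,
        laterality=laterality,
        date=date,
        pattern=pattern,
        thresholds=thr,
        md=md,
        fp_rate=rates[0],
        fn_rate=rates[1],
        fl_rate=rates[2],
        pd_prob=pd_prob,
        psd_prob=psd_prob,
        ght=ght,
    )


def make_series(values_by_date, pattern=Pattern.P24_2, **kwargs):
    """Series with uniform-threshold exams: {date: scalar or array}."""
    exams = [
        make_exam(v, pattern=pattern, date=d, **kwargs)
        for d, v in values_by_date.items()
    ]
    return VFSeries(eye_id=kwargs.get("eye_id", "E1"), pattern=pattern, exams=exams)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
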