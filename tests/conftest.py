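import datetime as dt
import logging

import pytest

from hdweight.ehr_io import HDSession, PatientSeries


@pytest.fixture(autouse=True)
def _quiet_model_logs(caplog):
    # rank-deficiency / degenerate-kernel warnings are expected on synthetic
    # edge cases; keep them out of test output unless a test opts in
    logging.getLogger("hdweight.emd_model").setLevel(logging.ERROR)
    yield
    logging.getLogger("hdweight.emd_model").setLevel(logging.NOTSET)


def make_series(rows, patient_id="p1", group="unknown", start=dt.date(2024, 1, 1)):
    """Build a PatientSeries from (pre, post, uf) tuples; None = missing."""
    sessions = [
        HDSession(
            patient_id=patient_id,
            date=start + dt.timedelta(days=2 * i),
            pre_weight=pre,
            post_weight=post,
            uf_volume=uf,
            session_index=i,
        )
        for i, (pre, post, uf) in enumerate(rows)
    ]
    return PatientSeries(patient_id, sessions, group)


@pytest.fixture
def series_factory():
    return make_series
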