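import os

os.environ.setdefault("MPLBACKEND", "Agg")

import pytest

from sbrt_pkpd.calibrate import calibrate_cohort
from sbrt_pkpd.cohort import load_cohort
from sbrt_pkpd.model import PKPDParams

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def bundled():
    """The packaged 23-lesion reference cohort."""
    return load_cohort("bundled")


@pytest.fixture(scope="session")
def params():
    return PKPDParams()


@pytest.fixture(scope="session")
def calibrated(bundled, params):
    """Per-lesion gamma fits for the full reference cohort (shared across
    tests because the fit is deterministic and moderately expensive)."""
    results = calibrate_cohort(bundled, params)
    assert all(r.error is None for r in results)
    return results


def by_id(records, patient_id, lesion_index=1):
    for rec in records:
        if rec.patient_id == patient_id and rec.lesion_index == lesion_index:
            return rec
    raise KeyError((patient_id, lesion_index))
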