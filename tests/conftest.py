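import pandas as pd
import pytest

from pvcalib.cohort import CohortTable, ExamineeRecord, default_registry


def make_record(examinee_id="p01", group="clinical", scores=None, **kw):
    return ExamineeRecord(
        examinee_id=examinee_id, group=group, scores=dict(scores or {}), **kw
    )


@pytest.fixture
def registry():
    return default_registry()


@pytest.fixture
def small_cohort():
    """Six hand-written clinical records spanning pass, borderline and fail
    profiles on the memory validity composite."""
    rows = [
        # all components at the good end -> EI5_MEM value 0
        ("a", {"cim": 12, "ds_acss": 10, "hvlt_fcr": 12, "rey15_fr": 15,
               "rey_wrt": 9, "rcft_yn": 21, "rcft_fcr": 22}),
        # one marginal failure -> value 1 (Pass)
        ("b", {"cim": 9, "ds_acss": 10, "hvlt_fcr": 12, "rey15_fr": 15,
               "rey_wrt": 9, "rcft_yn": 20, "rcft_fcr": 20}),
        # two marginal failures -> value 2 (Borderline)
        ("c", {"cim": 9, "ds_acss": 6, "hvlt_fcr": 12, "rey15_fr": 15,
               "rey_wrt": 9, "rcft_yn": 19, "rcft_fcr": 18}),
        # conservative failure + marginal -> value 4 (Fail)
        ("d", {"cim": 6, "ds_acss": 6, "hvlt_fcr": 12, "rey15_fr": 15,
               "rey_wrt": 9, "rcft_yn": 17, "rcft_fcr": 15}),
        # widespread failures -> value 12 (Fail)
        ("e", {"cim": 6, "ds_acss": 2, "hvlt_fcr": 8, "rey15_fr": 5,
               "rey_wrt": 9, "rcft_yn": 14, "rcft_fcr": 10}),
        # missing one component -> incomplete
        ("f", {"cim": 12, "ds_acss": 10, "hvlt_fcr": 12, "rey15_fr": 15,
               "rcft_yn": 22, "rcft_fcr": 23}),
    ]
    return CohortTable([make_record(i, scores=s) for i, s in rows])
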