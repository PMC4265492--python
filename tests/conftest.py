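import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper

from segplan import read_segment_table

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def f1_path() -> Path:
    return DATA / "segments_f1.csv"


@pytest.fixture()
def model_f1(f1_path):
    """Hand-built 10-segment synthetic lung with a unique least-diseased
    segment on the left (LB3) and a tied pair on the right."""
    return read_segment_table(f1_path)


@pytest.fixture()
def eligible_record() -> dict:
    """A record satisfying every computable criterion."""
    return dict(
        age=60,
        fev1_pct_pred=35,
        tlc_pct_pred=105,
        rv_pct_pred=180,
        six_mwd_m=250,
        mmrc=3,
        paco2_mmhg=45,
        pao2_mmhg=60,
        bmi=25,
        dlco_pct_pred=35,
        lower_lobe_tar=13,
        no_pulmonary_hypertension_attested=True,
    )
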