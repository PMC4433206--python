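"""Conventional qualitative exfoliative-cytology call.

The routine clinical readout counts aneuploid cells (DI >= 2.3, the British
Columbia Cancer Agency criterion): a case is "positive" for dysplasia/OSCC
with more than 5 aneuploid cells, "atypical" with 1-5, and "negative" with
none. This three-level call is the baseline the quantitative risk index is
measured against.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import DICase

ANEUPLOID_DI_THRESHOLD = 2.3
POSITIVE_CELL_COUNT = 5  # "positive" means strictly more than this


@dataclasses.dataclass(frozen=True)
class QualitativeCall:
    case_id: str
    aneuploid_cell_count: int
    call: str  # negative | atypical | positive


def qualitative_call(case: DICase) -> QualitativeCall:
    count = int(np.count_nonzero(case.di_values >= ANEUPLOID_DI_THRESHOLD))
    if count > POSITIVE_CELL_COUNT:
        call = "positive"
    elif count >= 1:
        call = "atypical"
    else:
        call = "negative"
    return QualitativeCall(case_id=case.case_id, aneuploid_cell_count=count, call=call)


def call_table(cases) -> pd.DataFrame:
    """Per-case qualitative calls as a table."""
    calls = [qualitative_call(c) for c in cases]
    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in calls],
            "aneuploid_cell_count": [c.aneuploid_cell_count for c in calls],
            "call": [c.call for c in calls],
        }
    )
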