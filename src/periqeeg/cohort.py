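"""Published characteristics of the surgical cohort the method was developed on.

Demographic and monitoring characteristics of the 16 pharmacoresistant
focal-epilepsy patients (Engel outcome classes I, II and IV) whose
peri-ictal intracranial recordings motivated this pipeline, plus the
channel-zone counts of one worked example patient.  The patient
recordings themselves are not redistributable; these summary values
support reproducible cohort arithmetic (medians, fractions, Jaccard
indices) without them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["cohort_table", "cohort_medians", "ZONE_EXAMPLE"]

# per patient: Engel class, age (y), follow-up (y), number of seizures during
# invasive monitoring, monitoring duration (d), mean seizure frequency (1/d),
# number of seizure types, artifact-free iEEG channels, intracranial volume (ml)
_ROWS = [
    ("I-1", "I", 26, 3, 2, 8, 0.250, 1, 64, 1437),
    ("I-2", "I", 48, 3, 4, 5, 0.800, 1, 64, 1297),
    ("I-3", "I", 27, 1, 9, 10, 0.900, 1, 56, 1321),
    ("I-4", "I", 36, 5, 7, 4, 1.750, 1, 74, 1627),
    ("I-5", "I", 19, 5, 4, 10, 0.400, 2, 40, 1426),
    ("I-6", "I", 25, 4, 2, 11, 0.182, 1, 99, 1518),
    ("II-1", "II", 49, 4, 6, 9, 0.667, 1, 92, 1248),
    ("II-2", "II", 46, 3, 5, 8, 0.625, 1, 100, 1093),
    ("II-3", "II", 20, 3, 10, 5, 2.000, 1, 54, 1623),
    ("II-4", "II", 31, 3, 6, 8, 0.750, 1, 59, 1233),
    ("II-5", "II", 24, 3, 2, 6, 0.333, 1, 47, 1347),
    ("IV-1", "IV", 38, 4, 2, 8, 0.250, 1, 59, 1430),
    ("IV-2", "IV", 23, 2, 3, 6, 0.500, 1, 61, 1248),
    ("IV-3", "IV", 59, 4, 10, 6, 1.667, 2, 49, 1286),
    ("IV-4", "IV", 32, 2, 14, 6, 2.333, 2, 96, 1711),
    ("IV-5", "IV", 31, 2, 2, 5, 0.400, 1, 32, 1321),
]

_COLUMNS = [
    "patient",
    "engel_class",
    "age_y",
    "follow_up_y",
    "n_seizures",
    "monitoring_days",
    "seizure_frequency",
    "n_seizure_types",
    "n_channels",
    "icv_ml",
]

# Worked-example channel zones (patient I-2): 64 artifact-free channels,
# 13 resected, 11 in the seizure onset zone, 9 in the overlap.
ZONE_EXAMPLE = {"n": 64, "rbt": 13, "soz": 11, "ovl": 9}


def cohort_table() -> pd.DataFrame:
    """Cohort characteristics, one row per patient."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def cohort_medians() -> dict[str, float]:
    """Cohort-wide medians of the numeric characteristics."""
    df = cohort_table()
    return {
        col: float(np.median(df[col]))
        for col in _COLUMNS[2:]
    }
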