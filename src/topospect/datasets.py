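"""Descriptive data of the five-participant hypnotic NDE-recall study.

These are the published participant-level descriptives (demographics,
hypnotic-susceptibility totals, Greyson NDE-scale totals for the original
experience).  They parameterize the default emulation design and feed the
behavioural descriptive statistics; no raw EEG accompanies them.
"""

from __future__ import annotations

import pandas as pd

# One row per participant: age (years), gender, age at the original NDE
# (years), Greyson NDE scale total for the original experience (0-32),
# SHSS:C total (0-12), and the circumstance of the original event.
_PARTICIPANTS = [
    # id, age, gender, age_at_nde, greyson_total, shss, circumstances
    ("P1", 60, "M", 21, 18, 6, "traumatic injury (loss of consciousness)"),
    ("P2", 44, "M", 12, 7, 9, "tonsil surgery"),
    ("P3", 66, "M", 57, 15, 8, "intense meditation state"),
    ("P4", 71, "F", 8, 15, 9, "surgery (removal of a foreign object)"),
    ("P5", 48, "F", 18, 12, 4, "traumatic injury (loss of consciousness)"),
]


def study_participants() -> pd.DataFrame:
    """Participant descriptives as a DataFrame (one row per participant)."""
    return pd.DataFrame(
        _PARTICIPANTS,
        columns=["participant", "age", "gender", "age_at_nde",
                 "greyson_total", "shss", "circumstances"],
    )
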