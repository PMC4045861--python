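"""Delimited-text survey I/O.

Surveys travel as plain CSV with one row per respondent; missing lab values
are encoded as empty fields.  The column dictionary is the union of the
covariate layout (see :mod:`diabscreen.design`), the flags/weight columns,
and, depending on survey type, the lab columns (``hba1c``, ``fpg``,
``ogtt_2h``) or the five visit-count columns.
"""

from __future__ import annotations

import pandas as pd

_STRING_COLUMNS = ["age_band", "race_eth", "bmi_class", "survey_wave", "latent_state", "status"]


def write_survey(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, na_rep="")


def read_survey(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in _STRING_COLUMNS:
        if col in frame.columns:
            frame[col] = frame[col].astype(str)
    return frame


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path)
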