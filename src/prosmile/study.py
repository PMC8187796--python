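"""Published study design constants.

The exploratory study enrolled six children with ASD (two analyzed
sessions each) and six typically developing children (one analyzed
session each); every analyzed session contained one robot-walking and
one robot-falling situation.  The roster below is the published
participant table; the 2×2 smile × prosocial-behavior proportions are
the published joint table over the resulting 36 cases.
"""

from __future__ import annotations

import pandas as pd

from .synth import STUDY_JOINT, generate_case_table

#: participant id, age (years), analyzed sessions
ROSTER = [
    ("ASD-P1", 16, (1, 2)),
    ("ASD-P2", 11, (1, 2)),
    ("ASD-P3", 8, (2, 4)),
    ("ASD-P4", 8, (2, 4)),
    ("ASD-P5", 6, (3, 4)),
    ("ASD-P6", 9, (1, 2)),
    ("TD-P1", 11, (2,)),
    ("TD-P2", 11, (1,)),
    ("TD-P3", 11, (3,)),
    ("TD-P4", 9, (2,)),
    ("TD-P5", 6, (1,)),
    ("TD-P6", 11, (1,)),
]

N_SITUATIONS = 2  # walking, falling — both present in every analyzed session


def roster_dataframe() -> pd.DataFrame:
    df = pd.DataFrame(ROSTER, columns=["participant", "age", "sessions"])
    df["group"] = df["participant"].str.split("-").str[0]
    df["n_sessions"] = df["sessions"].map(len)
    return df


def design_case_count() -> int:
    """Analyzed cases = participants × their sessions × situations."""
    df = roster_dataframe()
    return int((df["n_sessions"] * N_SITUATIONS).sum())


def age_summary() -> pd.DataFrame:
    """Group age mean and sample SD (ddof=1), as reported."""
    df = roster_dataframe()
    out = df.groupby("group")["age"].agg(
        mean="mean", sd=lambda s: s.std(ddof=1), min="min", max="max", n="count"
    )
    return out


def observed_case_fixture(seed: int = 0) -> list:
    """A 36-case table with the published smile × PB cell counts.

    Cell counts follow from the published proportions × 36 under
    largest-remainder rounding: (15, 3, 8, 10).  Individual case
    identities are synthetic; only the (S, PB) margins are anchored to
    the study.
    """
    return generate_case_table(design_case_count(), STUDY_JOINT, seed=seed)
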