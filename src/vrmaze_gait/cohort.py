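"""Cohort table schema: covariates, neuropsychological scores, outcomes.

The cohort table is one row per subject with demographic covariates
(age, sex, education, height, weight) and eleven neuropsychological
scores spanning attention (Trail Making Test A), executive function
(Trail Making Test B, Digit Symbol Substitution, Digit Comparison),
verbal fluency (COWA F-A-S, WRAT4 word reading), auditory memory
(immediate/delayed Logical Memory), visual memory (immediate/delayed
Designs) and visuospatial reasoning (Porteus Maze).  Score instruments
are bounded; the generator truncates accordingly.

Maze-navigation outcomes (completion time, the five spatiotemporal gait
parameters and their CoVs, and the balance metrics) are stored in a long
table with one row per subject × condition × visit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

COVARIATE_COLUMNS = ("age", "sex", "education", "height", "weight")


@dataclass(frozen=True)
class ScoreSpec:
    """Population mean/SD and instrument bounds for one cognitive test."""

    name: str
    mean: float
    sd: float
    lo: float = 0.0
    hi: float = np.inf
    higher_is_better: bool = True


#: the eleven-test battery with population means ± SDs and instrument ranges
SCORE_SPECS: tuple[ScoreSpec, ...] = (
    ScoreSpec("tmt_a", 37.7, 13.4, 0.0, np.inf, higher_is_better=False),
    ScoreSpec("tmt_b", 83.9, 41.2, 0.0, np.inf, higher_is_better=False),
    ScoreSpec("dsst", 49.7, 13.5, 0.0, 93.0),
    ScoreSpec("digit_comparison", 59.7, 12.1, 0.0, 192.0),
    ScoreSpec("cowa_fas", 41.6, 12.1, 0.0, np.inf),
    ScoreSpec("wrat4", 49.4, 6.4, 0.0, 70.0),
    ScoreSpec("logical_memory_immediate", 29.0, 7.0, 0.0, 50.0),
    ScoreSpec("logical_memory_delayed", 23.7, 7.3, 0.0, 50.0),
    ScoreSpec("designs_immediate", 61.6, 10.4, 0.0, 120.0),
    ScoreSpec("designs_delayed", 50.8, 9.4, 0.0, 120.0),
    ScoreSpec("porteus_maze", 15.5, 1.5, 0.0, 17.0),
)

SCORE_COLUMNS = tuple(s.name for s in SCORE_SPECS)
SCORE_MEANS = {s.name: s.mean for s in SCORE_SPECS}

#: demographics: mean, SD, lower truncation (study population of older adults)
DEMOGRAPHICS = {
    "age": (67.8, 6.3, 60.0),
    "education": (16.9, 3.2, 1.0),
    "height": (167.7, 8.6, 120.0),
    "weight": (77.4, 17.7, 35.0),
}
P_MALE = 16 / 65

#: per-session outcome measures, long-table columns
GAIT_OUTCOME_COLUMNS = (
    "stride_length",
    "stride_width",
    "stride_time",
    "stride_velocity",
    "stance_pct",
)
COV_OUTCOME_COLUMNS = tuple(f"{c}_cov" for c in GAIT_OUTCOME_COLUMNS)
BALANCE_OUTCOME_COLUMNS = ("mos_ml", "com_ml", "com_ml_cov")
OUTCOME_COLUMNS = (
    ("completion_time",) + GAIT_OUTCOME_COLUMNS + COV_OUTCOME_COLUMNS + BALANCE_OUTCOME_COLUMNS
)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", *COVARIATE_COLUMNS, *SCORE_COLUMNS) if c not in df]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
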