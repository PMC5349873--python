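"""Feature-table conventions shared across the pipeline.

A *feature table* is a :class:`pandas.DataFrame` with a ``subject_id``
column, a binary ``grade`` column (1 = high grade, 0 = low grade) and one
numeric column per marker.  All downstream stages (screening, panel
building, validation, PCA) consume this shape.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ID_COLUMN = "subject_id"
GRADE_COLUMN = "grade"
HIGH_GRADE = "HG"
LOW_GRADE = "LG"

_GRADE_ALIASES = {"HG": 1, "LG": 0, "1": 1, "0": 0, 1: 1, 0: 0, True: 1, False: 0}


def parse_grade(value) -> int:
    """Map a grade label (``HG``/``LG`` or ``1``/``0``) to the canonical int."""
    key = value.strip() if isinstance(value, str) else value
    try:
        return _GRADE_ALIASES[key]
    except (KeyError, TypeError):
        raise ValueError(f"unrecognized grade label: {value!r}") from None


def marker_columns(table: pd.DataFrame) -> list[str]:
    """Names of the marker columns, preserving table order."""
    return [c for c in table.columns if c not in (ID_COLUMN, GRADE_COLUMN)]


def grade_labels(table: pd.DataFrame) -> np.ndarray:
    """Binary label vector (1 = high grade) as an int array."""
    return table[GRADE_COLUMN].to_numpy(dtype=int)


def marker_matrix(table: pd.DataFrame, names: list[str] | None = None) -> np.ndarray:
    """Subjects x markers design matrix as float64."""
    if names is None:
        names = marker_columns(table)
    return table.loc[:, names].to_numpy(dtype=float)


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants; returns the table unchanged.

    Raises
    ------
    ValueError
        On a missing id/grade column, duplicate subject ids, a grade
        outside {0, 1}, non-numeric marker cells or missing values.
    """
    for required in (ID_COLUMN, GRADE_COLUMN):
        if required not in table.columns:
            raise ValueError(f"feature table lacks required column {required!r}")
    dupes = table[ID_COLUMN][table[ID_COLUMN].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate subject_id values: {sorted(set(dupes))}")
    grades = set(table[GRADE_COLUMN].unique().tolist())
    if not grades <= {0, 1}:
        raise ValueError(f"grade column contains labels outside {{0,1}}: {grades}")
    for col in marker_columns(table):
        values = table[col]
        if not pd.api.types.is_numeric_dtype(values):
            bad = values.index[pd.to_numeric(values, errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else "?"
            raise ValueError(f"non-numeric value in marker column {col!r}, row {row}")
        if values.isna().any():
            row = int(values.index[values.isna()][0])
            raise ValueError(f"missing value in marker column {col!r}, row {row}")
    return table
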