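"""Derived scores, missing-data handling and per-group score matrices.

The two executive "ratio" nodes are computed from raw subtest times:
Stroop interference = time(card III) / time(card II), and TMT flexibility
= time(part B) / time(part A); higher ratios mean more interference /
less flexibility. Network estimation consumes, per group, the
complete-case score matrix and its Pearson correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScoreMatrix",
    "stroop_ratio",
    "tmt_ratio",
    "derive_ratio_scores",
    "load_cohort_csv",
    "split_complete_cases",
    "DEFAULT_NODE_COLUMNS",
]

log = logging.getLogger(__name__)

DEFAULT_NODE_COLUMNS = ["15T", "15R", "DSB", "FLU", "STR", "TMT", "FAP", "FID", "FEF"]

RAW_STROOP = ("stroop_III_s", "stroop_II_s")
RAW_TMT = ("tmt_B_s", "tmt_A_s")


@dataclass
class ScoreMatrix:
    """Complete-case scores for one group, plus their correlation matrix."""

    group_name: str
    labels: list[str]
    X: np.ndarray
    correlation: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.labels):
            raise ValueError("X must be n x p with p = len(labels)")
        if not np.isfinite(self.X).all():
            raise ValueError("X must be complete (no missing/non-finite entries)")
        if self.correlation is None:
            self.correlation = np.corrcoef(self.X, rowvar=False)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return len(self.labels)


def stroop_ratio(time_III: float, time_II: float, subject: str | None = None) -> float:
    """Stroop interference ratio (card III time over card II time)."""
    if not (time_III > 0 and time_II > 0):
        who = f" for subject {subject!r}" if subject else ""
        raise ValueError(f"Stroop times must be strictly positive{who}")
    return time_III / time_II


def tmt_ratio(time_B: float, time_A: float, subject: str | None = None) -> float:
    """Trail Making flexibility ratio (part B time over part A time)."""
    if not (time_B > 0 and time_A > 0):
        who = f" for subject {subject!r}" if subject else ""
        raise ValueError(f"TMT times must be strictly positive{who}")
    return time_B / time_A


def derive_ratio_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Fill the STR and TMT columns from raw times where raw times exist.

    Raw times win over any precomputed ratio column (a warning is logged
    when both are present). Rows without raw times keep the ratio column.
    """
    out = table.copy()
    for ratio_col, (num, den) in (("STR", RAW_STROOP), ("TMT", RAW_TMT)):
        if num in out.columns and den in out.columns:
            have = out[num].notna() & out[den].notna()
            if ratio_col in out.columns and out.loc[have, ratio_col].notna().any():
                log.warning(
                    "both raw times and %s present; raw times take precedence",
                    ratio_col,
                )
            bad = have & ((out[num] <= 0) | (out[den] <= 0))
            if bad.any():
                sid = out.loc[bad].iloc[0].get("subject_id", "<unknown>")
                raise ValueError(
                    f"non-positive time for {ratio_col} ratio (subject {sid!r})"
                )
            if ratio_col not in out.columns:
                out[ratio_col] = np.nan
            out.loc[have, ratio_col] = out.loc[have, num] / out.loc[have, den]
    return out


def load_cohort_csv(
    path,
    group_column: str = "group",
    group_levels: list[str] | None = None,
    node_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Read a cohort CSV and validate its group labels and score columns."""
    table = pd.read_csv(path)
    node_columns = node_columns or DEFAULT_NODE_COLUMNS
    table = derive_ratio_scores(table)
    missing = [c for c in [group_column] + node_columns if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    if group_levels is not None:
        unknown = set(table[group_column].unique()) - set(group_levels)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
    return table


def split_complete_cases(
    table: pd.DataFrame,
    group_column: str = "group",
    node_columns: list[str] | None = None,
    group_levels: list[str] | None = None,
) -> dict[str, ScoreMatrix]:
    """Listwise deletion within each group across the analysis variables.

    Returns one :class:`ScoreMatrix` per group; groups left with fewer
    than p+1 complete rows raise, because a partial-correlation network
    (and its bootstrap) needs n > p.
    """
    node_columns = list(node_columns or DEFAULT_NODE_COLUMNS)
    p = len(node_columns)
    levels = group_levels or list(pd.unique(table[group_column]))
    out: dict[str, ScoreMatrix] = {}
    for g in levels:
        sub = table.loc[table[group_column] == g, node_columns]
        complete = sub.dropna()
        dropped = len(sub) - len(complete)
        if dropped:
            log.info("group %s: dropped %d incomplete rows of %d", g, dropped, len(sub))
        if len(complete) < p + 1:
            raise ValueError(
                f"group {g!r} has only {len(complete)} complete rows; "
                f"at least {p + 1} required"
            )
        out[g] = ScoreMatrix(group_name=g, labels=node_columns, X=complete.to_numpy())
    return out
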