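"""Defect-count statistics for the thioridazine exposure experiment.

Six independent trials of 100 Xenopus laevis embryos were scored for six
defect categories under thioridazine exposure and control conditions.
This module reproduces the pooled defect percentages, per-trial means
with their standard errors, and per-category condition comparisons from
the packaged raw-count table.

The comparison is a Welch two-sample t-test on the six per-trial
percentages of each condition (the trial, not the embryo, is the
independent unit).  Degenerate zero-variance pairs are handled by a
documented rule: equal means give t = 0, p = 1; unequal means give
t = +/-inf, p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DEFECT_CATEGORIES = (
    "Hypopigmentation",
    "Kinked body",
    "Edema",
    "Abnormal face shape",
    "Gut",
    "Cleft cement gland",
)
CONDITIONS = ("Thioridazine", "Control")


class CountTableError(ValueError):
    """Malformed or invalid defect-count data."""


@dataclass(frozen=True)
class DefectCountTable:
    """Complete (category x condition x trial) grid of defect counts."""

    counts: pd.DataFrame  # columns: category, condition, trial, count
    trial_size: int = 100

    @property
    def n_trials(self) -> int:
        return self.counts["trial"].nunique()

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.counts["category"].unique())

    def __post_init__(self) -> None:
        required = {"category", "condition", "trial", "count"}
        missing = required - set(self.counts.columns)
        if missing:
            raise CountTableError(f"missing columns: {sorted(missing)}")
        if self.counts.empty:
            raise CountTableError("empty count table")
        bad = self.counts[
            (self.counts["count"] < 0) | (self.counts["count"] > self.trial_size)
        ]
        if not bad.empty:
            row = bad.iloc[0]
            raise CountTableError(
                f"count {row['count']} outside [0, {self.trial_size}] "
                f"({row['category']}, {row['condition']}, trial {row['trial']})"
            )
        trials = sorted(self.counts["trial"].unique())
        for (cat, cond), grp in self.counts.groupby(["category", "condition"]):
            if sorted(grp["trial"]) != trials:
                raise CountTableError(
                    f"incomplete grid for ({cat}, {cond}): trials {sorted(grp['trial'])}"
                )

    def trial_counts(self, category: str, condition: str) -> np.ndarray:
        """Counts per trial, in trial order."""
        if category not in set(self.counts["category"]):
            raise CountTableError(f"unknown category {category!r}")
        if condition not in set(self.counts["condition"]):
            raise CountTableError(f"unknown condition {condition!r}")
        sub = self.counts[
            (self.counts["category"] == category)
            & (self.counts["condition"] == condition)
        ].sort_values("trial")
        return sub["count"].to_numpy()


def read_counts(path: str | Path, trial_size: int = 100) -> DefectCountTable:
    """Parse and validate a delimited counts file.

    Expected columns: ``category, condition, trial, count``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CountTableError(f"{path}: empty or malformed file") from exc
    try:
        df["count"] = df["count"].astype(int)
        df["trial"] = df["trial"].astype(int)
    except (KeyError, ValueError) as exc:
        raise CountTableError(f"{path}: malformed rows ({exc})") from exc
    return DefectCountTable(counts=df, trial_size=trial_size)


def packaged_counts() -> DefectCountTable:
    """The packaged six-trial thioridazine/control count table."""
    from importlib.resources import files

    with files("morphoinfer.data").joinpath(
        "thioridazine_defect_counts.csv"
    ).open("rb") as fh:
        df = pd.read_csv(fh)
    return DefectCountTable(counts=df)


def pooled_percentage(
    table: DefectCountTable, category: str, condition: str
) -> float:
    """Percent of all embryos (pooled over trials) showing the defect."""
    counts = table.trial_counts(category, condition)
    return 100.0 * counts.sum() / (len(counts) * table.trial_size)


def per_trial_stats(
    table: DefectCountTable, category: str, condition: str
) -> tuple[float, float]:
    """Mean and standard error of the per-trial defect percentages."""
    pct = 100.0 * table.trial_counts(category, condition) / table.trial_size
    sem = float(np.std(pct, ddof=1) / np.sqrt(len(pct))) if len(pct) > 1 else 0.0
    return float(np.mean(pct)), sem


def compare_conditions(
    table: DefectCountTable,
    category: str,
    conditions: tuple[str, str] = CONDITIONS,
) -> tuple[float, float]:
    """Welch t-test between the per-trial percentages of two conditions."""
    a = 100.0 * table.trial_counts(category, conditions[0]) / table.trial_size
    b = 100.0 * table.trial_counts(category, conditions[1]) / table.trial_size
    if len(a) < 2 or len(b) < 2:
        raise CountTableError("need at least two trials per condition")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.sign(np.mean(a) - np.mean(b)) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def report(table: DefectCountTable) -> pd.DataFrame:
    """Per-category summary: pooled %, mean +/- SEM, Welch comparison."""
    rows = []
    for cat in table.categories:
        mean_t, sem_t = per_trial_stats(table, cat, "Thioridazine")
        mean_c, sem_c = per_trial_stats(table, cat, "Control")
        t, p = compare_conditions(table, cat)
        rows.append(
            {
                "category": cat,
                "treated_pooled_pct": round(pooled_percentage(table, cat, "Thioridazine"), 2),
                "control_pooled_pct": round(pooled_percentage(table, cat, "Control"), 2),
                "treated_mean_pct": mean_t,
                "treated_sem": sem_t,
                "control_mean_pct": mean_c,
                "control_sem": sem_c,
                "welch_t": t,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
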