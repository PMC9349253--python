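"""Repeatability and accuracy statistics for sectioning validation runs.

Implements the arithmetic used to validate the planner on position-known
three-targeted phantoms: per-coordinate coefficients of variation across
repeat measurement runs, their unweighted "total" mean, the pooled Pearson
correlation between foreknown and measured coordinates, and the paired
t-test between expected and actual cutting-forward distances.

Conventions (verified to reproduce the reference run tables exactly):

* CV uses the sample (n−1) standard deviation divided by the absolute mean,
  computed on coordinate magnitudes.
* The total CV is the unweighted arithmetic mean of the component CVs.

Multiple-comparison procedures (Tukey HSD) are deliberately not implemented
here; any standard implementation can be applied to the same tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError, UndefinedStatisticError


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD of magnitudes over |mean|."""
    v = np.abs(np.asarray(values, dtype=float))
    if v.size < 2:
        raise InputError("CV needs at least 2 values")
    m = v.mean()
    if m == 0:
        raise UndefinedStatisticError("CV is undefined for zero mean")
    return float(v.std(ddof=1) / abs(m))


def total_cv(cvs: Sequence[float]) -> float:
    """Unweighted arithmetic mean of component CVs."""
    c = np.asarray(cvs, dtype=float)
    if c.size == 0:
        raise InputError("total CV needs at least one component CV")
    return float(c.mean())


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation between two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("samples must have equal length")
    if x.size < 3:
        raise InputError("correlation needs at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("correlation undefined for zero variance")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def paired_t(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, int, float]:
    """Student's paired t-test; returns (t, df, two-tailed p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("samples must have equal length")
    if x.size < 2:
        raise InputError("paired t-test needs at least 2 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        raise UndefinedStatisticError(
            "paired t-test undefined for zero-variance differences"
        )
    res = stats.ttest_rel(x, y)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


@dataclass(frozen=True)
class ValidationReport:
    """CV / correlation / paired-comparison summary of a validation campaign.

    ``coordinate_cvs`` maps (target, axis) to the CV of that coordinate's
    measured magnitudes across runs; ``distance_cvs`` maps each target to the
    CV of its actual cutting-forward distances.  Totals are unweighted means
    of the listed components.
    """

    coordinate_cvs: dict
    coordinate_total_cv: float
    pearson_r: float
    pearson_n: int
    distance_cvs: dict
    distance_total_cv: float
    expected_distance_cv: float
    t_statistic: float
    t_df: int
    t_pvalue: float
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coordinate_cvs": {
                f"{t}/{a}": v for (t, a), v in self.coordinate_cvs.items()
            },
            "coordinate_total_cv": self.coordinate_total_cv,
            "pearson_r": self.pearson_r,
            "pearson_n": self.pearson_n,
            "distance_cvs": dict(self.distance_cvs),
            "distance_total_cv": self.distance_total_cv,
            "expected_distance_cv": self.expected_distance_cv,
            "paired_t": {
                "t": self.t_statistic,
                "df": self.t_df,
                "p_two_tailed": self.t_pvalue,
            },
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def summary(self) -> str:
        lines = ["Sectioning validation report", "=" * 28, ""]
        lines.append("Per-coordinate CVs (measured positions across runs):")
        for (t, a), v in self.coordinate_cvs.items():
            lines.append(f"  {t:<8s} {a}  CV = {v:.5f}")
        lines.append(f"  Total (mean of {len(self.coordinate_cvs)}): "
                     f"{self.coordinate_total_cv:.5f}")
        lines.append("")
        lines.append(
            f"Foreknown vs measured pooled correlation: "
            f"r = {self.pearson_r:.6f} (N = {self.pearson_n})"
        )
        lines.append("")
        lines.append("Cutting-forward distance CVs (actual, across runs):")
        for t, v in self.distance_cvs.items():
            lines.append(f"  {t:<8s}    CV = {v:.5f}")
        lines.append(f"  Total: {self.distance_total_cv:.4f}   "
                     f"(expected distances: CV = {self.expected_distance_cv:.4f})")
        lines.append("")
        lines.append(
            f"Expected vs actual paired t-test: t = {self.t_statistic:.4f}, "
            f"df = {self.t_df}, two-tailed p = {self.t_pvalue:.3f}"
        )
        return "\n".join(lines)


def _run_columns(df: pd.DataFrame) -> list[str]:
    runs = [c for c in df.columns if c.startswith("run")]
    if not runs:
        raise InputError("table has no run1..runN columns")
    return runs


def build_report(
    position_table: pd.DataFrame,
    distance_table: pd.DataFrame,
    provenance: dict | None = None,
) -> ValidationReport:
    """Assemble a :class:`ValidationReport` from the two validation tables.

    Parameters
    ----------
    position_table : DataFrame
        Columns ``target, axis, foreknown, run1..runN`` — per-coordinate
        foreknown magnitude and the repeated measured magnitudes.
    distance_table : DataFrame
        Columns ``target, run, actual, expected`` — cutting-forward
        distances per target and run; the expected value is shared by the
        targets of a run.
    """
    required = {"target", "axis", "foreknown"}
    if not required.issubset(position_table.columns):
        raise InputError(
            f"position table must have columns {sorted(required)} plus run1..runN"
        )
    runs = _run_columns(position_table)
    required_d = {"target", "run", "actual", "expected"}
    if not required_d.issubset(distance_table.columns):
        raise InputError(f"distance table must have columns {sorted(required_d)}")

    coordinate_cvs: dict = {}
    fore_pooled: list[float] = []
    meas_pooled: list[float] = []
    for _, row in position_table.iterrows():
        measured = [abs(float(row[c])) for c in runs]
        coordinate_cvs[(row["target"], row["axis"])] = cv(measured)
        fore_pooled.extend([abs(float(row["foreknown"]))] * len(runs))
        meas_pooled.extend(measured)
    coord_total = total_cv(list(coordinate_cvs.values()))
    r = pearson(fore_pooled, meas_pooled)

    distance_cvs: dict = {}
    for target, grp in distance_table.groupby("target", sort=False):
        distance_cvs[target] = cv(grp["actual"].to_numpy(dtype=float))
    dist_total = total_cv(list(distance_cvs.values()))
    per_run_expected = (
        distance_table.groupby("run", sort=False)["expected"].agg("first")
    )
    expected_cv = cv(per_run_expected.to_numpy(dtype=float))
    t, df_, p = paired_t(
        distance_table["actual"].to_numpy(dtype=float),
        distance_table["expected"].to_numpy(dtype=float),
    )
    return ValidationReport(
        coordinate_cvs=coordinate_cvs,
        coordinate_total_cv=coord_total,
        pearson_r=r,
        pearson_n=len(fore_pooled),
        distance_cvs=distance_cvs,
        distance_total_cv=dist_total,
        expected_distance_cv=expected_cv,
        t_statistic=t,
        t_df=df_,
        t_pvalue=p,
        provenance=provenance or {},
    )
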