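"""Count indices, group summaries, test battery, and report assembly.

Conventions: summaries are reported as mean +/- SE with the sample (n-1)
standard deviation; two-group comparisons use the Mann-Whitney U test
(exact for small tie-free samples, otherwise the tie- and
continuity-corrected normal approximation) reporting the smaller of the two
U statistics; symmetric-vs-null questions use the one-sample t test. All
p-values are two-sided and uncorrected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ContractError, DegenerateStatisticError
from .imgio.model import MeasurementTable

__all__ = [
    "CountIndex",
    "GroupSummary",
    "mitotic_index",
    "summarize_group",
    "mann_whitney",
    "one_sample_t",
    "significance_marker",
    "build_report",
]

#: sample sizes up to which the exact Mann-Whitney distribution is used
EXACT_MW_LIMIT = 8


@dataclass
class CountIndex:
    """A positive/total count pair expressed as a percentage."""

    positive: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ContractError("total count must be positive")
        if not 0 <= self.positive <= self.total:
            raise ContractError(f"positive count {self.positive} outside [0, {self.total}]")

    @property
    def percent(self) -> float:
        return 100.0 * self.positive / self.total

    @property
    def percent_2dp(self) -> float:
        return round(self.percent, 2)


@dataclass
class GroupSummary:
    """n, mean and standard error of one measure in one group."""

    n: int
    mean: float
    se: float | None  # None (flagged) when n == 1
    measure: str = ""
    group: str = ""


def mitotic_index(positive: int, total: int) -> CountIndex:
    """Percentage of mitotic-mark-positive cells among all scored cells."""
    return CountIndex(positive=int(positive), total=int(total))


def summarize_group(values: Sequence[float], measure: str = "", group: str = "") -> GroupSummary:
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ContractError("cannot summarize an empty group")
    mean = float(values.mean())
    se = None if values.size == 1 else float(values.std(ddof=1) / np.sqrt(values.size))
    return GroupSummary(n=int(values.size), mean=mean, se=se, measure=measure, group=group)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Returns ``(U, p)`` with U reported as ``min(U_a, U_b)``. The exact null
    distribution is used when both samples are small (min n <= 8) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ContractError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                   use_continuity=True)
    u_a = float(res.statistic)
    u_min = min(u_a, a.size * b.size - u_a)
    return u_min, float(res.pvalue)


def one_sample_t(values: Sequence[float], null_value: float = 0.0) -> tuple[float, float]:
    """One-sample t test of the mean against ``null_value``, two-sided."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise DegenerateStatisticError("one-sample t needs n >= 2")
    if values.std(ddof=1) == 0:
        raise DegenerateStatisticError("zero variance: t statistic undefined")
    res = scipy.stats.ttest_1samp(values, popmean=null_value)
    return float(res.statistic), float(res.pvalue)


def significance_marker(p: float) -> str:
    """Display-level annotation for a p-value (no correction applied)."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def build_report(
    tables: Sequence[MeasurementTable],
    config: Mapping,
    out_dir,
) -> dict:
    """Join measurement tables, summarize groups, run configured tests.

    ``config`` keys:

    * ``measures``: list of measure names to include (empty -> QC only);
    * ``group_by``: column defining groups (default ``cell_type``);
    * ``tests``: list of dicts, each either
      ``{"test": "mann_whitney", "measure": m, "group_a": ga, "group_b": gb}``
      or ``{"test": "one_sample_t", "measure": m, "group": g, "null": x}``.

    Writes ``measurements.csv``, ``summaries.csv``, ``tests.csv`` and
    ``summary.json`` under ``out_dir`` with deterministic ordering, and
    returns the summary payload.
    """
    if not tables:
        raise ContractError("need at least one measurement table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.concat([t.df for t in tables], ignore_index=True)
    group_col = config.get("group_by", "cell_type")
    if group_col not in df.columns:
        raise ContractError(f"group_by column {group_col!r} missing from tables")
    measures = list(config.get("measures", []))
    if measures:
        unknown = set(measures) - set(df["measure"].unique())
        if unknown:
            raise ContractError(f"configured measures not present: {sorted(unknown)}")
        df = df[df["measure"].isin(measures)]
    df = df.sort_values(["measure", group_col, "pair_id", "channel"],
                        kind="stable", ignore_index=True)
    df.to_csv(out_dir / "measurements.csv", index=False)

    qc = {"n_rows": int(len(df)), "n_pairs": int(df["pair_id"].nunique()) if len(df) else 0}

    summaries = []
    for (measure, group), sub in sorted(df.groupby(["measure", group_col])):
        s = summarize_group(sub["value"].astype(float), measure=measure, group=str(group))
        summaries.append(
            {"measure": s.measure, "group": s.group, "n": s.n, "mean": s.mean, "se": s.se}
        )
    pd.DataFrame(summaries, columns=["measure", "group", "n", "mean", "se"]).to_csv(
        out_dir / "summaries.csv", index=False
    )

    test_rows = []
    for spec in config.get("tests", []):
        measure = spec["measure"]
        sub = df[df["measure"] == measure]
        if spec["test"] == "mann_whitney":
            a = sub[sub[group_col] == spec["group_a"]]["value"].astype(float)
            b = sub[sub[group_col] == spec["group_b"]]["value"].astype(float)
            stat, p = mann_whitney(a, b)
            label = f"{spec['group_a']} vs {spec['group_b']}"
        elif spec["test"] == "one_sample_t":
            g = sub[sub[group_col] == spec["group"]]["value"].astype(float)
            stat, p = one_sample_t(g, null_value=float(spec.get("null", 0.0)))
            label = f"{spec['group']} vs null {spec.get('null', 0.0)}"
        else:
            raise ContractError(f"unknown test {spec['test']!r}")
        test_rows.append(
            {"test": spec["test"], "measure": measure, "comparison": label,
             "statistic": stat, "p_value": p, "marker": significance_marker(p)}
        )
    pd.DataFrame(
        test_rows, columns=["test", "measure", "comparison", "statistic", "p_value", "marker"]
    ).to_csv(out_dir / "tests.csv", index=False)

    payload = {"qc": qc, "summaries": summaries, "tests": test_rows}
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return payload
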