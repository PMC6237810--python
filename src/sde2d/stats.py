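"""Repair-experiment statistics: classical two-sample t-tests, dose-response
summaries and report compilation."""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "RepairExperiment",
    "students_t",
    "summarize_dose_response",
    "compile_report",
]


@dataclass(frozen=True)
class TestResult:
    fraction: str
    group_a: str
    group_b: str
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    significant: bool
    alpha: float = 0.05


@dataclass
class RepairExperiment:
    """Per-condition replicate fraction percentages.

    ``conditions`` maps a condition label (e.g. ``"0 h"``, ``"24 h"``) to a
    list of replicate dicts ``{fraction_name: percentage}``.
    """

    conditions: dict[str, list[dict[str, float]]]

    def __post_init__(self) -> None:
        for label, reps in self.conditions.items():
            if len(reps) < 2:
                raise ValueError(f"condition {label!r} needs >= 2 replicates")

    @property
    def fraction_names(self) -> list[str]:
        names: list[str] = []
        for reps in self.conditions.values():
            for rep in reps:
                for k in rep:
                    if k not in names:
                        names.append(k)
        return names


def students_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    fraction: str = "",
    labels: tuple[str, str] = ("a", "b"),
    alpha: float = 0.05,
) -> TestResult:
    """Classical equal-variance two-sample t-test, two-sided.

    Implemented from the pooled-variance closed form (cross-checked against
    the reference implementation in the test suite).  Zero pooled variance
    with equal means gives ``t = 0, p = 1``; with unequal means it is an
    error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            raise ValueError("zero pooled variance with unequal means: t undefined")
    else:
        t_stat = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * float(sps.t.sf(abs(t_stat), df))
    return TestResult(
        fraction=fraction,
        group_a=labels[0],
        group_b=labels[1],
        t_statistic=float(t_stat),
        degrees_of_freedom=df,
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
    )


def summarize_dose_response(
    reports: Sequence[tuple[float, dict[str, float]]]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Mean +/- sd of each fraction versus dose, plus the Spearman rank
    correlation of each fraction (and of behind+front combined) with dose.

    Duplicate doses are collapsed (averaged) with a warning.  Constant
    fractions get rho = 0 (ties carry no rank information).
    """
    if len({d for d, _ in reports}) < 3:
        raise ValueError("need >= 3 distinct doses")
    rows = [{"dose": d, **fracs} for d, fracs in reports]
    df = pd.DataFrame(rows)
    doses = df["dose"].to_numpy()
    if len(np.unique(doses)) < len(doses):
        warnings.warn("duplicate doses collapsed by averaging", stacklevel=2)
    frac_cols = [c for c in df.columns if c != "dose"]
    if {"behind", "front"} <= set(frac_cols):
        df["behind+front"] = df["behind"] + df["front"]
        frac_cols.append("behind+front")
    summary = df.groupby("dose").agg(["mean", "std"])
    rhos: dict[str, float] = {}
    for c in frac_cols:
        y = df[c].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            rhos[c] = 0.0
        else:
            rho = sps.spearmanr(df["dose"].to_numpy(dtype=float), y).statistic
            rhos[c] = 0.0 if np.isnan(rho) else float(rho)
    return summary, rhos


def compile_report(
    experiment: RepairExperiment, alpha: float = 0.05, bonferroni: bool = False
) -> dict:
    """Fraction table plus one t-test per fraction per condition pair.

    Deterministic and idempotent; no multiple-testing correction by default
    (a Bonferroni option is available).
    """
    fractions = experiment.fraction_names
    table_rows = []
    for label, reps in experiment.conditions.items():
        for i, rep in enumerate(reps):
            table_rows.append({"condition": label, "replicate": i, **rep})
    table = pd.DataFrame(table_rows)

    pairs = list(itertools.combinations(experiment.conditions, 2))
    n_tests = max(1, len(pairs) * len(fractions))
    eff_alpha = alpha / n_tests if bonferroni else alpha
    tests: list[TestResult] = []
    for frac in fractions:
        for la, lb in pairs:
            ga = [rep[frac] for rep in experiment.conditions[la] if frac in rep]
            gb = [rep[frac] for rep in experiment.conditions[lb] if frac in rep]
            if len(ga) < 2 or len(gb) < 2:
                continue
            tests.append(students_t(ga, gb, fraction=frac, labels=(la, lb), alpha=eff_alpha))
    return {
        "fractions": table,
        "tests": tests,
        "alpha": eff_alpha,
        "summary": table.groupby("condition")[fractions].agg(["mean", "std"]),
    }
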