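"""Transfer-effect statistics on batches of simulated (or tabulated) runs.

Provides the comparisons used to characterise transfer between tasks:
Pearson correlation of Task-1 with Task-2 accuracy within each subspace
relation, the Fisher r-to-z contrast of those correlations between
relations, and paired / independent t-tests on mean accuracies.  All
p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "FisherZResult",
    "TTestResult",
    "pearson",
    "fisher_z_compare",
    "t_test",
    "transfer_summary",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float

    @property
    def df(self) -> int:
        return self.n - 2


@dataclass(frozen=True)
class FisherZResult:
    z: float
    p: float
    r1: float
    n1: int
    r2: float
    n2: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    kind: str  # "paired" | "independent"


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=len(x), p=float(res.pvalue))


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> FisherZResult:
    """Compare two independent correlations via Fisher's r-to-z transform.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), with a
    two-sided normal p-value.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not abs(r) < 1:
            raise ValueError("correlations must lie strictly in (-1, 1)")
        if n <= 3:
            raise ValueError("group sizes must exceed 3")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return FisherZResult(z=float(z), p=float(p), r1=r1, n1=n1, r2=r2, n2=n2)


def t_test(x, y, kind: str = "paired") -> TTestResult:
    """Paired or pooled-variance independent t-test (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind == "paired":
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.ptp(d) == 0:
            if d[0] == 0:  # identical samples: no effect at all
                return TTestResult(t=0.0, df=len(x) - 1, p=1.0, kind=kind)
            raise ValueError("paired differences have zero variance")
        res = stats.ttest_rel(x, y)
        df = len(x) - 1
    elif kind == "independent":
        if min(len(x), len(y)) < 2:
            raise ValueError("independent samples need length >= 2 each")
        df = len(x) + len(y) - 2
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
            return TTestResult(t=0.0, df=df, p=1.0, kind=kind)
        res = stats.ttest_ind(x, y, equal_var=True)
    else:
        raise ValueError("kind must be 'paired' or 'independent'")
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue), kind=kind)


def _summary_rows(group: pd.DataFrame, variant: str, mode: str) -> list[dict]:
    same = group[group["relation"] == "same"]
    diff = group[group["relation"] == "different"]
    if same.empty or diff.empty:
        raise ValueError("transfer summary needs both same and different conditions")

    def row(contrast, statistic, value, df=np.nan, p=np.nan):
        return {
            "variant": variant,
            "mode": mode,
            "contrast": contrast,
            "statistic": statistic,
            "value": value,
            "df": df,
            "p": p,
        }

    rows = [
        row("task1_mean_same", "mean", same["task1_acc"].mean()),
        row("task1_mean_different", "mean", diff["task1_acc"].mean()),
        row("task2_mean_same", "mean", same["task2_acc"].mean()),
        row("task2_mean_different", "mean", diff["task2_acc"].mean()),
    ]
    tt = t_test(same["task2_acc"], same["task1_acc"], kind="paired")
    rows.append(row("task2_vs_task1_same", "t", tt.t, tt.df, tt.p))
    tt = t_test(same["task2_acc"], diff["task2_acc"], kind="independent")
    rows.append(row("task2_same_vs_different", "t", tt.t, tt.df, tt.p))

    corr = {}
    for label, part in (("same", same), ("different", diff)):
        try:
            corr[label] = pearson(part["task1_acc"], part["task2_acc"])
            rows.append(
                row(f"task1_task2_corr_{label}", "r", corr[label].r, corr[label].df, corr[label].p)
            )
        except ValueError:
            rows.append(row(f"task1_task2_corr_{label}", "r", np.nan))
    if len(corr) == 2:
        fz = fisher_z_compare(
            corr["same"].r, corr["same"].n, corr["different"].r, corr["different"].n
        )
        rows.append(row("corr_same_vs_different", "z", fz.z, np.nan, fz.p))
    return rows


def transfer_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Every reported transfer contrast, per (variant, mode) batch.

    Expects the per-run table produced by ``simulation.run_batch`` with
    columns relation, variant, mode, task1_acc, task2_acc.
    """
    rows: list[dict] = []
    for (variant, mode), group in results.groupby(["variant", "mode"], sort=False):
        rows.extend(_summary_rows(group, variant, mode))
    return pd.DataFrame(rows)
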