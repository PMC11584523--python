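"""Replicate-level aggregation and two-condition statistical comparison.

Metric values are aggregated per condition as mean +/- SD over replicates
and compared per (supercluster, metric) cell with Welch's unequal-variance
t-test (two-sided).  Cells where either condition has fewer than two
replicate values are marked *untestable* rather than silently dropped,
mirroring how replicate-sparse tunnels must be reported.  No
multiple-testing correction is applied by default; Holm adjustment is
available as an option.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dynamics_stats import StatsParams, br_summary, detection_frequency

__all__ = [
    "METRICS",
    "AggregateResult",
    "WelchResult",
    "ComparisonReport",
    "aggregate_replicates",
    "welch_t",
    "student_t",
    "build_metric_table",
    "compare_conditions",
    "render_report",
    "load_report",
]

#: Metric names produced by :func:`build_metric_table`.
METRICS = ("detection_frequency", "mean_br", "max_br", "mean_length")

_EPS = 1e-300  # variance guard for degenerate zero-variance samples


@dataclass(frozen=True)
class AggregateResult:
    mean: float
    sd: float | None  # None for a single value
    n: int


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def aggregate_replicates(values: Sequence[float]) -> AggregateResult:
    """Arithmetic mean and sample SD (n-1 denominator; absent for n=1)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to aggregate")
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else None
    return AggregateResult(mean=float(v.mean()), sd=sd, n=int(v.size))


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t statistic with Satterthwaite df, two-sided p.

    Both zero-variance samples with different means yield t = +/-inf and
    p = 0 (the variance is floored at a tiny epsilon to avoid a division
    blow-up); equal constant samples yield t = 0, p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test needs at least two values per sample")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    se2 = va / na + vb / nb
    if se2 <= _EPS:
        if diff == 0:
            return WelchResult(t=0.0, df=float(na + nb - 2), p=1.0)
        return WelchResult(
            t=math.copysign(math.inf, diff), df=float(na + nb - 2), p=0.0
        )
    t = diff / math.sqrt(se2)
    df = se2**2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def student_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchResult:
    """Classical pooled-variance two-sample t-test (equal-variance variant)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Student's t-test needs at least two values per sample")
    na, nb = a.size, b.size
    df = float(na + nb - 2)
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    se2 = pooled * (1.0 / na + 1.0 / nb)
    if se2 <= _EPS:
        if diff == 0:
            return WelchResult(t=0.0, df=df, p=1.0)
        return WelchResult(t=math.copysign(math.inf, diff), df=df, p=0.0)
    t = diff / math.sqrt(se2)
    return WelchResult(t=float(t), df=df, p=float(2.0 * sps.t.sf(abs(t), df)))


def build_metric_table(
    superclusters: Sequence, params: StatsParams = StatsParams()
) -> pd.DataFrame:
    """Per-(condition, replicate, supercluster) metric values, long form."""
    rows = []
    for sc in superclusters:
        for (cond, rep), bs in sorted(sc.series.items()):
            rows.append(
                (cond, rep, sc.supercluster_id, "detection_frequency",
                 detection_frequency(bs, params))
            )
            summ = br_summary(bs)
            if summ is not None:
                rows.append((cond, rep, sc.supercluster_id, "mean_br", summ.mean_br))
                rows.append((cond, rep, sc.supercluster_id, "max_br", summ.max_br))
                if summ.mean_length is not None:
                    rows.append(
                        (cond, rep, sc.supercluster_id, "mean_length", summ.mean_length)
                    )
    return pd.DataFrame(
        rows,
        columns=["condition", "replicate_id", "supercluster_id", "metric", "value"],
    )


@dataclass
class ComparisonReport:
    """Two-condition comparison: one row per (supercluster, metric) cell."""

    condition_a: str
    condition_b: str
    alpha: float
    table: pd.DataFrame  # columns: see REPORT_COLUMNS


REPORT_COLUMNS = [
    "supercluster_id",
    "metric",
    "mean_a",
    "sd_a",
    "n_a",
    "mean_b",
    "sd_b",
    "n_b",
    "t",
    "df",
    "p",
    "significant",
    "untestable",
    "note",
]


def compare_conditions(
    metrics: pd.DataFrame,
    alpha: float = 0.05,
    holm: bool = False,
    variant: str = "welch",
) -> ComparisonReport:
    """Compare every (supercluster, metric) cell between the two conditions.

    Cells with fewer than two replicate values in either condition are
    flagged untestable (e.g. a tunnel found in one replicate only).
    ``holm`` applies a Holm step-down adjustment across testable cells;
    off by default to report raw per-metric p-values.  ``variant`` selects
    Welch (default, robust to unequal variances at 3-4 replicates) or
    ``"student"`` (pooled variance).
    """
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    test = welch_t if variant == "welch" else student_t
    conditions = list(dict.fromkeys(metrics["condition"]))
    if len(conditions) != 2:
        raise ValueError(f"exactly 2 conditions required, got {conditions}")
    cond_a, cond_b = conditions

    rows = []
    cells = metrics.groupby(["supercluster_id", "metric"], sort=True)
    for (sc_id, metric), cell in cells:
        va = cell.loc[cell["condition"] == cond_a, "value"].to_numpy()
        vb = cell.loc[cell["condition"] == cond_b, "value"].to_numpy()
        agg_a = aggregate_replicates(va) if va.size else None
        agg_b = aggregate_replicates(vb) if vb.size else None
        row = {
            "supercluster_id": sc_id,
            "metric": metric,
            "mean_a": agg_a.mean if agg_a else np.nan,
            "sd_a": agg_a.sd if agg_a and agg_a.sd is not None else np.nan,
            "n_a": agg_a.n if agg_a else 0,
            "mean_b": agg_b.mean if agg_b else np.nan,
            "sd_b": agg_b.sd if agg_b and agg_b.sd is not None else np.nan,
            "n_b": agg_b.n if agg_b else 0,
        }
        if va.size < 2 or vb.size < 2:
            row.update(
                t=np.nan, df=np.nan, p=np.nan, significant=False, untestable=True,
                note="untestable: fewer than two replicates in a condition",
            )
        else:
            res = test(va, vb)
            row.update(
                t=res.t, df=res.df, p=res.p,
                significant=bool(res.p < alpha), untestable=False, note="",
            )
        rows.append(row)
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)

    if holm and len(table):
        testable = ~table["untestable"]
        p = table.loc[testable, "p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        table.loc[testable, "p"] = adj
        table.loc[testable, "significant"] = adj < alpha

    return ComparisonReport(
        condition_a=cond_a, condition_b=cond_b, alpha=alpha, table=table
    )


def render_report(
    report: ComparisonReport,
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    """Emit the report as CSV and/or JSON; round-trips via load_report."""
    if csv_path is not None:
        table = report.table.copy()
        table.insert(0, "condition_b", report.condition_b)
        table.insert(0, "condition_a", report.condition_a)
        table.insert(0, "alpha", report.alpha)
        table.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "condition_a": report.condition_a,
            "condition_b": report.condition_b,
            "alpha": report.alpha,
            "cells": json.loads(report.table.to_json(orient="records")),
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))


def load_report(csv_path: str | Path) -> ComparisonReport:
    """Read a report written by :func:`render_report` back into memory."""
    raw = pd.read_csv(csv_path, keep_default_na=True)
    if len(raw) == 0:
        raise ValueError("empty report file")
    alpha = float(raw["alpha"].iloc[0])
    cond_a = str(raw["condition_a"].iloc[0])
    cond_b = str(raw["condition_b"].iloc[0])
    table = raw[REPORT_COLUMNS].copy()
    table["note"] = table["note"].fillna("")
    return ComparisonReport(
        condition_a=cond_a, condition_b=cond_b, alpha=alpha, table=table
    )
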