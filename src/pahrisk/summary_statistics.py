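"""Descriptive statistics, ΣPAH/PAH4 aggregates, EU-limit compliance and
the Mann-Whitney rank-sum comparison.

The surveillance convention reported here is mean ± sample SD (n−1
denominator) with median/min/max per analyte per group; between-group
differences are judged with the two-sided Mann-Whitney U test at α = 0.05,
reflecting the non-normality typical of contaminant concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import analytes
from .concentration_io import ConcentrationTable

#: EU maximum levels for fish, µg/kg wet weight.
EU_LIMITS = {"BaP": 2.0, "PAH4": 12.0}

#: Combined sample size at or below which the rank-sum test enumerates the
#: exact null distribution (tie-free data only).
EXACT_SWITCHOVER = 12


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney U test outcome for two independent groups."""

    statistic: float  # U for the first group
    p_value: float
    method: str  # "exact_enumeration" | "normal_approx_tie_corrected"
    n_a: int
    n_b: int


def summarize(
    table: ConcentrationTable,
    group_by: Sequence[str] = ("species", "cooking"),
    include_aggregates: bool = True,
) -> pd.DataFrame:
    """Per-group, per-analyte descriptive statistics.

    Returns one row per group × analyte with ``mean, median, min, max, sd,
    n`` (sd with the n−1 denominator; NaN when n = 1). With
    *include_aggregates*, per-sample ΣPAH (``TOTAL``) and ``PAH4`` sums are
    summarised as additional pseudo-analyte rows, matching the published
    table layout.
    """
    df = table.data.copy()
    group_by = list(group_by)
    if include_aggregates:
        df = pd.concat([df, _per_sample_aggregates(df)], ignore_index=True)

    def _agg(g: pd.DataFrame) -> pd.Series:
        x = g["concentration"].to_numpy(dtype=float)
        return pd.Series(
            {
                "mean": x.mean(),
                "median": float(np.median(x)),
                "min": x.min(),
                "max": x.max(),
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
                "n": len(x),
            }
        )

    out = (
        df.groupby(group_by + ["analyte"], sort=False, observed=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    if (out["n"] == 1).any():
        warnings.warn("groups with a single record: sd undefined (NaN)", stacklevel=2)
    order = {a: i for i, a in enumerate(analytes.CANONICAL + analytes.AGGREGATES)}
    out = out.sort_values(
        group_by + ["analyte"], key=lambda s: s.map(order) if s.name == "analyte" else s
    ).reset_index(drop=True)
    return out


def _per_sample_aggregates(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample TOTAL and PAH4 rows (sum over the analytes present)."""
    rows = []
    keys = ["sample_id", "species", "cooking", "replicate"]
    for vals, g in df.groupby(keys, sort=False):
        present = dict(zip(g["analyte"], g["concentration"]))
        rec = dict(zip(keys, vals))
        rows.append({**rec, "analyte": "TOTAL", "concentration": sum(present.values())})
        if all(m in present for m in analytes.PAH4_MEMBERS):
            rows.append(
                {
                    **rec,
                    "analyte": "PAH4",
                    "concentration": sum(present[m] for m in analytes.PAH4_MEMBERS),
                }
            )
    return pd.DataFrame(rows)


def total_pah(values: Mapping[str, float], missing_as_zero: bool = False) -> float:
    """Σ16 PAH: arithmetic sum over the 16 priority analytes.

    *values* maps analyte labels (codes or full names) to concentrations in
    µg/kg. All 16 analytes must be present unless *missing_as_zero*.
    """
    resolved = {analytes.resolve(k): float(v) for k, v in values.items()}
    missing = [a for a in analytes.CANONICAL if a not in resolved]
    if missing and not missing_as_zero:
        raise KeyError(f"missing analyte(s): {', '.join(missing)}")
    return sum(resolved.get(a, 0.0) for a in analytes.CANONICAL)


def pah4(values: Mapping[str, float]) -> float:
    """EU PAH4 aggregate: BaA + Chr + BbF + BaP (µg/kg)."""
    resolved = {analytes.resolve(k): float(v) for k, v in values.items()}
    for member in analytes.PAH4_MEMBERS:
        if member not in resolved:
            raise KeyError(f"PAH4 member missing: {member}")
    return sum(resolved[m] for m in analytes.PAH4_MEMBERS)


def eu_compliance(
    summary: pd.DataFrame, limits: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Flag each group's mean BaP and PAH4 against the EU maximum levels.

    Returns one row per group × {BaP, PAH4} with the mean, the limit and
    ``compliant = (mean <= limit)``.
    """
    limits = dict(EU_LIMITS if limits is None else limits)
    group_cols = [c for c in ("species", "cooking") if c in summary.columns]
    rows = []
    for keys, g in summary.groupby(group_cols, sort=False, observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        by_analyte = g.set_index("analyte")["mean"]
        for analyte, limit in limits.items():
            if analyte not in by_analyte.index:
                raise KeyError(f"summary lacks a {analyte} row for group {keys}")
            mean = float(by_analyte[analyte])
            rows.append(
                dict(zip(group_cols, keys))
                | {
                    "analyte": analyte,
                    "mean": mean,
                    "limit": float(limit),
                    "compliant": mean <= limit,
                }
            )
    return pd.DataFrame(rows)


def rank_sum_test(
    group_a: Iterable[float],
    group_b: Iterable[float],
    alternative: str = "two-sided",
) -> RankTestResult:
    """Mann-Whitney U test for two independent samples.

    Uses exact enumeration of the rank-assignment null distribution when the
    combined sample size is ≤ 12 and the pooled data are tie-free; otherwise
    the normal approximation with tie-corrected variance and continuity
    correction. The statistic reported is U for *group_a*.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == pooled.size
    if pooled.size <= EXACT_SWITCHOVER and tie_free:
        u, p = _exact_mwu(a, b, alternative)
        method = "exact_enumeration"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative=alternative, method="asymptotic", use_continuity=True
        )
        u, p = float(res.statistic), float(res.pvalue)
        method = "normal_approx_tie_corrected"
    return RankTestResult(u, p, method, a.size, b.size)


def _exact_mwu(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    """Enumerate all C(n, nA) rank assignments of tie-free pooled data."""
    na, nb = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2)
    n = na + nb
    mu = na * nb / 2
    rank_values = np.arange(1, n + 1)
    count = 0
    for combo in combinations(range(n), na):
        u = rank_values[list(combo)].sum() - na * (na + 1) / 2
        if alternative == "two-sided":
            hit = abs(u - mu) >= abs(u_obs - mu) - 1e-12
        elif alternative == "greater":
            hit = u >= u_obs - 1e-12
        elif alternative == "less":
            hit = u <= u_obs + 1e-12
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        count += hit
    return u_obs, count / comb(n, na)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values (optional; the
    source analysis reports uncorrected per-analyte p-values)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
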