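"""Synthetic per-sample concentration tables calibrated to published
group summaries.

The source survey released only per-group summary statistics (mean, median,
min, max, SD per analyte per group), not per-fish measurements. This module
turns each summary row into a parametric sampling distribution by moment
matching and draws reproducible per-sample tables from it, so the whole
downstream pipeline (aggregation, BaP-equivalents, intake, risk) can be
exercised and tested end to end.

Bounded concentrations are modelled by default as normal distributions
truncated to the printed [min, max]; truncation biases the naive plug-in
moments, so the underlying (µ, σ) are adjusted numerically until the
*truncated* mean matches the printed mean (and the SD as closely as the
family allows — pooled cross-group rows are mixtures and can print an SD
above any truncated normal's maximum on that range; see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import analytes
from ._rng import substream
from .concentration_io import ConcentrationTable

FAMILIES = ("point", "truncated_normal", "lognormal", "uniform", "triangular")

#: Relative tolerance for the iterative truncated-moment adjustment.
FIT_RTOL = 1e-6
FIT_MAX_ITER = 100


@dataclass(frozen=True)
class DistributionSpec:
    """A univariate sampling distribution in measurement units.

    ``loc``/``scale`` are family-specific: the underlying normal µ/σ for
    ``truncated_normal``; log-space µ/σ for ``lognormal``; the value for
    ``point``; the mode for ``triangular``. ``lo``/``hi`` are hard
    truncation bounds where applicable.
    """

    family: str
    loc: float = 0.0
    scale: float = 0.0
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.lo is not None and self.hi is not None and self.lo > self.hi:
            raise ValueError(f"lo {self.lo} > hi {self.hi}")

    # -- analytic moments -------------------------------------------------
    def _frozen(self):
        if self.family == "truncated_normal":
            a = (self.lo - self.loc) / self.scale
            b = (self.hi - self.loc) / self.scale
            return stats.truncnorm(a, b, loc=self.loc, scale=self.scale)
        if self.family == "lognormal":
            return stats.lognorm(s=self.scale, scale=np.exp(self.loc))
        if self.family == "uniform":
            return stats.uniform(self.lo, self.hi - self.lo)
        if self.family == "triangular":
            w = self.hi - self.lo
            return stats.triang((self.loc - self.lo) / w, loc=self.lo, scale=w)
        raise ValueError(self.family)

    def mean(self) -> float:
        """Analytic mean of the (truncated) distribution."""
        if self.family == "point":
            return self.loc
        if self.family == "lognormal" and self.lo is not None:
            return self._truncated_lognorm_moments()[0]
        return float(self._frozen().mean())

    def sd(self) -> float:
        """Analytic standard deviation of the (truncated) distribution."""
        if self.family == "point":
            return 0.0
        if self.family == "lognormal" and self.lo is not None:
            return self._truncated_lognorm_moments()[1]
        return float(self._frozen().std())

    def _truncated_lognorm_moments(self) -> tuple[float, float]:
        d = self._frozen()
        m1 = d.expect(lambda x: x, lb=self.lo, ub=self.hi, conditional=True)
        m2 = d.expect(lambda x: x * x, lb=self.lo, ub=self.hi, conditional=True)
        return float(m1), float(np.sqrt(max(m2 - m1 * m1, 0.0)))

    # -- sampling ----------------------------------------------------------
    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw *n* values; inverse-CDF transform of ``rng.random`` so the
        draws are a deterministic function of the generator state."""
        if self.family == "point":
            return np.full(n, self.loc)
        u = rng.random(n)
        if self.family == "uniform":
            return self.lo + (self.hi - self.lo) * u
        d = self._frozen()
        if self.family in ("lognormal",) and self.lo is not None:
            flo, fhi = d.cdf(self.lo), d.cdf(self.hi)
            u = flo + (fhi - flo) * u
        x = d.ppf(u)
        if self.lo is not None:
            x = np.clip(x, self.lo, self.hi)
        return x


@dataclass
class GeneratorPlan:
    """Everything needed to synthesise one concentration table.

    ``specs`` maps (species, cooking) → {analyte code → DistributionSpec};
    ``n`` is the replicate count per group (the source survey used
    triplicates); draws are keyed off ``seed`` per (group, analyte) so
    adding a cell never perturbs another cell's values.
    """

    specs: dict[tuple[str, str], dict[str, DistributionSpec]]
    n: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("replicate count n must be >= 1")
        for group, cell in self.specs.items():
            missing = [a for a in analytes.CANONICAL if a not in cell]
            if missing:
                raise ValueError(
                    f"group {group}: missing spec for analyte(s) {', '.join(missing)}"
                )


def fit_distribution(
    row: Mapping[str, float] | pd.Series, family: str = "truncated_normal"
) -> DistributionSpec:
    """Moment-match a sampling distribution to a summary row.

    *row* must provide ``mean, sd, min, max``. A zero (or missing) SD
    degenerates to a point mass at the mean. For ``truncated_normal`` the
    underlying µ, σ are adjusted numerically (≤ :data:`FIT_MAX_ITER`
    evaluations, relative tolerance :data:`FIT_RTOL`) so the truncated mean
    equals the row mean; σ additionally targets the row SD, saturating at
    the family's maximum when the printed SD is unattainable on [min, max].
    """
    m, s = float(row["mean"]), float(row["sd"])
    lo, hi = float(row["min"]), float(row["max"])
    if hi < lo:
        raise ValueError(f"max {hi} < min {lo}")
    if not np.isfinite(s) or s == 0.0 or hi == lo:
        return DistributionSpec("point", loc=m)
    if family == "uniform":
        return DistributionSpec("uniform", lo=lo, hi=hi)
    if family == "triangular":
        mode = min(max(3.0 * m - lo - hi, lo), hi)
        return DistributionSpec("triangular", loc=mode, lo=lo, hi=hi)
    if family == "truncated_normal":
        mu, sigma = _fit_truncnorm(m, s, lo, hi)
        return DistributionSpec("truncated_normal", loc=mu, scale=sigma, lo=lo, hi=hi)
    if family == "lognormal":
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        return DistributionSpec(
            "lognormal", loc=float(mu), scale=float(np.sqrt(sigma2)), lo=lo, hi=hi
        )
    if family == "point":
        return DistributionSpec("point", loc=m)
    raise ValueError(f"unsupported family {family!r}")


def _tn_mean_sd(mu: float, sigma: float, lo: float, hi: float) -> tuple[float, float]:
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    mean, var = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(mean), float(np.sqrt(var))


def _fit_truncnorm(m: float, s: float, lo: float, hi: float) -> tuple[float, float]:
    """Underlying (µ, σ) whose [lo, hi]-truncation reproduces mean *m* and,
    as far as attainable, SD *s*."""
    w = hi - lo

    def residual(x):
        mu, log_sigma = x
        tm, ts = _tn_mean_sd(mu, np.exp(log_sigma), lo, hi)
        return [(tm - m) / w, (ts - s) / w]

    res = optimize.least_squares(
        residual,
        x0=[m, np.log(min(s, 0.9 * w))],
        bounds=([lo - 10 * w, np.log(1e-4 * w)], [hi + 10 * w, np.log(50 * w)]),
        max_nfev=FIT_MAX_ITER,
        xtol=FIT_RTOL,
        ftol=FIT_RTOL,
    )
    mu, sigma = res.x[0], float(np.exp(res.x[1]))

    # refine µ at fixed σ so the truncated mean is matched to high precision;
    # expand the bracket geometrically until it straddles the target
    def mean_err(mu_):
        return _tn_mean_sd(mu_, sigma, lo, hi)[0] - m

    span = w
    for _ in range(20):
        a, b = lo - span, hi + span
        if mean_err(a) <= 0.0 <= mean_err(b):
            mu = optimize.brentq(mean_err, a, b, xtol=FIT_RTOL * w)
            break
        span *= 2.0
    return float(mu), sigma


def plan_from_summary(
    summary: pd.DataFrame,
    n: int = 3,
    seed: int = 0,
    family: str = "truncated_normal",
) -> GeneratorPlan:
    """Build a complete plan from a summary table (fixture or computed).

    Aggregate rows (TOTAL, PAH4) are skipped — aggregates are recomputed
    from the generated per-analyte values downstream.
    """
    specs: dict[tuple[str, str], dict[str, DistributionSpec]] = {}
    for _, row in summary.iterrows():
        if row["analyte"] in analytes.AGGREGATES:
            continue
        key = (str(row.get("species", "all")), str(row.get("cooking", "all")))
        specs.setdefault(key, {})[row["analyte"]] = fit_distribution(row, family)
    return GeneratorPlan(specs=specs, n=n, seed=seed)


def generate(plan: GeneratorPlan) -> ConcentrationTable:
    """Draw a per-sample concentration table from *plan*.

    Deterministic under a fixed seed; every draw respects its cell's
    truncation bounds. Sample ids are ``<species>-<cooking>-r<k>``.
    """
    frames = []
    for (species, cooking), cell in plan.specs.items():
        draws = {}
        for analyte in analytes.CANONICAL:
            rng = substream(plan.seed, "conc", species, cooking, analyte)
            x = cell[analyte].sample(rng, plan.n)
            spec = cell[analyte]
            if spec.lo is not None and (
                (x < spec.lo - 1e-12).any() or (x > spec.hi + 1e-12).any()
            ):
                raise AssertionError(
                    f"draw outside bounds for {(species, cooking, analyte)}"
                )
            draws[analyte] = x
        for k in range(plan.n):
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": f"{species}-{cooking}-r{k + 1}",
                        "species": species,
                        "cooking": cooking,
                        "replicate": k + 1,
                        "analyte": list(analytes.CANONICAL),
                        "concentration": [draws[a][k] for a in analytes.CANONICAL],
                    }
                )
            )
    return ConcentrationTable(pd.concat(frames, ignore_index=True))


def recovery_report(
    generated: ConcentrationTable,
    target: pd.DataFrame,
    tolerance: float = 0.02,
) -> pd.DataFrame:
    """Relative error of the generated table's summaries vs their targets.

    Joins on (species, cooking, analyte); reports
    ``|sample stat − target| / target`` for mean and sd and flags cells
    whose mean error exceeds *tolerance*. Raises if no cells overlap.
    """
    from .summary_statistics import summarize

    got = summarize(generated, group_by=("species", "cooking"), include_aggregates=False)
    merged = got.merge(
        target[["species", "cooking", "analyte", "mean", "sd"]],
        on=["species", "cooking", "analyte"],
        suffixes=("_obs", "_target"),
    )
    if merged.empty:
        raise ValueError("no overlapping (group, analyte) cells between tables")
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["mean_rel_err"] = np.abs(
            merged["mean_obs"] - merged["mean_target"]
        ) / np.abs(merged["mean_target"])
        merged["sd_rel_err"] = np.abs(merged["sd_obs"] - merged["sd_target"]) / np.abs(
            merged["sd_target"]
        )
    merged["flagged"] = merged["mean_rel_err"] > tolerance
    cols = [
        "species", "cooking", "analyte",
        "mean_obs", "mean_target", "mean_rel_err",
        "sd_obs", "sd_target", "sd_rel_err", "n", "flagged",
    ]
    return merged[cols]
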