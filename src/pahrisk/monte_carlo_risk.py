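"""Seeded Monte Carlo propagation of concentration and exposure-parameter
uncertainty into daily intake (EDI) and incremental lifetime cancer risk.

Per iteration the engine draws an analyte concentration profile, collapses
it to a BaP-equivalent concentration (BEC), draws exposure parameters per
population, and computes

    EDI  = BEC_mg · IR · (EF · ED) / (BW · AT)
    ILCR = EDI · SF

Two printed forms of the risk equation circulate — risk as EDI × SF and
risk written directly from the BaP-equivalent concentration. Read naively
the second omits the intake rate and is dimensionally inconsistent with
the first, so this engine defines the BEC route as the EDI route applied
to the BaP-equivalent concentration; the two are then algebraically
identical on every draw, which is asserted by tests.

ILCR bands follow the usual regulatory convention: < 10⁻⁶ negligible,
10⁻⁶–10⁻⁴ acceptable, > 10⁻⁴ serious.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import analytes
from ._rng import substream
from .concentration_io import load_fixture
from .exposure_model import ExposureParameters, edi, to_mg_per_kg
from .synthetic_generator import DistributionSpec, fit_distribution
from .toxic_equivalents import TEFTable, bec, builtin_tef

RISK_BANDS = ("negligible", "acceptable", "serious")
NEGLIGIBLE_BELOW = 1e-6
SERIOUS_ABOVE = 1e-4


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo run settings."""

    iterations: int = 10_000
    seed: int = 0
    percentiles: tuple[float, ...] = (5.0, 50.0, 75.0, 95.0)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        p = np.asarray(self.percentiles, dtype=float)
        if p.size == 0 or (p <= 0).any() or (p >= 100).any() or (np.diff(p) <= 0).any():
            raise ValueError("percentiles must be strictly increasing within (0, 100)")


@dataclass
class RiskResult:
    """Draws and percentile summaries of one Monte Carlo run.

    ``draws`` maps population → {"bec", "edi", "ilcr"} → per-iteration
    arrays; ``table`` is the long percentile summary; ``classification``
    maps population → risk band of the ILCR at *classify_at* percent.
    """

    draws: dict[str, dict[str, np.ndarray]]
    percentiles: tuple[float, ...]
    classify_at: float
    config: McConfig
    table: pd.DataFrame = field(init=False)
    classification: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for pop, d in self.draws.items():
            for quantity in ("edi", "ilcr"):
                q = percentile_table(d[quantity], self.percentiles)
                for p, v in zip(self.percentiles, q):
                    rows.append(
                        {"population": pop, "quantity": quantity,
                         "percentile": p, "value": v}
                    )
        self.table = pd.DataFrame(rows)
        self.classification = {
            pop: classify_risk(
                float(np.percentile(d["ilcr"], self.classify_at))
            )
            for pop, d in self.draws.items()
        }


def ilcr_from_edi(edi_value, sf):
    """Incremental lifetime cancer risk: EDI × SF (dimensionless)."""
    e = np.asarray(edi_value, dtype=float)
    s = np.asarray(sf, dtype=float)
    if (e < 0).any() or (s < 0).any():
        raise ValueError("EDI and SF must be non-negative")
    out = e * s
    return float(out) if np.ndim(out) == 0 else out


def ilcr_from_bec(bec_ug_per_kg, params: ExposureParameters, **overrides):
    """ILCR from a BaP-equivalent concentration (µg/kg).

    Defined as the EDI route applied to the BEC, so it equals
    ``ilcr_from_edi(edi(to_mg_per_kg(BEC), params), SF)`` exactly.
    """
    sf = overrides.pop("SF", params.SF)
    return ilcr_from_edi(edi(to_mg_per_kg(bec_ug_per_kg), params, **overrides), sf)


def percentile_table(draws, percentiles: Sequence[float]) -> np.ndarray:
    """Empirical quantiles by linear interpolation of order statistics."""
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("no draws")
    return np.percentile(x, list(percentiles), method="linear")


def classify_risk(
    ilcr: float,
    negligible_below: float = NEGLIGIBLE_BELOW,
    serious_above: float = SERIOUS_ABOVE,
) -> str:
    """Risk band of a single ILCR value."""
    if ilcr < 0:
        raise ValueError("ILCR must be non-negative")
    if ilcr < negligible_below:
        return "negligible"
    if ilcr > serious_above:
        return "serious"
    return "acceptable"


ParamSpec = DistributionSpec | float


def run_monte_carlo(
    conc_dists: Mapping[str, DistributionSpec],
    param_dists: Mapping[str, Mapping[str, ParamSpec]],
    tef: TEFTable,
    config: McConfig,
    classify_at: float = 95.0,
) -> RiskResult:
    """Propagate input uncertainty into EDI and ILCR per population.

    Parameters
    ----------
    conc_dists
        Analyte code → concentration distribution (µg/kg). Point specs give
        a degenerate (deterministic) concentration.
    param_dists
        Population → {IR, EF, ED, BW, AT, SF → spec or fixed value}.
    tef
        TEF scheme for the BEC collapse.
    config
        Iterations, seed, percentiles. Every stochastic input draws from
        its own substream of the master seed, so toggling one input's
        stochasticity never perturbs the others.
    """
    n = config.iterations
    missing = [a for a in analytes.CANONICAL if a not in conc_dists]
    if missing:
        raise KeyError(f"no concentration spec for analyte(s): {', '.join(missing)}")

    conc_draws = {
        a: conc_dists[a].sample(substream(config.seed, "mc", "conc", a), n)
        for a in analytes.CANONICAL
    }
    # BEC per iteration: Σ_i C_i(t) × TEF_i, kept consistent with bec()
    bec_draws = np.zeros(n)
    for a in analytes.CANONICAL:
        bec_draws += conc_draws[a] * tef.values[a]
    # spot-check linear collapse against the scalar implementation
    first = bec({a: conc_draws[a][0] for a in analytes.CANONICAL}, tef).total
    if not np.isclose(first, bec_draws[0], rtol=1e-12, atol=0.0):
        raise AssertionError("vectorised BEC disagrees with scalar bec()")

    draws: dict[str, dict[str, np.ndarray]] = {}
    for pop, specs in param_dists.items():
        vals: dict[str, np.ndarray | float] = {}
        for name in ("IR", "EF", "ED", "BW", "AT", "SF"):
            if name not in specs:
                raise KeyError(f"population {pop!r}: missing spec for {name}")
            spec = specs[name]
            if isinstance(spec, DistributionSpec):
                vals[name] = spec.sample(substream(config.seed, "mc", pop, name), n)
            else:
                vals[name] = float(spec)
        base = ExposureParameters(
            IR=float(np.mean(vals["IR"])), EF=min(float(np.mean(vals["EF"])), 365.0),
            ED=float(np.mean(vals["ED"])), BW=float(np.mean(vals["BW"])),
            AT=float(np.mean(vals["AT"])), SF=float(np.mean(vals["SF"])),
            population=pop,
        )
        edi_draws = edi(
            to_mg_per_kg(bec_draws), base,
            IR=vals["IR"], EF=vals["EF"], ED=vals["ED"],
            BW=vals["BW"], AT=vals["AT"],
        )
        ilcr_draws = ilcr_from_edi(edi_draws, vals["SF"])
        draws[pop] = {
            "bec": bec_draws,
            "edi": np.atleast_1d(edi_draws),
            "ilcr": np.atleast_1d(ilcr_draws),
        }
    return RiskResult(draws, tuple(config.percentiles), classify_at, config)


def default_concentration_dists(
    family: str = "truncated_normal",
) -> dict[str, DistributionSpec]:
    """Per-analyte concentration distributions moment-matched to the pooled
    all-samples summary table."""
    rows = load_fixture("table2_all")
    out = {}
    for _, row in rows.iterrows():
        if row["analyte"] in analytes.AGGREGATES:
            continue
        out[row["analyte"]] = fit_distribution(row, family)
    return out


def default_param_dists() -> dict[str, dict[str, ParamSpec]]:
    """Default stochastic exposure parameters for adults and children.

    Intake rate and body weight vary (truncated normal); frequency,
    duration, averaging time and slope factor are fixed. See
    docs/methods.md for the rationale behind each value.
    """
    return {
        "adults": {
            "IR": DistributionSpec("truncated_normal", loc=0.02, scale=0.005,
                                   lo=0.005, hi=0.05),
            "BW": DistributionSpec("truncated_normal", loc=70.0, scale=10.0,
                                   lo=45.0, hi=100.0),
            "EF": 365.0, "ED": 70.0, "AT": 70.0 * 365.0, "SF": 7.3,
        },
        "children": {
            "IR": DistributionSpec("truncated_normal", loc=0.0197, scale=0.005,
                                   lo=0.004, hi=0.05),
            "BW": DistributionSpec("truncated_normal", loc=15.0, scale=3.0,
                                   lo=8.0, hi=25.0),
            "EF": 365.0, "ED": 70.0, "AT": 70.0 * 365.0, "SF": 7.3,
        },
    }


def default_simulation(
    seed: int,
    iterations: int = 10_000,
    tef_scheme: str = "usepa_dahA1",
    percentiles: Sequence[float] = (5.0, 50.0, 75.0, 95.0),
) -> RiskResult:
    """The default end-to-end probabilistic assessment.

    Concentrations from the pooled summary fixture, default adult/children
    exposure distributions, default TEF scheme, 10,000 iterations.
    """
    config = McConfig(iterations=iterations, seed=seed,
                      percentiles=tuple(percentiles))
    return run_monte_carlo(
        default_concentration_dists(),
        default_param_dists(),
        builtin_tef(tef_scheme),
        config,
    )
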