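"""Deterministic dietary intake (EDI) and the unit bookkeeping around it.

The estimated daily intake of a contaminant through fish consumption is

    EDI = C · IR · (EF · ED) / (BW · AT)      [mg / kg bw / day]

with C the concentration in the food (mg/kg), IR the daily intake of fish
(kg/day), EF the exposure frequency (days/year), ED the exposure duration
(years) — so EF·ED is the total number of exposed days — BW the body weight
(kg) and AT the averaging time (days; lifetime for carcinogens).
Concentrations are reported in µg/kg and converted here so that EDI times
the oral slope factor SF ((mg/(kg·day))⁻¹) is a dimensionless lifetime risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: WHO screening threshold for dietary BaP, mg/kg bw/day (10 ng/kg bw/day).
WHO_BAP_THRESHOLD = 1e-5

#: Oral carcinogenic slope factor for BaP, (mg/(kg·day))^-1.
DEFAULT_SF = 7.3


@dataclass(frozen=True)
class ExposureParameters:
    """Point values of the exposure equation for one population.

    Defaults describe a lifetime-averaged adult consumer: BW 70 kg,
    IR 20 g fish/day, daily exposure over a 70-year duration averaged over
    the same 70 years (EF·ED/AT = 1). The children defaults keep the same
    lifetime averaging with BW 15 kg and IR chosen to give a
    children/adult intake-per-kg ratio of ≈ 4.6.
    """

    IR: float = 0.02  # kg/day
    EF: float = 365.0  # days/year
    ED: float = 70.0  # years
    BW: float = 70.0  # kg
    AT: float = 70.0 * 365.0  # days
    SF: float = DEFAULT_SF  # (mg/(kg·day))^-1
    population: str = "adults"

    def __post_init__(self) -> None:
        for name in ("IR", "EF", "ED", "BW", "AT", "SF"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.EF > 365.0:
            raise ValueError(f"EF {self.EF} days/year exceeds 365")
        if self.AT < self.ED * self.EF:
            warnings.warn(
                f"averaging time AT={self.AT} d is shorter than the exposed "
                f"period ED*EF={self.ED * self.EF} d",
                stacklevel=2,
            )

    @classmethod
    def adults(cls, **overrides) -> "ExposureParameters":
        return cls(population="adults", **overrides)

    @classmethod
    def children(cls, **overrides) -> "ExposureParameters":
        defaults = dict(IR=0.0197, BW=15.0, population="children")
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class Dose:
    """A body-weight-normalised daily dose in mg/kg bw/day."""

    value: float
    population: str = "adults"
    provenance: str = "point"  # "point" | "draw"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"dose must be non-negative, got {self.value}")


def to_mg_per_kg(concentration_ug_per_kg):
    """Exact µg/kg → mg/kg unit bridge (× 10⁻³)."""
    c = np.asarray(concentration_ug_per_kg, dtype=float)
    if (c < 0).any():
        raise ValueError("concentration must be non-negative")
    out = c * 1e-3
    return float(out) if out.ndim == 0 else out


def edi(concentration_mg_per_kg, params: ExposureParameters,
        IR=None, EF=None, ED=None, BW=None, AT=None):
    """Estimated daily intake, mg/kg bw/day.

    Accepts scalars or numpy arrays in every slot (the Monte Carlo engine
    passes per-draw vectors via the keyword overrides); broadcasting
    applies. Monotone increasing in C, IR, EF, ED and decreasing in BW, AT.
    """
    C = np.asarray(concentration_mg_per_kg, dtype=float)
    if (C < 0).any():
        raise ValueError("concentration must be non-negative")
    IR = params.IR if IR is None else np.asarray(IR, dtype=float)
    EF = params.EF if EF is None else np.asarray(EF, dtype=float)
    ED = params.ED if ED is None else np.asarray(ED, dtype=float)
    BW = params.BW if BW is None else np.asarray(BW, dtype=float)
    AT = params.AT if AT is None else np.asarray(AT, dtype=float)
    if np.any(np.asarray(BW) <= 0) or np.any(np.asarray(AT) <= 0):
        raise ValueError("BW and AT must be strictly positive")
    out = C * IR * (EF * ED) / (BW * AT)
    return float(out) if np.ndim(out) == 0 else out


def edi_dose(concentration_mg_per_kg: float, params: ExposureParameters) -> Dose:
    """Scalar :func:`edi` wrapped with population provenance."""
    return Dose(edi(concentration_mg_per_kg, params), params.population, "point")


def who_bap_screen(dose: Dose | float, threshold: float = WHO_BAP_THRESHOLD) -> bool:
    """Screen a BaP dose against the WHO dietary guidance value.

    Returns True (pass) iff the dose is strictly below the threshold
    (default 10 ng/kg bw/day); a dose exactly at the threshold fails.
    """
    value = dose.value if isinstance(dose, Dose) else float(dose)
    return value < threshold
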