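"""Toxicity equivalency factors (TEF) and BaP-equivalent concentrations.

Individual PAHs differ widely in carcinogenic potency, so mixture exposure
is expressed on a common scale by weighting each analyte's concentration by
its TEF relative to benzo[a]pyrene (TEF = 1) and summing:

    BEC = Σ_i C_i × TEF_i        [µg BaP-eq / kg]

Two widely used schemes ship built in; they differ only in the
dibenz[a,h]anthracene factor (1 vs 5). The default keeps DahA = 1.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from . import analytes

_BASE_TEF = {
    "BaP": 1.0, "DahA": 1.0,
    "BaA": 0.1, "BbF": 0.1, "BkF": 0.1, "IcdP": 0.1,
    "An": 0.01, "Chr": 0.01, "BgP": 0.01,
    "Nap": 0.001, "Acy": 0.001, "Ace": 0.001, "Fle": 0.001,
    "Ph": 0.001, "Fla": 0.001, "Py": 0.001,
}

SCHEMES = ("usepa_dahA1", "nisbet_lagoy_dahA5")


@dataclass(frozen=True)
class TEFTable:
    """Analyte → TEF mapping with scheme provenance."""

    values: Mapping[str, float]
    scheme: str
    reference: str = ""

    def __post_init__(self) -> None:
        missing = [a for a in analytes.CANONICAL if a not in self.values]
        if missing:
            raise ValueError(f"TEF table missing analyte(s): {', '.join(missing)}")
        if any(v < 0 for v in self.values.values()):
            raise ValueError("TEFs must be non-negative")
        if self.values.get("BaP") != 1.0:
            warnings.warn(
                f"scheme {self.scheme!r} has TEF(BaP) = {self.values.get('BaP')}, "
                "expected 1 (BaP is the normalisation anchor)",
                stacklevel=2,
            )

    def __getitem__(self, analyte: str) -> float:
        return self.values[analytes.resolve(analyte)]


@dataclass(frozen=True)
class BecResult:
    """Total BaP-equivalent concentration with per-analyte breakdown."""

    total: float  # µg/kg
    contributions: Mapping[str, float]  # µg/kg per analyte
    fractions: Mapping[str, float] | None  # of total; None when total == 0

    @property
    def fractions_defined(self) -> bool:
        return self.fractions is not None


def builtin_tef(scheme: str = "usepa_dahA1") -> TEFTable:
    """One of the shipped TEF schemes.

    ``usepa_dahA1`` keeps dibenz[a,h]anthracene at 1; ``nisbet_lagoy_dahA5``
    raises it to 5 (all other factors identical).
    """
    if scheme == "usepa_dahA1":
        return TEFTable(dict(_BASE_TEF), scheme, reference="USEPA-style potency ranking")
    if scheme == "nisbet_lagoy_dahA5":
        vals = dict(_BASE_TEF)
        vals["DahA"] = 5.0
        return TEFTable(vals, scheme, reference="Nisbet & LaGoy potency ranking")
    raise LookupError(f"unknown TEF scheme {scheme!r}; choose from {SCHEMES}")


def bec(concentrations: Mapping[str, float], tef: TEFTable) -> BecResult:
    """BaP-equivalent concentration of an analyte profile (µg/kg).

    Linear and monotone in each concentration; every analyte present in
    *concentrations* must have a TEF.
    """
    contrib: dict[str, float] = {}
    for name, c in concentrations.items():
        code = analytes.resolve(name)
        if code not in tef.values:
            raise KeyError(f"analyte {code} missing from TEF scheme {tef.scheme!r}")
        if c < 0:
            raise ValueError(f"negative concentration for {code}: {c}")
        contrib[code] = float(c) * tef.values[code]
    total = sum(contrib.values())
    fractions = {a: v / total for a, v in contrib.items()} if total > 0 else None
    return BecResult(total=total, contributions=contrib, fractions=fractions)


def contribution_ranking(result: BecResult) -> list[tuple[str, float]]:
    """Analytes by descending share of the total BEC.

    Ties broken by canonical analyte order; requires a positive total.
    """
    if not result.fractions_defined:
        raise ValueError("ranking undefined: total BEC is zero")
    return sorted(
        result.fractions.items(),
        key=lambda kv: (-kv[1], analytes.canonical_index(kv[0])),
    )


def write_tef_csv(tef: TEFTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["analyte", "tef", "scheme"])
        for a in analytes.CANONICAL:
            w.writerow([a, tef.values[a], tef.scheme])
    return path


def read_tef_csv(path: str | Path) -> TEFTable:
    """User-supplied scheme; the BaP = 1 anchor is enforced as a warning."""
    values: dict[str, float] = {}
    scheme = Path(path).stem
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            values[analytes.resolve(row["analyte"])] = float(row["tef"])
            scheme = row.get("scheme", scheme) or scheme
    return TEFTable(values, scheme, reference=str(path))
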