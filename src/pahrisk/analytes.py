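"""Registry of the 16 priority PAH analytes and the regulatory aggregates.

Short codes follow the common surveillance convention (Nap, BaP, DahA, ...).
Full chemical names, with any bracket style or spacing, resolve
case-insensitively to the canonical codes.
"""

from __future__ import annotations

import re

#: Canonical order of the 16 priority PAHs, lightest to heaviest ring systems.
CANONICAL: tuple[str, ...] = (
    "Nap", "Acy", "Ace", "Fle", "Ph", "An", "Fla", "Py",
    "BaA", "Chr", "BbF", "BkF", "BaP", "DahA", "BgP", "IcdP",
)

#: EU PAH4 marker set: benz[a]anthracene, chrysene, benzo[b]fluoranthene,
#: benzo[a]pyrene.
PAH4_MEMBERS: tuple[str, ...] = ("BaA", "Chr", "BbF", "BaP")

#: Aggregate keys allowed alongside single analytes in summary tables.
AGGREGATES: tuple[str, ...] = ("TOTAL", "PAH4")

_FULL_NAMES = {
    "naphthalene": "Nap",
    "acenaphthylene": "Acy",
    "acenaphthene": "Ace",
    "fluorene": "Fle",
    "phenanthrene": "Ph",
    "anthracene": "An",
    "fluoranthene": "Fla",
    "pyrene": "Py",
    "benzaanthracene": "BaA",
    "benzoaanthracene": "BaA",
    "chrysene": "Chr",
    "benzobfluoranthene": "BbF",
    "benzokfluoranthene": "BkF",
    "benzoapyrene": "BaP",
    "dibenzahanthracene": "DahA",
    "dibenzoahanthracene": "DahA",
    "benzoghiperylene": "BgP",
    "indeno123cdpyrene": "IcdP",
    "totalpahs": "TOTAL",
    "totalpah": "TOTAL",
    "sumpahs": "TOTAL",
    "pah16": "TOTAL",
}

_CODES_LOWER = {c.lower(): c for c in CANONICAL + AGGREGATES}


class UnknownAnalyteError(KeyError):
    """Raised when a label cannot be resolved to a canonical analyte code."""


def _squash(name: str) -> str:
    return re.sub(r"[\s\[\]\(\)\,\-\.]+", "", name.lower())


def resolve(name: str, allow_aggregates: bool = False) -> str:
    """Resolve an analyte label (code or full name, any case) to its code.

    Parameters
    ----------
    name
        Short code (``"BaP"``), full name (``"benzo(a)pyrene"``) or an
        aggregate key when *allow_aggregates* is true.
    allow_aggregates
        Accept ``TOTAL`` / ``PAH4`` labels in addition to single analytes.
    """
    key = str(name).strip().lower()
    code = _CODES_LOWER.get(key)
    if code is None:
        code = _FULL_NAMES.get(_squash(name))
    if code is None:
        raise UnknownAnalyteError(f"unknown PAH analyte: {name!r}")
    if code in AGGREGATES and not allow_aggregates:
        raise UnknownAnalyteError(
            f"aggregate key {code!r} not allowed where a single analyte is expected"
        )
    return code


def canonical_index(code: str) -> int:
    """Position of *code* in the canonical analyte order (for tie-breaking)."""
    return CANONICAL.index(code)
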