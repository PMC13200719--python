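"""Theoretical monoisotopic m/z calculation and small-molecule annotation.

Negative-mode DESI features are matched against deprotonated ([M-H]-)
monoisotopic masses of a small built-in table of root metabolites (TCA cycle
acids, erythrose, succinic anhydride); user tables load from CSV.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dimple.errors import ParameterError
from dimple.compare import PeakList

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ReferenceCompound",
    "builtin_references",
    "load_references",
    "parse_formula",
    "theoretical_mz",
    "match_features",
]

# IUPAC/CODATA monoisotopic atomic masses (u); electron mass is folded into
# the proton-subtraction convention (sub-ppm effect at these masses).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}
PROTON_MASS = 1.00727646

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

ADDUCTS = ("[M-H]-", "M")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula like ``C4H6O4`` into element counts."""
    if not formula or not formula.strip():
        raise ParameterError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula.strip()):
        if match.start() != pos:
            raise ParameterError(f"unparseable formula {formula!r}")
        pos = match.end()
        elem, num = match.group(1), match.group(2)
        if elem not in MONOISOTOPIC_MASS:
            raise ParameterError(
                f"unknown element {elem!r} in formula {formula!r}; "
                f"supported: {sorted(MONOISOTOPIC_MASS)}"
            )
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(formula.strip()) or not counts:
        raise ParameterError(f"unparseable formula {formula!r}")
    return counts


def theoretical_mz(formula: str | dict[str, int], adduct: str = "[M-H]-") -> float:
    """Theoretical m/z of a formula for the given adduct.

    ``[M-H]-`` subtracts one proton (1.00727646 u) from the neutral
    monoisotopic mass; ``M`` returns the neutral mass itself.
    """
    if adduct not in ADDUCTS:
        raise ParameterError(f"unsupported adduct {adduct!r}; choose from {ADDUCTS}")
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    if not counts or any(n <= 0 for n in counts.values()):
        raise ParameterError("formula must have positive element counts")
    unknown = set(counts) - set(MONOISOTOPIC_MASS)
    if unknown:
        raise ParameterError(f"unknown element(s) {sorted(unknown)}")
    mass = sum(MONOISOTOPIC_MASS[e] * n for e, n in counts.items())
    if adduct == "[M-H]-":
        mass -= PROTON_MASS
    return mass


@dataclass(frozen=True)
class ReferenceCompound:
    """A named compound with its formula and computed adduct m/z."""

    name: str
    formula: str
    adduct: str = "[M-H]-"
    theoretical: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "theoretical", theoretical_mz(self.formula, self.adduct))


def builtin_references() -> list[ReferenceCompound]:
    """The built-in table: TCA-cycle acids plus erythrose and succinic anhydride."""
    table = [
        ("succinate", "C4H6O4"),
        ("fumarate", "C4H4O4"),
        ("malate", "C4H6O5"),
        ("D-erythrose", "C4H8O4"),
        ("succinic anhydride", "C4H4O3"),
        ("citrate", "C6H8O7"),
        ("cis-aconitate", "C6H6O6"),
        ("alpha-ketoglutarate", "C5H6O5"),
        ("oxaloacetate", "C4H4O5"),
        ("pyruvate", "C3H4O3"),
    ]
    return [ReferenceCompound(name, formula) for name, formula in table]


def load_references(path: str | os.PathLike) -> list[ReferenceCompound]:
    """Load a reference table from CSV with columns (name, formula[, adduct])."""
    df = pd.read_csv(os.fspath(path))
    for col in ("name", "formula"):
        if col not in df.columns:
            raise ParameterError(f"reference CSV must have a '{col}' column")
    refs = []
    for _, row in df.iterrows():
        adduct = row.get("adduct", "[M-H]-")
        if not isinstance(adduct, str):
            adduct = "[M-H]-"
        refs.append(ReferenceCompound(str(row["name"]), str(row["formula"]), adduct))
    return refs


def match_features(
    peaks: PeakList | np.ndarray,
    refs: list[ReferenceCompound] | None = None,
    ppm_tol: float = 5.0,
) -> pd.DataFrame:
    """Annotate observed features against a reference table.

    Each feature is annotated with every reference compound whose theoretical
    m/z lies within ``ppm_tol``, sorted by |delta ppm|; features without a
    match get one row with name ``unknown``.
    """
    if ppm_tol <= 0:
        raise ParameterError("ppm_tol must be positive")
    refs = refs if refs is not None else builtin_references()
    mzs = peaks.mz if isinstance(peaks, PeakList) else np.asarray(peaks, dtype=np.float64)
    rows = []
    for mz in mzs:
        hits = []
        for ref in refs:
            delta_ppm = (mz - ref.theoretical) / ref.theoretical * 1e6
            if abs(delta_ppm) <= ppm_tol:
                hits.append((abs(delta_ppm), ref, delta_ppm))
        hits.sort(key=lambda h: h[0])
        if not hits:
            rows.append(
                {"feature_mz": mz, "name": "unknown", "formula": "",
                 "adduct": "", "theoretical_mz": np.nan, "delta_ppm": np.nan}
            )
        for _, ref, delta in hits:
            rows.append(
                {"feature_mz": mz, "name": ref.name, "formula": ref.formula,
                 "adduct": ref.adduct, "theoretical_mz": ref.theoretical,
                 "delta_ppm": delta}
            )
    return pd.DataFrame(
        rows,
        columns=["feature_mz", "name", "formula", "adduct", "theoretical_mz", "delta_ppm"],
    )
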