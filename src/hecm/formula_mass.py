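"""Molecular-formula parsing, monoisotopic masses and negative-mode adduct m/z.

Theoretical m/z values for ESI(-) adducts are computed as the monoisotopic
mass of the neutral molecule plus a signed adduct delta that accounts for the
gained/lost species *and* the electron carried by the -1 charge.  Mass error
between a theoretical and an experimental m/z is expressed in parts per
million (ppm) relative to the theoretical value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ElementCounts",
    "AdductSpec",
    "PeakAnnotation",
    "PeakMatch",
    "FormulaError",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "annotate_peaks",
    "load_reference_library",
]

# Monoisotopic masses of the most abundant isotopes, Da (CODATA/IUPAC 2021
# atomic mass evaluation, truncated to 8 decimals).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376200,
    "S": 31.97207117,
    "Cl": 34.96885268,
    "Na": 22.98976928,
    "K": 38.96370649,
}

# CODATA electron mass in Da.
ELECTRON_MASS = 0.00054858


class FormulaError(ValueError):
    """Raised for formula strings outside the element-count grammar."""


@dataclass(frozen=True)
class ElementCounts:
    """Element -> count map for a neutral molecular formula."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative integer")

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def hill_string(self) -> str:
        """Canonical Hill-order formula string (C, H, then alphabetical)."""
        items = {el: n for el, n in self.counts.items() if n > 0}
        ordered: list[str] = []
        for el in ("C", "H"):
            if el in items:
                ordered.append(el + (str(items[el]) if items[el] != 1 else ""))
                del items[el]
        for el in sorted(items):
            ordered.append(el + (str(items[el]) if items[el] != 1 else ""))
        return "".join(ordered)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementCounts:
    """Parse a plain molecular formula such as ``"C15H10O7"``.

    The grammar is element symbol followed by an optional integer count;
    repeated mentions of an element are summed.  Parentheses, isotope labels
    and charges are not part of the grammar and raise :class:`FormulaError`.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(
                f"unparseable token {text[pos:m.start()]!r} in formula {text!r}"
            )
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"unparseable token {text[pos:]!r} in formula {text!r}")
    return ElementCounts(counts)


def monoisotopic_mass(f: ElementCounts) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, Da."""
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in f.counts.items())


@dataclass(frozen=True)
class AdductSpec:
    """A negative-mode adduct: name, signed mass delta (Da) and charge.

    ``mass_delta`` includes the mass of the electron gained by the -1 ion.
    """

    name: str
    mass_delta: float
    charge: int = -1


_FORMATE_MASS = (
    MONOISOTOPIC_MASS["C"] + MONOISOTOPIC_MASS["H"] + 2 * MONOISOTOPIC_MASS["O"]
)

ADDUCTS: dict[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", -MONOISOTOPIC_MASS["H"] + ELECTRON_MASS),
    "[M+Cl]-": AdductSpec("[M+Cl]-", MONOISOTOPIC_MASS["Cl"] + ELECTRON_MASS),
    # "[M+COOH]-" is the formate adduct [M+HCOO]-.
    "[M+COOH]-": AdductSpec("[M+COOH]-", _FORMATE_MASS + ELECTRON_MASS),
}
ADDUCTS["[M+HCOO]-"] = AdductSpec("[M+HCOO]-", ADDUCTS["[M+COOH]-"].mass_delta)


def _resolve_adduct(a: "AdductSpec | str") -> AdductSpec:
    if isinstance(a, AdductSpec):
        return a
    try:
        return ADDUCTS[a]
    except KeyError:
        raise ValueError(
            f"unsupported adduct {a!r}; supported: {sorted(ADDUCTS)}"
        ) from None


def adduct_mz(f: ElementCounts, a: "AdductSpec | str") -> float:
    """Theoretical m/z of a singly charged negative adduct of formula ``f``."""
    adduct_spec = _resolve_adduct(a)
    return monoisotopic_mass(f) + adduct_spec.mass_delta


def ppm_error(calculated: float, experimental: float) -> float:
    """Mass error (calculated - experimental) / calculated, in ppm."""
    if calculated <= 0:
        raise ValueError("calculated m/z must be positive")
    return (calculated - experimental) / calculated * 1e6


@dataclass(frozen=True)
class PeakAnnotation:
    """A library entry: identity, formula, adduct and reference m/z values."""

    peak_id: str
    rt: float
    experimental_mz: float
    formula: ElementCounts
    adduct: AdductSpec
    calculated_mz: float
    error_ppm: float
    name: str = ""


@dataclass
class PeakMatch:
    """An observed peak with its library matches ordered by |ppm error|."""

    peak_id: str
    rt: float
    mz: float
    matches: list[tuple[PeakAnnotation, float]] = field(default_factory=list)

    @property
    def matched(self) -> bool:
        return bool(self.matches)


def annotate_peaks(
    observed: Iterable[tuple[str, float, float]],
    library: Sequence[PeakAnnotation],
    tol_ppm: float = 5.0,
) -> list[PeakMatch]:
    """Match observed (peak_id, rt, mz) triples against a reference library.

    A library entry matches when the ppm difference between its theoretical
    m/z and the observed m/z is within ``tol_ppm``.  Unmatched peaks are
    returned with an empty match list rather than dropped.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    library = list(library)
    if not library:
        raise ValueError("reference library is empty")
    out: list[PeakMatch] = []
    for peak_id, rt, mz in observed:
        hits: list[tuple[PeakAnnotation, float]] = []
        for entry in library:
            err = ppm_error(entry.calculated_mz, mz)
            if abs(err) <= tol_ppm:
                hits.append((entry, err))
        hits.sort(key=lambda h: abs(h[1]))
        out.append(PeakMatch(peak_id=peak_id, rt=rt, mz=mz, matches=hits))
    return out


def load_reference_library() -> list[PeakAnnotation]:
    """Load the packaged 40-compound reference library.

    Theoretical m/z values are recomputed from the formulas at load time;
    the printed values from the source table are kept alongside (the
    ``error_ppm`` field stores the transcribed error verbatim).
    """
    import pandas as pd

    with resources.files("hecm.data").joinpath("reference_library.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"peak_no": str})
    entries = []
    for row in df.itertuples(index=False):
        f = parse_formula(row.formula)
        adduct = _resolve_adduct(row.adduct)
        entries.append(
            PeakAnnotation(
                peak_id=str(row.peak_no),
                rt=float(row.rt_min),
                experimental_mz=float(row.experimental_mz),
                formula=f,
                adduct=adduct,
                calculated_mz=adduct_mz(f, adduct),
                error_ppm=float(row.error_ppm_printed),
                name="" if pd.isna(row.name) else str(row.name),
            )
        )
    return entries


def load_reference_table():
    """The packaged reference table as a pandas DataFrame (verbatim columns)."""
    from .datasets import reference_library_table

    return reference_library_table()
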