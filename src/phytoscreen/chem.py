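"""Exact-mass arithmetic for small-molecule mass spectrometry.

Molecular formulas, monoisotopic masses, singly charged ion species
([M−H]⁻, [M+H]⁺, [M+COOH]⁻ formate adducts, intrinsic cations M⁺) and
ppm error — the numeric substrate of the annotation pipeline.

Masses are monoisotopic (most abundant isotope) in unified atomic mass
units.  Intrinsic cations (quaternary alkaloids such as berberine) carry
their charge in the neutral formula, so their m/z is the formula mass
minus one electron; protonation/deprotonation adds/removes a proton
(H atom minus electron), which collapses to ±1.007276 u for |z| = 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterator, Mapping

__all__ = [
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ElementMassTable",
    "MolecularFormula",
    "IonSpecies",
    "NeutralLoss",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "loss_mass",
    "builtin_losses",
    "get_loss",
]

#: mass of the proton, u (CODATA)
PROTON_MASS = 1.007276466879
#: mass of the electron, u (CODATA)
ELECTRON_MASS = 0.000548579909

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula text or unknown element symbol."""


class ElementMassTable(Mapping[str, float]):
    """Immutable element → monoisotopic mass lookup.

    Loaded from the packaged TSV; guaranteed to contain at least
    C, H, N, O, S, P with strictly positive masses.
    """

    def __init__(self, masses: Dict[str, float]):
        for sym, m in masses.items():
            if m <= 0:
                raise ValueError(f"non-positive mass for {sym}")
        for required in ("C", "H", "N", "O", "S", "P"):
            if required not in masses:
                raise ValueError(f"mass table missing required element {required}")
        self._masses = dict(masses)

    def __getitem__(self, symbol: str) -> float:
        return self._masses[symbol]

    def __iter__(self) -> Iterator[str]:
        return iter(self._masses)

    def __len__(self) -> int:
        return len(self._masses)

    @classmethod
    def load_default(cls) -> "ElementMassTable":
        text = (
            resources.files("phytoscreen.data")
            .joinpath("element_masses.tsv")
            .read_text()
        )
        masses: Dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sym, mass = line.split("\t")
            masses[sym] = float(mass)
        return cls(masses)


_DEFAULT_TABLE: ElementMassTable | None = None


def default_mass_table() -> ElementMassTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ElementMassTable.load_default()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class MolecularFormula:
    """Element → count map with exact-mass semantics.

    Counts are non-negative integers; at least one atom.  The canonical
    text form follows Hill order (C first, then H, then alphabetical;
    without carbon, all alphabetical).
    """

    counts: Mapping[str, int]

    def __post_init__(self):
        table = default_mass_table()
        clean = {}
        for sym, n in self.counts.items():
            if sym not in table:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"bad count for {sym}: {n!r}")
            if n > 0:
                clean[sym] = n
        if not clean:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", dict(clean))

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return MolecularFormula(merged)

    def subtract(self, other: "MolecularFormula") -> "MolecularFormula | None":
        """Elementwise difference, or None when not subtractable."""
        out = dict(self.counts)
        for sym, n in other.counts.items():
            if out.get(sym, 0) < n:
                return None
            out[sym] -= n
        if not any(v > 0 for v in out.values()):
            return None
        return MolecularFormula(out)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        result = self.subtract(other)
        if result is None:
            raise FormulaError(f"{other} not subtractable from {self}")
        return result

    # -- text form ----------------------------------------------------
    def hill(self) -> str:
        syms = sorted(self.counts)
        ordered = []
        if "C" in self.counts:
            ordered.append("C")
            if "H" in self.counts:
                ordered.append("H")
            ordered += [s for s in syms if s not in ("C", "H")]
        else:
            ordered = syms
        return "".join(
            f"{s}{self.counts[s]}" if self.counts[s] > 1 else s for s in ordered
        )

    def __str__(self) -> str:
        return self.hill()

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __eq__(self, other) -> bool:
        return isinstance(other, MolecularFormula) and self.counts == other.counts


def parse_formula(text: str) -> MolecularFormula:
    """Parse plain formula text (e.g. ``"C15H10O5"``) into counts.

    Subscript markers (``_``) are stripped before parsing.  Unknown
    element symbols or leftover characters raise :class:`FormulaError`.
    """
    if not isinstance(text, str) or not text:
        raise FormulaError("empty formula text")
    stripped = text.replace("_", "").strip()
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(stripped):
        if match.start() != pos:
            raise FormulaError(f"malformed formula text: {text!r}")
        if not match.group(0):
            break
        sym = match.group(1)
        n = int(match.group(2)) if match.group(2) else 1
        counts[sym] = counts.get(sym, 0) + n
        pos = match.end()
    if pos != len(stripped) or not counts:
        raise FormulaError(f"malformed formula text: {text!r}")
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Sum of count × monoisotopic element mass, in u."""
    table = default_mass_table()
    return sum(n * table[sym] for sym, n in formula.counts.items())


@dataclass(frozen=True)
class IonSpecies:
    """A singly charged ion species observed in one polarity.

    ``mode`` ∈ {``"[M-H]-"``, ``"[M+H]+"``, ``"[M+COOH]-"``, ``"M+"``}.
    For ``"M+"`` (intrinsic cation, e.g. quaternary alkaloids) the
    supplied formula is the cation's own formula.
    """

    mode: str

    _MODES = {
        "[M-H]-": "negative",
        "[M+H]+": "positive",
        "[M+COOH]-": "negative",
        "M+": "positive",
    }

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ValueError(f"unsupported ion species: {self.mode!r}")

    @property
    def polarity(self) -> str:
        return self._MODES[self.mode]

    @property
    def charge(self) -> int:
        return 1

    def __str__(self) -> str:
        return self.mode


DEPROTONATED = IonSpecies("[M-H]-")
PROTONATED = IonSpecies("[M+H]+")
FORMATE_ADDUCT = IonSpecies("[M+COOH]-")
INTRINSIC_CATION = IonSpecies("M+")

_FORMIC_ACID_MASS = None


def _formic_acid() -> float:
    global _FORMIC_ACID_MASS
    if _FORMIC_ACID_MASS is None:
        _FORMIC_ACID_MASS = monoisotopic_mass(parse_formula("CH2O2"))
    return _FORMIC_ACID_MASS


def ion_mz(formula: MolecularFormula, species: IonSpecies) -> float:
    """Theoretical m/z of ``formula`` as the given singly charged species.

    [M−H]⁻ = M − proton; [M+H]⁺ = M + proton;
    [M+COOH]⁻ = M + mass(HCOOH) − proton; M⁺ = M − electron.
    """
    m = monoisotopic_mass(formula)
    if species.mode == "[M-H]-":
        return m - PROTON_MASS
    if species.mode == "[M+H]+":
        return m + PROTON_MASS
    if species.mode == "[M+COOH]-":
        return m + _formic_acid() - PROTON_MASS
    if species.mode == "M+":
        return m - ELECTRON_MASS
    raise ValueError(f"unsupported ion species: {species.mode!r}")


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation, parts per million."""
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class NeutralLoss:
    """A named neutral fragment ejected during CID.

    ``radical`` marks odd-electron losses (H•, CH3•, OCH3•, COOH•) that
    change the electron parity of the product ion.
    """

    name: str
    formula: MolecularFormula
    radical: bool = False

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def nominal(self) -> int:
        return round(self.mass)


def _loss(name: str, formula: str, radical: bool = False) -> NeutralLoss:
    return NeutralLoss(name, parse_formula(formula), radical)


# Registered neutral-loss vocabulary.  Nominal masses match the integer
# loss labels used in diagnostic-ion shorthand (Glc→162, Rha→146, H2O→18).
_BUILTIN_LOSSES = [
    _loss("H", "H", radical=True),
    _loss("H2O", "H2O"),
    _loss("CO", "CO"),
    _loss("CO2", "CO2"),
    _loss("CH3", "CH3", radical=True),
    _loss("2CH3", "C2H6"),
    _loss("CH4", "CH4"),
    _loss("CH2O", "CH2O"),
    _loss("OCH3", "CH3O", radical=True),
    _loss("CH3OH", "CH4O"),
    _loss("COOH", "CHO2", radical=True),
    _loss("HCOOH", "CH2O2"),
    _loss("NH3", "NH3"),
    _loss("C2H2", "C2H2"),
    _loss("C2H2O", "C2H2O"),
    _loss("C3H6", "C3H6"),
    _loss("C4H8", "C4H8"),
    _loss("C6H12", "C6H12"),
    _loss("O", "O"),
    _loss("(CH3)2NH", "C2H7N"),
    _loss("CH3NH2", "CH5N"),
    # glycosyl residues (dehydrated sugar units)
    _loss("Glc", "C6H10O5"),
    _loss("Rha", "C6H10O4"),
    _loss("Ara", "C5H8O4"),
    _loss("Glua", "C6H8O6"),
    _loss("GlcRha", "C12H20O9"),
    _loss("2Glc", "C12H20O10"),
    # acyl / aryl residues
    _loss("caffeoyl", "C9H6O3"),
    _loss("ribosyl", "C5H8O4"),
    # class-specific ring-cleavage (RDA / alpha-cleavage) residues
    _loss("C8H6O", "C8H6O"),
    _loss("C7H4O4", "C7H4O4"),
    _loss("C9H6O3", "C9H6O3"),
    _loss("C8H8O", "C8H8O"),
    _loss("C6H6O", "C6H6O"),
    _loss("C9H8O3", "C9H8O3"),
    _loss("C3H2O3", "C3H2O3"),
    _loss("C8H6O4", "C8H6O4"),
    _loss("C9H8O4", "C9H8O4"),
    _loss("C9H10O2", "C9H10O2"),
    _loss("C11H13NO2", "C11H13NO2"),
    _loss("C12H17NO2", "C12H17NO2"),
    _loss("C6H4O4", "C6H4O4"),
    _loss("C7H4O5", "C7H4O5"),
    _loss("C5H10", "C5H10"),
    _loss("C7H10O5", "C7H10O5"),
    _loss("C12H14O2", "C12H14O2"),
    _loss("C8H18O3", "C8H18O3"),
    _loss("C7H6O", "C7H6O"),
]


def builtin_losses() -> Dict[str, NeutralLoss]:
    """Name → NeutralLoss vocabulary used by the shipped rulebase."""
    return {l.name: l for l in _BUILTIN_LOSSES}


def get_loss(name: str) -> NeutralLoss:
    try:
        return builtin_losses()[name]
    except KeyError:
        raise KeyError(f"unknown neutral loss: {name!r}") from None


def loss_mass(loss: "NeutralLoss | str") -> float:
    """Monoisotopic mass of a registered neutral loss (by object or name)."""
    if isinstance(loss, str):
        loss = get_loss(loss)
    return loss.mass
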