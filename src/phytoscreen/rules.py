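"""Compound-class diagnostic fragmentation rules.

Each compound class (anthraquinone, flavone, protoberberine alkaloid, ...)
has a characteristic set of neutral losses and ring-cleavage (retro-
Diels-Alder) product ions under collision-induced dissociation.  This
module encodes those behaviors as declarative, scoreable rules: a rule is
a list of diagnostic entries (ordered neutral-loss chains from the
quasi-molecular ion, plus optional absolute product-ion formulas), each
with a weight.

`score_class` turns the qualitative "characteristic ions" judgement into
a number in [0, 1]: the weight fraction of applicable diagnostic entries
matched by observed peaks.  An entry is *applicable* when its total loss
formula is elementwise subtractable from the precursor ion formula, so a
glycoside loss never penalizes an aglycone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

from .chem import (
    ELECTRON_MASS,
    IonSpecies,
    MolecularFormula,
    NeutralLoss,
    get_loss,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
)

__all__ = [
    "COMPOUND_CLASSES",
    "RuleEntry",
    "FragmentationRule",
    "RuleHit",
    "ExpectedFragment",
    "builtin_rulebase",
    "load_rulebase",
    "ion_formula",
    "expected_fragments",
    "score_class",
]

#: closed controlled vocabulary of compound classes
COMPOUND_CLASSES = (
    "anthraquinone",
    "flavone",
    "isoflavone",
    "flavanone",
    "flavonol",
    "flavanol",
    "tetrahydroprotoberberine",
    "protoberberine",
    "aporphine",
    "benzylisoquinoline",
    "iridoid",
    "triterpenoid",
    "triterpenoid_saponin",
    "lignan",
    "coumarin",
    "quinic_acid_derivative",
    "phenolic_acid",
    "aliphatic_acid",
    "phenylethanoid_glycoside",
    "amino_acid",
    "steroid",
    "phthalide",
    "nucleoside",
    "stilbene",
    "other",
)


@dataclass(frozen=True)
class RuleEntry:
    """One diagnostic entry: an ordered chain of registered neutral losses."""

    losses: Tuple[str, ...]
    weight: float = 1.0

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("entry weight must be >= 0")
        if not self.losses:
            raise ValueError("entry needs at least one loss")

    @property
    def loss_objects(self) -> Tuple[NeutralLoss, ...]:
        return tuple(get_loss(name) for name in self.losses)

    def total_formula(self) -> MolecularFormula:
        objs = self.loss_objects
        total = objs[0].formula
        for l in objs[1:]:
            total = total + l.formula
        return total

    def total_mass(self) -> float:
        return monoisotopic_mass(self.total_formula())


@dataclass(frozen=True)
class FragmentationRule:
    """Per-class vocabulary of diagnostic losses and product-ion formulas."""

    compound_class: str
    entries: Tuple[RuleEntry, ...]
    product_formulas: Tuple[MolecularFormula, ...] = ()
    polarity: str = "negative"
    minimum_hits: int = 1

    def __post_init__(self):
        if not self.entries:
            raise ValueError("rule needs at least one diagnostic loss entry")
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"bad polarity: {self.polarity!r}")

    def loss_alphabet(self) -> Tuple[str, ...]:
        seen: List[str] = []
        for e in self.entries:
            for name in e.losses:
                if name not in seen:
                    seen.append(name)
        return tuple(seen)


@dataclass(frozen=True)
class RuleHit:
    """A diagnostic entry matched by an observed peak."""

    losses: Tuple[str, ...]
    theoretical_mz: float
    observed_mz: float
    ppm: float
    weight: float
    is_product_formula: bool = False


@dataclass(frozen=True)
class ExpectedFragment:
    losses: Tuple[str, ...]
    formula: MolecularFormula  # fragment *ion* formula
    mz: float
    kind: str = "loss"  # "loss" | "precursor" | "product"


# ---------------------------------------------------------------------------
# rulebase loading


def _parse_rulebase(payload: dict) -> Dict[str, FragmentationRule]:
    rules: Dict[str, FragmentationRule] = {}
    for cls, spec in payload["classes"].items():
        if cls not in COMPOUND_CLASSES:
            raise ValueError(f"unknown compound class in rulebase: {cls!r}")
        entries = tuple(
            RuleEntry(tuple(e["losses"]), float(e.get("weight", 1.0)))
            for e in spec["entries"]
        )
        products = tuple(parse_formula(f) for f in spec.get("product_formulas", ()))
        rules[cls] = FragmentationRule(
            compound_class=cls,
            entries=entries,
            product_formulas=products,
            polarity=spec.get("polarity", "negative"),
            minimum_hits=int(spec.get("minimum_hits", 1)),
        )
    missing = set(COMPOUND_CLASSES) - set(rules)
    if missing:
        raise ValueError(f"rulebase missing classes: {sorted(missing)}")
    return rules


def load_rulebase(path) -> Dict[str, FragmentationRule]:
    """Load a user-editable JSON rulebase (same schema as the shipped one)."""
    with open(path) as fh:
        return _parse_rulebase(json.load(fh))


_BUILTIN: Optional[Dict[str, FragmentationRule]] = None


def builtin_rulebase() -> Dict[str, FragmentationRule]:
    """The shipped class → rule map (every class in the vocabulary has one)."""
    global _BUILTIN
    if _BUILTIN is None:
        text = (
            resources.files("phytoscreen.data").joinpath("rulebase.json").read_text()
        )
        _BUILTIN = _parse_rulebase(json.loads(text))
    return dict(_BUILTIN)


# ---------------------------------------------------------------------------
# fragment enumeration


def ion_formula(neutral: MolecularFormula, species: IonSpecies) -> MolecularFormula:
    """Elemental composition of the quasi-molecular ion itself."""
    if species.mode == "[M-H]-":
        return neutral - parse_formula("H")
    if species.mode == "[M+H]+":
        return neutral + parse_formula("H")
    if species.mode == "[M+COOH]-":
        return neutral + parse_formula("CHO2")
    return neutral  # intrinsic cation: the supplied formula is the ion


def expected_fragments(
    precursor_formula: MolecularFormula,
    species: IonSpecies,
    rule: FragmentationRule,
    max_depth: int = 3,
) -> List[ExpectedFragment]:
    """Enumerate diagnostic fragment ions for a precursor under a rule.

    Explores all ordered chains over the rule's loss alphabet up to
    ``max_depth``, pruning chains whose loss is not elementwise
    subtractable from the precursor ion formula and allowing at most one
    radical (odd-electron) step per chain.  Chains yielding an already-
    seen fragment composition are dropped (first, shortest chain wins).
    Product-ion formulas contained in the precursor ion are appended.
    """
    prec_ion = ion_formula(precursor_formula, species)
    prec_mz = ion_mz(precursor_formula, species)
    out: List[ExpectedFragment] = [
        ExpectedFragment((), prec_ion, prec_mz, kind="precursor")
    ]
    seen = {prec_ion}
    alphabet = [get_loss(name) for name in rule.loss_alphabet()]

    frontier: List[Tuple[Tuple[str, ...], MolecularFormula, float, int]] = [
        ((), prec_ion, prec_mz, 0)
    ]
    for _depth in range(max_depth):
        nxt = []
        for path, form, mz, nrad in frontier:
            for loss in alphabet:
                rad = nrad + (1 if loss.radical else 0)
                if rad > 1:
                    continue
                sub = form.subtract(loss.formula)
                if sub is None:
                    continue
                new_path = path + (loss.name,)
                new_mz = mz - loss.mass
                nxt.append((new_path, sub, new_mz, rad))
                if sub not in seen:
                    seen.add(sub)
                    out.append(ExpectedFragment(new_path, sub, new_mz))
        frontier = nxt

    sign = ELECTRON_MASS if species.polarity == "negative" else -ELECTRON_MASS
    for prod in rule.product_formulas:
        if prec_ion.subtract(prod) is not None or prec_ion == prod:
            mz = monoisotopic_mass(prod) + sign
            out.append(ExpectedFragment((), prod, mz, kind="product"))
    return out


# ---------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class Tolerances:
    """Matching tolerances in parts per million."""

    precursor_ppm: float = 5.0
    fragment_ppm: float = 10.0


def _entry_mz(
    entry: RuleEntry, prec_ion: MolecularFormula, prec_mz: float
) -> Optional[float]:
    """Theoretical fragment m/z of a diagnostic entry, or None if inapplicable."""
    if prec_ion.subtract(entry.total_formula()) is None:
        return None
    return prec_mz - entry.total_mass()


def score_class(
    spectrum,
    precursor_formula: MolecularFormula,
    species: IonSpecies,
    rule: FragmentationRule,
    tolerances: Tolerances = Tolerances(),
) -> Tuple[float, List[RuleHit]]:
    """Weight fraction of applicable diagnostic entries matched by peaks.

    ``spectrum`` needs ``peaks`` (sequence of (m/z, intensity)).  Returns
    (score in [0,1], matched RuleHits).  Empty spectra score 0 with a
    warning; a precursor with no applicable entry scores 0.
    """
    peaks = list(spectrum.peaks)
    if not peaks:
        warnings.warn("empty spectrum: class score is 0", stacklevel=2)
        return 0.0, []
    mzs = [p[0] for p in peaks]

    prec_ion = ion_formula(precursor_formula, species)
    prec_mz = ion_mz(precursor_formula, species)

    total_weight = 0.0
    matched_weight = 0.0
    hits: List[RuleHit] = []
    tol = tolerances.fragment_ppm

    candidates: List[Tuple[Tuple[str, ...], float, float, bool]] = []
    for entry in rule.entries:
        mz = _entry_mz(entry, prec_ion, prec_mz)
        if mz is not None:
            candidates.append((entry.losses, mz, entry.weight, False))
    sign = ELECTRON_MASS if species.polarity == "negative" else -ELECTRON_MASS
    for prod in rule.product_formulas:
        if prec_ion.subtract(prod) is not None or prec_ion == prod:
            candidates.append(((), monoisotopic_mass(prod) + sign, 1.0, True))

    for losses, theo, weight, is_prod in candidates:
        total_weight += weight
        best = None
        for obs in mzs:
            err = ppm_error(obs, theo)
            if abs(err) <= tol and (best is None or abs(err) < abs(best[1])):
                best = (obs, err)
        if best is not None:
            matched_weight += weight
            hits.append(
                RuleHit(
                    losses=losses,
                    theoretical_mz=theo,
                    observed_mz=best[0],
                    ppm=best[1],
                    weight=weight,
                    is_product_formula=is_prod,
                )
            )

    if total_weight == 0:
        return 0.0, []
    return matched_weight / total_weight, hits
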