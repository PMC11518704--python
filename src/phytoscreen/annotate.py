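"""Library matching and confidence tiering for MS/MS spectra.

A centroided product-ion spectrum is matched against a compound library
by precursor exact mass (polarity-compatible ion species only), each
candidate is scored against the diagnostic fragmentation rule of its
compound class, and the result is tiered the way natural-product
dereplication studies report it:

``identified_with_standard``
    precursor match, retention time agrees with a reference standard,
    and the class score clears a threshold;
``tentatively_characterized``
    precursor match plus at least one diagnostic rule hit (or a
    peak-free precursor-only match, flagged);
``unmatched``
    precursor match but no diagnostic fragment support.

Isomers (identical formula) are never merged: both are reported and the
retention-time tier separates them, mirroring how reference standards
resolve cianidanol/epicatechin or angelicin/psoralen.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .chem import (
    DEPROTONATED,
    FORMATE_ADDUCT,
    INTRINSIC_CATION,
    PROTONATED,
    IonSpecies,
    MolecularFormula,
    NeutralLoss,
    ion_mz,
    parse_formula,
    ppm_error,
)
from .rules import (
    COMPOUND_CLASSES,
    FragmentationRule,
    RuleHit,
    Tolerances,
    builtin_rulebase,
    ion_formula,
    score_class,
)

__all__ = [
    "Spectrum",
    "CompoundRecord",
    "AnnotationResult",
    "PeakAnnotation",
    "load_library",
    "builtin_library",
    "read_spectra_mgf",
    "read_spectra_csv",
    "candidate_search",
    "annotate",
    "annotate_all",
    "explain_peaks",
    "write_annotations_tsv",
    "write_annotations_json",
]

TIER_ORDER = {"identified_with_standard": 0, "tentatively_characterized": 1, "unmatched": 2}


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS/MS spectrum in one polarity.

    Peaks are (m/z, relative intensity in [0, 1]) sorted ascending by
    m/z; the precursor m/z must not sit below the largest fragment.
    """

    identifier: str
    polarity: str
    precursor_mz: float
    peaks: Tuple[Tuple[float, float], ...]
    rt_min: Optional[float] = None

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity: {self.polarity!r}")
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        for mz, inten in pk:
            if not (0.0 <= inten <= 1.0):
                raise ValueError(f"intensity out of [0,1]: {inten}")
            if mz <= 0:
                raise ValueError("peak m/z must be positive")
        if pk and pk[-1][0] > self.precursor_mz * (1 + 20e-6):
            raise ValueError("fragment m/z above precursor")
        object.__setattr__(self, "peaks", pk)


@dataclass(frozen=True)
class CompoundRecord:
    """A library compound: name, formula, class, optional reference RT."""

    name: str
    formula: MolecularFormula
    compound_class: str
    intrinsic_cation: bool = False
    rt_min: Optional[float] = None
    source_botanical: Optional[str] = None

    def __post_init__(self):
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(f"unknown compound class: {self.compound_class!r}")

    def species_for(self, polarity: str) -> Tuple[IonSpecies, ...]:
        """Polarity-compatible ion species for this compound."""
        if self.intrinsic_cation:
            return (INTRINSIC_CATION,) if polarity == "positive" else ()
        if polarity == "positive":
            return (PROTONATED,)
        return (DEPROTONATED, FORMATE_ADDUCT)


@dataclass(frozen=True)
class AnnotationResult:
    spectrum_id: str
    compound: CompoundRecord
    species: IonSpecies
    precursor_ppm: float
    class_score: float
    hits: Tuple[RuleHit, ...]
    tier: str
    zero_rule_hits_flagged: bool = False

    def sort_key(self) -> tuple:
        return (
            TIER_ORDER[self.tier],
            -self.class_score,
            abs(self.precursor_ppm),
            self.compound.name,
        )


# ---------------------------------------------------------------------------
# library / spectra I/O


def load_library(path) -> List[CompoundRecord]:
    """Read a compound library CSV (name, formula, compound_class,
    intrinsic_cation, rt_min, source_botanical) or JSON list."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    records = []
    for row in rows:
        rt = row.get("rt_min")
        rt = float(rt) if rt not in (None, "", "NA") else None
        records.append(
            CompoundRecord(
                name=row["name"],
                formula=parse_formula(row["formula"]),
                compound_class=row["compound_class"],
                intrinsic_cation=str(row.get("intrinsic_cation", "0")) in ("1", "True", "true"),
                rt_min=rt,
                source_botanical=row.get("source_botanical") or None,
            )
        )
    return records


def builtin_library() -> List[CompoundRecord]:
    """The packaged fixture library of worked-example standards."""
    with resources.as_file(
        resources.files("phytoscreen.data").joinpath("compound_library.csv")
    ) as p:
        return load_library(p)


def read_spectra_mgf(path) -> List[Spectrum]:
    """Read spectra from an MGF file (TITLE, PEPMASS, CHARGE, RTINSECONDS)."""
    from pyteomics import mgf

    spectra = []
    with mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = params.get("charge")
            polarity = "negative"
            if charge is not None:
                polarity = "negative" if str(charge[0]).endswith("-") else "positive"
            rt = params.get("rtinseconds")
            rt_min = float(rt) / 60.0 if rt is not None else None
            inten = entry["intensity array"]
            top = float(inten.max()) if len(inten) else 1.0
            peaks = tuple(
                (float(m), float(i) / top)
                for m, i in zip(entry["m/z array"], inten)
            )
            spectra.append(
                Spectrum(
                    identifier=str(params.get("title", "")),
                    polarity=polarity,
                    precursor_mz=float(params["pepmass"][0]),
                    peaks=peaks,
                    rt_min=rt_min,
                )
            )
    return spectra


def read_spectra_csv(path) -> List[Spectrum]:
    """Read the documented CSV dialect: one peak per row with columns
    spectrum_id, polarity, precursor_mz, rt_min, fragment_mz, intensity."""
    groups: Dict[str, dict] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            g = groups.setdefault(
                row["spectrum_id"],
                {
                    "polarity": row["polarity"],
                    "precursor_mz": float(row["precursor_mz"]),
                    "rt_min": float(row["rt_min"]) if row.get("rt_min") else None,
                    "peaks": [],
                },
            )
            g["peaks"].append((float(row["fragment_mz"]), float(row["intensity"])))
    return [
        Spectrum(
            identifier=sid,
            polarity=g["polarity"],
            precursor_mz=g["precursor_mz"],
            peaks=tuple(g["peaks"]),
            rt_min=g["rt_min"],
        )
        for sid, g in groups.items()
    ]


# ---------------------------------------------------------------------------
# search and annotation


def candidate_search(
    spectrum: Spectrum,
    library: Sequence[CompoundRecord],
    precursor_tol_ppm: float = 5.0,
) -> List[Tuple[CompoundRecord, IonSpecies, float]]:
    """All (compound, species) pairs whose theoretical m/z matches the
    precursor within tolerance, sorted by |ppm error|."""
    if not library:
        raise ValueError("empty compound library")
    out = []
    for rec in library:
        for sp in rec.species_for(spectrum.polarity):
            err = ppm_error(spectrum.precursor_mz, ion_mz(rec.formula, sp))
            if abs(err) <= precursor_tol_ppm:
                out.append((rec, sp, err))
    out.sort(key=lambda t: (abs(t[2]), t[0].name))
    return out


def annotate(
    spectrum: Spectrum,
    library: Sequence[CompoundRecord],
    rulebase: Optional[Dict[str, FragmentationRule]] = None,
    tolerances: Tolerances = Tolerances(),
    rt_window: float = 0.2,
    standard_score_threshold: float = 0.1,
) -> List[AnnotationResult]:
    """Rank library candidates for one spectrum.

    Candidates are ordered by (tier, class score, |precursor ppm|, name);
    the ordering is deterministic and invariant to peak input order.
    """
    if rulebase is None:
        rulebase = builtin_rulebase()
    results = []
    for rec, sp, prec_err in candidate_search(
        spectrum, library, tolerances.precursor_ppm
    ):
        rule = rulebase[rec.compound_class]
        score, hits = (0.0, []) if not spectrum.peaks else score_class(
            spectrum, rec.formula, sp, rule, tolerances
        )
        flagged = False
        if not spectrum.peaks:
            tier = "tentatively_characterized"
            flagged = True
        elif not hits:
            tier = "unmatched"
        else:
            tier = "tentatively_characterized"
        if (
            tier == "tentatively_characterized"
            and rec.rt_min is not None
            and spectrum.rt_min is not None
            and abs(spectrum.rt_min - rec.rt_min) <= rt_window
            and score >= standard_score_threshold
        ):
            tier = "identified_with_standard"
        results.append(
            AnnotationResult(
                spectrum_id=spectrum.identifier,
                compound=rec,
                species=sp,
                precursor_ppm=prec_err,
                class_score=score,
                hits=tuple(hits),
                tier=tier,
                zero_rule_hits_flagged=flagged,
            )
        )
    results.sort(key=lambda r: r.sort_key())
    return results


def annotate_all(spectra, library, **kwargs) -> Dict[str, List[AnnotationResult]]:
    return {s.identifier: annotate(s, library, **kwargs) for s in spectra}


# ---------------------------------------------------------------------------
# per-peak explanation


@dataclass(frozen=True)
class PeakAnnotation:
    mz: float
    intensity: float
    losses: Optional[Tuple[str, ...]]  # None = unassigned; () = precursor
    ppm: Optional[float]


def explain_peaks(
    spectrum: Spectrum,
    precursor_formula: MolecularFormula,
    species: IonSpecies,
    loss_vocabulary: Sequence[NeutralLoss],
    max_depth: int = 3,
    tol_ppm: float = 10.0,
) -> Tuple[List[PeakAnnotation], float]:
    """Assign each fragment peak the minimum-length neutral-loss path
    matching within tolerance (ties by |ppm|), or leave it unassigned.

    Returns the per-peak annotations and the fraction of total intensity
    explained.  Radical losses are allowed at most once per path.
    """
    prec_ion = ion_formula(precursor_formula, species)
    prec_mz = ion_mz(precursor_formula, species)

    # breadth-first expansion so shorter paths are found first
    levels: List[Dict[MolecularFormula, Tuple[Tuple[str, ...], float]]] = [
        {prec_ion: ((), prec_mz)}
    ]
    seen = {prec_ion}
    for _ in range(max_depth):
        nxt: Dict[MolecularFormula, Tuple[Tuple[str, ...], float]] = {}
        for form, (path, mz) in levels[-1].items():
            nrad = sum(1 for n in path if _is_radical(n, loss_vocabulary))
            for loss in loss_vocabulary:
                if loss.radical and nrad >= 1:
                    continue
                sub = form.subtract(loss.formula)
                if sub is None or sub in seen:
                    continue
                nxt[sub] = (path + (loss.name,), mz - loss.mass)
        for f in nxt:
            seen.add(f)
        if not nxt:
            break
        levels.append(nxt)

    annotations: List[PeakAnnotation] = []
    explained = 0.0
    total = sum(i for _, i in spectrum.peaks) or 1.0
    for mz, inten in spectrum.peaks:
        best: Optional[Tuple[Tuple[str, ...], float]] = None
        for level in levels:
            for path, theo in level.values():
                err = ppm_error(mz, theo)
                if abs(err) <= tol_ppm and (best is None or abs(err) < abs(best[1])):
                    best = (path, err)
            if best is not None:
                break  # minimum-length level found
        if best is None:
            annotations.append(PeakAnnotation(mz, inten, None, None))
        else:
            annotations.append(PeakAnnotation(mz, inten, best[0], best[1]))
            explained += inten
    return annotations, explained / total


def _is_radical(name: str, vocab: Sequence[NeutralLoss]) -> bool:
    for l in vocab:
        if l.name == name:
            return l.radical
    return False


# ---------------------------------------------------------------------------
# output writers


def write_annotations_tsv(results: Dict[str, List[AnnotationResult]], path) -> None:
    """One row per (spectrum, candidate)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            [
                "spectrum_id",
                "rank",
                "compound",
                "formula",
                "compound_class",
                "ion_species",
                "precursor_ppm",
                "class_score",
                "n_rule_hits",
                "tier",
            ]
        )
        for sid, anns in results.items():
            for rank, a in enumerate(anns, 1):
                w.writerow(
                    [
                        sid,
                        rank,
                        a.compound.name,
                        a.compound.formula.hill(),
                        a.compound.compound_class,
                        str(a.species),
                        f"{a.precursor_ppm:.2f}",
                        f"{a.class_score:.4f}",
                        len(a.hits),
                        a.tier,
                    ]
                )


def write_annotations_json(results: Dict[str, List[AnnotationResult]], path) -> None:
    payload = {}
    for sid, anns in results.items():
        payload[sid] = [
            {
                "compound": a.compound.name,
                "formula": a.compound.formula.hill(),
                "class": a.compound.compound_class,
                "species": str(a.species),
                "precursor_ppm": a.precursor_ppm,
                "class_score": a.class_score,
                "tier": a.tier,
                "zero_rule_hits_flagged": a.zero_rule_hits_flagged,
                "hits": [
                    {
                        "losses": list(h.losses),
                        "theoretical_mz": h.theoretical_mz,
                        "observed_mz": h.observed_mz,
                        "ppm": h.ppm,
                        "product_formula": h.is_product_formula,
                    }
                    for h in a.hits
                ],
            }
            for a in anns
        ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
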