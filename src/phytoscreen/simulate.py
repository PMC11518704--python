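"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all seed-deterministic:

* `simulate_spectrum` — rule-consistent MS/MS spectra for a library
  compound: one peak per applicable diagnostic entry of the class rule
  (plus the precursor), multiplied by ppm-scale Gaussian mass noise,
  with off-grid decoy peaks placed at least 20 ppm from any true peak.
* `simulate_presence` — compound × matrix detection tables drawn from a
  probability vector over the 2⁶ presence patterns (extract fixed true).
* `simulate_dta` — drug-target activity records whose label follows a
  plantable rule (aromatic-thiophene pharmacophore in the molecule AND
  a 5-residue motif in the protein), flipped with label-noise ε; the
  Bayes-optimal AUROC under that noise is reported in closed form.

Intensities are cosmetic: annotation is m/z-driven; the exponential
intensity model simply documents that.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotate import CompoundRecord, Spectrum
from .chem import (
    DEPROTONATED,
    ELECTRON_MASS,
    INTRINSIC_CATION,
    PROTONATED,
    IonSpecies,
    ion_mz,
    monoisotopic_mass,
)
from .fate import MATRICES, PresenceMatrix
from .rules import FragmentationRule, builtin_rulebase, ion_formula
from .screen.featurize import ActivityRecord

__all__ = [
    "SpectrumSimConfig",
    "FateSimConfig",
    "DTASimConfig",
    "simulate_spectrum",
    "simulate_spectra",
    "simulate_presence",
    "simulate_dta",
    "bayes_auroc",
    "PHARMACOPHORE_TOKEN",
    "PROTEIN_MOTIF",
    "write_spectra_mgf",
]


# ---------------------------------------------------------------------------
# spectra


@dataclass
class SpectrumSimConfig:
    ppm_sigma: float = 2.0
    decoy_fraction: float = 0.3
    intensity_model: str = "exponential"  # or "uniform"
    rt_jitter_min: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.ppm_sigma < 0:
            raise ValueError("ppm sigma must be >= 0")
        if not (0 <= self.decoy_fraction < 1):
            raise ValueError("decoy fraction must be in [0, 1)")
        if self.intensity_model not in ("exponential", "uniform"):
            raise ValueError("intensity model must be exponential or uniform")


@dataclass(frozen=True)
class SpectrumGroundTruth:
    compound: str
    species: str
    true_peaks: Tuple[Tuple[float, Tuple[str, ...]], ...]  # (noiseless m/z, loss path)
    decoy_mzs: Tuple[float, ...]


def preferred_species(record: CompoundRecord, rulebase=None) -> IonSpecies:
    """The ion species the compound class is usually observed as."""
    if record.intrinsic_cation:
        return INTRINSIC_CATION
    if rulebase is None:
        rulebase = builtin_rulebase()
    polarity = rulebase[record.compound_class].polarity
    return DEPROTONATED if polarity == "negative" else PROTONATED


def _diagnostic_peaks(
    record: CompoundRecord, rule: FragmentationRule, species: IonSpecies
) -> List[Tuple[float, Tuple[str, ...]]]:
    """Noiseless (m/z, loss path) for the precursor + every applicable entry."""
    prec_ion = ion_formula(record.formula, species)
    prec_mz = ion_mz(record.formula, species)
    peaks = [(prec_mz, ())]
    for entry in rule.entries:
        if prec_ion.subtract(entry.total_formula()) is not None:
            peaks.append((prec_mz - entry.total_mass(), entry.losses))
    sign = ELECTRON_MASS if species.polarity == "negative" else -ELECTRON_MASS
    for prod in rule.product_formulas:
        if prec_ion.subtract(prod) is not None or prec_ion == prod:
            peaks.append((monoisotopic_mass(prod) + sign, (f"->{prod.hill()}",)))
    return peaks


def simulate_spectrum(
    record: CompoundRecord,
    config: SpectrumSimConfig,
    rng: Optional[np.random.Generator] = None,
    rulebase: Optional[Dict[str, FragmentationRule]] = None,
) -> Tuple[Spectrum, SpectrumGroundTruth]:
    """One rule-consistent spectrum plus its ground-truth annotation."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if rulebase is None:
        rulebase = builtin_rulebase()
    rule = rulebase[record.compound_class]
    species = preferred_species(record, rulebase)
    truth = _diagnostic_peaks(record, rule, species)

    peaks = []
    for mz, _path in truth:
        noisy = mz * (1.0 + rng.normal(0.0, config.ppm_sigma) * 1e-6)
        if config.intensity_model == "exponential":
            inten = float(np.clip(rng.exponential(0.3), 0.01, 1.0))
        else:
            inten = float(rng.uniform(0.05, 1.0))
        peaks.append((noisy, inten))
    peaks[0] = (peaks[0][0], 1.0)  # precursor peak is the base peak

    n_true = len(truth)
    f = config.decoy_fraction
    n_decoys = int(rng.binomial(n_true, f / (1.0 - f))) if f > 0 else 0
    true_mzs = np.array([m for m, _ in truth])
    prec_mz = truth[0][0]
    decoys = []
    lo = min(100.0, prec_mz * 0.5)
    while len(decoys) < n_decoys:
        cand = rng.uniform(lo, prec_mz)
        if np.min(np.abs(cand - true_mzs) / true_mzs) * 1e6 >= 20.0:
            decoys.append(float(cand))
            peaks.append((cand, float(np.clip(rng.exponential(0.15), 0.01, 1.0))))

    rt = None
    if record.rt_min is not None:
        rt = record.rt_min + float(rng.uniform(-config.rt_jitter_min, config.rt_jitter_min))

    spectrum = Spectrum(
        identifier=f"sim::{record.name}",
        polarity=species.polarity,
        precursor_mz=peaks[0][0],
        peaks=tuple(peaks),
        rt_min=rt,
    )
    gt = SpectrumGroundTruth(
        compound=record.name,
        species=str(species),
        true_peaks=tuple((m, p) for m, p in truth),
        decoy_mzs=tuple(decoys),
    )
    return spectrum, gt


def simulate_spectra(
    library: Sequence[CompoundRecord],
    n_spectra: int,
    config: SpectrumSimConfig,
) -> List[Tuple[Spectrum, SpectrumGroundTruth]]:
    """Draw ``n_spectra`` spectra from library compounds (uniformly)."""
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(n_spectra):
        rec = library[int(rng.integers(len(library)))]
        sp, gt = simulate_spectrum(rec, config, rng=rng)
        sp = Spectrum(
            identifier=f"{sp.identifier}::{i}",
            polarity=sp.polarity,
            precursor_mz=sp.precursor_mz,
            peaks=sp.peaks,
            rt_min=sp.rt_min,
        )
        out.append((sp, gt))
    return out


def write_spectra_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra as MGF (deterministic formatting)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.identifier}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.5f}\n")
            fh.write("CHARGE=1" + ("-" if s.polarity == "negative" else "+") + "\n")
            if s.rt_min is not None:
                fh.write(f"RTINSECONDS={s.rt_min * 60.0:.3f}\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.5f} {inten:.5f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# presence / fate


@dataclass
class FateSimConfig:
    n_compounds: int = 100
    #: probability for each of the 64 (gastric..feces) presence patterns,
    #: ordered as binary numbers over (gastric, intestinal, hepatic,
    #: systemic, urine, feces); extract is always present.
    pattern_probs: Optional[Sequence[float]] = None
    seed: int = 0

    def __post_init__(self):
        if self.pattern_probs is None:
            # default: a broad mixture favoring gastric-stable compounds
            probs = np.ones(64)
            probs[63] = 10.0  # present everywhere
            probs[0] = 5.0  # degraded in stomach
            self.pattern_probs = (probs / probs.sum()).tolist()
        p = np.asarray(self.pattern_probs, dtype=float)
        if p.shape != (64,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("pattern_probs must be 64 non-negative numbers summing to 1")


def _pattern_row(code: int) -> Dict[str, bool]:
    bits = [(code >> (5 - i)) & 1 for i in range(6)]
    row = {"extract": True}
    for m, b in zip(MATRICES[1:], bits):
        row[m] = bool(b)
    return row


def simulate_presence(config: FateSimConfig) -> Tuple[PresenceMatrix, Dict[int, int]]:
    """i.i.d. presence rows from the pattern distribution + true tallies."""
    rng = np.random.default_rng(config.seed)
    codes = rng.choice(64, size=config.n_compounds, p=np.asarray(config.pattern_probs))
    rows = []
    tallies: Dict[int, int] = {}
    for i, code in enumerate(codes):
        code = int(code)
        tallies[code] = tallies.get(code, 0) + 1
        rows.append({"compound": f"cpd_{i:04d}", **_pattern_row(code)})
    df = pd.DataFrame(rows).set_index("compound")
    return PresenceMatrix(df), tallies


# ---------------------------------------------------------------------------
# drug-target pairs


#: aromatic thiophene ring token — the plantable pharmacophore
PHARMACOPHORE_TOKEN = "c1ccsc1"
#: 5-residue protein motif detectable by the convolutional encoder
PROTEIN_MOTIF = "HWYKH"

_CHAIN_TOKENS = ["C", "CC", "CO", "CN", "CCO", "CCN", "CC(C)", "CCS", "c1ccccc1"]
_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class DTASimConfig:
    n_pairs: int = 2000
    label_noise: float = 0.05
    class_balance: float = 0.13  # target positive-label fraction
    min_protein_len: int = 60
    max_protein_len: int = 120
    min_mol_tokens: int = 3
    max_mol_tokens: int = 8
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label noise must be in [0, 0.5)")
        if not (0 < self.class_balance < 1):
            raise ValueError("class balance must be in (0, 1)")
        if self.class_balance <= self.label_noise:
            raise ValueError("class balance must exceed the label noise")

    @property
    def rule_positive_fraction(self) -> float:
        """π such that π(1−ε) + (1−π)ε equals the requested balance."""
        return (self.class_balance - self.label_noise) / (1.0 - 2.0 * self.label_noise)


def _random_molecule(rng, config: DTASimConfig, with_pharmacophore: bool) -> str:
    n = int(rng.integers(config.min_mol_tokens, config.max_mol_tokens + 1))
    tokens = [str(rng.choice(_CHAIN_TOKENS)) for _ in range(n)]
    if with_pharmacophore:
        pos = int(rng.integers(0, n + 1))
        tokens.insert(pos, PHARMACOPHORE_TOKEN)
    return "".join(tokens)


def _random_protein(rng, config: DTASimConfig, with_motif: bool) -> str:
    length = int(rng.integers(config.min_protein_len, config.max_protein_len + 1))
    while True:
        seq = "".join(rng.choice(list(_AMINO_ACIDS), size=length))
        if PROTEIN_MOTIF in seq:
            continue  # decoys must not contain the motif by chance
        break
    if with_motif:
        pos = int(rng.integers(0, length - len(PROTEIN_MOTIF) + 1))
        seq = seq[:pos] + PROTEIN_MOTIF + seq[pos + len(PROTEIN_MOTIF) :]
    return seq


def bayes_auroc(label_noise: float, rule_positive_fraction: float) -> float:
    """AUROC of the Bayes-optimal scorer against the noisy labels.

    The optimal scorer outputs the binary rule bit; labels are the rule
    bit XOR Bernoulli(ε).  With π the rule-positive fraction, among
    observed positives a fraction a score 1, among observed negatives a
    fraction b score 1; ties count 1/2.
    """
    eps, pi = label_noise, rule_positive_fraction
    a = pi * (1 - eps) / (pi * (1 - eps) + (1 - pi) * eps)
    b = pi * eps / (pi * eps + (1 - pi) * (1 - eps))
    return a * (1 - b) + 0.5 * (a * b + (1 - a) * (1 - b))


def simulate_dta(config: DTASimConfig) -> Tuple[List[ActivityRecord], float]:
    """Activity records under the motif co-occurrence rule + Bayes AUROC.

    label = [pharmacophore present AND motif present] XOR Bernoulli(ε).
    """
    rng = np.random.default_rng(config.seed)
    # P(pharm) = P(motif) = √π so that the *label* prevalence matches balance
    q = float(np.sqrt(config.rule_positive_fraction))
    records: List[ActivityRecord] = []
    rule_positive = 0
    for i in range(config.n_pairs):
        has_pharm = bool(rng.random() < q)
        has_motif = bool(rng.random() < q)
        rule = has_pharm and has_motif
        rule_positive += rule
        label = int(rule) ^ int(rng.random() < config.label_noise)
        records.append(
            ActivityRecord(
                substance_id=f"MOL{i:05d}",
                smiles=_random_molecule(rng, config, has_pharm),
                target_id=f"TGT{i:05d}",
                sequence=_random_protein(rng, config, has_motif),
                category="Active" if label else "Inactive",
                label=label,
            )
        )
    return records, bayes_auroc(config.label_noise, rule_positive / config.n_pairs)


def rule_label(record: ActivityRecord) -> int:
    """Noise-free ground-truth bit of the planted co-occurrence rule."""
    return int(
        PHARMACOPHORE_TOKEN in record.smiles and PROTEIN_MOTIF in record.sequence
    )


def dta_records_to_frame(records: Sequence[ActivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "substance_id": [r.substance_id for r in records],
            "smiles": [r.smiles for r in records],
            "target_id": [r.target_id for r in records],
            "sequence": [r.sequence for r in records],
            "category": [r.category for r in records],
            "label": [r.label for r in records],
        }
    )
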