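"""Sequential-metabolism fate assignment.

After oral dosing a prototype compound passes, in order, through gastric
juice, the intestinal lumen/wall (sampled at the mesenteric vein), the
liver (sampled at the femoral vein after first pass), the systemic
circulation, and finally urinary/fecal excretion.  Detection (presence /
absence) of each compound across the six biological matrices plus the
dosing extract yields a deterministic fate label:

* absent in the gastric sample        -> degraded in the stomach;
* present gastric, absent intestinal  -> blocked or consumed at the
  intestinal barrier;
* present intestinal, absent hepatic  -> removed by hepatic (first-pass)
  metabolism;
* present hepatic, absent systemic    -> cleared from circulation;
* "absorbed" = detected in any plasma-derived matrix (intestinal,
  hepatic, systemic — the complementary sampling routes).

Presence is boolean at the caller's detection threshold; quantitative
bioavailability and parent→metabolite linkage are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Sequence

import pandas as pd

__all__ = [
    "MATRICES",
    "PLASMA_MATRICES",
    "FateLabel",
    "PresenceMatrix",
    "classify_fate",
    "summarize",
]

#: fixed matrix vocabulary, in sequential order
MATRICES = ("extract", "gastric", "intestinal", "hepatic", "systemic", "urine", "feces")
#: plasma-derived matrices whose union defines "absorbed"
PLASMA_MATRICES = ("intestinal", "hepatic", "systemic")


@dataclass(frozen=True)
class FateLabel:
    gastric_stable: bool
    absorbed: bool
    site_flags: FrozenSet[str]
    excretion: FrozenSet[str]

    def as_dict(self) -> dict:
        return {
            "gastric_stable": self.gastric_stable,
            "absorbed": self.absorbed,
            "site_flags": sorted(self.site_flags),
            "excretion": sorted(self.excretion),
        }


class PresenceMatrix:
    """Compound × matrix boolean detection table.

    Wraps a pandas DataFrame indexed by compound with the seven fixed
    matrix columns.  Every compound must be present in the extract (the
    prototype universe).
    """

    def __init__(self, table: pd.DataFrame):
        missing = [m for m in MATRICES if m not in table.columns]
        if missing:
            raise ValueError(f"presence table missing matrices: {missing}")
        extra = [c for c in table.columns if c not in MATRICES]
        if extra:
            raise ValueError(f"unknown matrix columns: {extra}")
        if table.isna().any().any():
            bad = table.isna().stack()
            compound, matrix = bad[bad].index[0]
            raise ValueError(f"missing matrix value for {compound!r} in {matrix!r}")
        table = table[list(MATRICES)].astype(bool)
        if not table["extract"].all():
            absent = table.index[~table["extract"]].tolist()
            raise ValueError(f"compounds absent from extract: {absent}")
        self.table = table

    @classmethod
    def from_csv(cls, path, sep=None) -> "PresenceMatrix":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.table.astype(int).to_csv(path, sep="\t")

    @property
    def compounds(self) -> List[str]:
        return list(self.table.index)

    def row(self, compound: str) -> Dict[str, bool]:
        return {m: bool(v) for m, v in self.table.loc[compound].items()}


def classify_fate(row: Mapping[str, bool]) -> FateLabel:
    """Deterministic fate label for one complete presence row."""
    missing = [m for m in MATRICES if m not in row]
    if missing:
        raise ValueError(f"row missing matrices: {missing}")
    gastric_stable = bool(row["gastric"])
    absorbed = any(bool(row[m]) for m in PLASMA_MATRICES)

    flags = set()
    if not row["gastric"]:
        flags.add("degraded_in_stomach")
    if row["gastric"] and not row["intestinal"]:
        flags.add("intestinal_barrier_or_metabolism")
    if row["intestinal"] and not row["hepatic"]:
        flags.add("hepatic_metabolism")
    if row["hepatic"] and not row["systemic"]:
        flags.add("cleared_from_systemic")

    excretion = {m for m in ("urine", "feces") if row[m]}
    if not excretion:
        excretion = {"none_detected"}
    return FateLabel(
        gastric_stable=gastric_stable,
        absorbed=absorbed,
        site_flags=frozenset(flags),
        excretion=frozenset(excretion),
    )


def summarize(matrix: PresenceMatrix) -> dict:
    """Per-matrix detection counts plus fate tallies.

    Counts equal column sums; the absorbed count is the union over the
    plasma matrices.  The result is JSON/TSV-serializable.
    """
    table = matrix.table
    counts = {m: int(table[m].sum()) for m in MATRICES}
    labels = {c: classify_fate(matrix.row(c)) for c in matrix.compounds}

    flag_tally: Dict[str, int] = {
        f: 0
        for f in (
            "degraded_in_stomach",
            "intestinal_barrier_or_metabolism",
            "hepatic_metabolism",
            "cleared_from_systemic",
        )
    }
    excretion_tally = {"urine": 0, "feces": 0, "none_detected": 0}
    absorbed = 0
    gastric_stable = 0
    for lab in labels.values():
        absorbed += lab.absorbed
        gastric_stable += lab.gastric_stable
        for f in lab.site_flags:
            flag_tally[f] += 1
        for e in lab.excretion:
            excretion_tally[e] += 1

    return {
        "n_compounds": len(labels),
        "matrix_counts": counts,
        "absorbed": absorbed,
        "gastric_stable": gastric_stable,
        "site_flags": flag_tally,
        "excretion": excretion_tally,
    }


def write_fate_report(matrix: PresenceMatrix, out_dir) -> None:
    """TSV fate report (one row per compound) + JSON summary."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in matrix.compounds:
        lab = classify_fate(matrix.row(c))
        rows.append(
            {
                "compound": c,
                "gastric_stable": int(lab.gastric_stable),
                "absorbed": int(lab.absorbed),
                "site_flags": ";".join(sorted(lab.site_flags)) or "-",
                "excretion": ";".join(sorted(lab.excretion)),
            }
        )
    pd.DataFrame(rows).to_csv(out / "fate_report.tsv", sep="\t", index=False)
    with open(out / "fate_summary.json", "w") as fh:
        json.dump(summarize(matrix), fh, indent=1)
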