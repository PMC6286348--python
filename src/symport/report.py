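"""Per-construct parameter tables and comparative statistics.

Assembles measured transporter parameters (apparent affinities K_0.5 and
inhibition constants K_i per construct) and derives the two comparative
quantities of interest: mutant-vs-wild-type fold changes within a subtype,
and inhibitor subtype selectivity K_i(hSGLT1)/K_i(hSGLT2).

A transcription of the measured parameter table ships with the package
(``data/table1.csv``) so the report runs offline; a provenance column records
which entries come from earlier literature, and entries reported only as a
bound (e.g. ">100 mM") are left blank rather than used in ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import math

import pandas as pd

__all__ = [
    "PARAMETERS",
    "ConstructRecord",
    "FoldChange",
    "fold_change",
    "load_packaged_records",
    "records_from_frame",
    "build_selectivity_table",
    "SelectivityReport",
]

#: parameter key -> unit
PARAMETERS = {
    "k05_sugar": "mM",
    "k05_na": "mM",
    "ki_phlorizin": "uM",
    "ki_phloretin": "uM",
    "ki_dapagliflozin": "uM",
    "ki_dapa_aglycon": "uM",
}

INHIBITOR_PARAMS = ("ki_phlorizin", "ki_phloretin", "ki_dapagliflozin",
                    "ki_dapa_aglycon")


@dataclass
class ConstructRecord:
    construct: str
    subtype: str
    is_wild_type: bool
    params: dict[str, float] = field(default_factory=dict)
    sems: dict[str, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        for key, value in self.params.items():
            if key not in PARAMETERS:
                raise ValueError(f"unknown parameter {key!r}")
            if value <= 0:
                raise ValueError(f"{self.construct}: {key} must be positive")


@dataclass(frozen=True)
class FoldChange:
    ratio: float          # a / b
    direction: str        # 'increase' | 'decrease' | 'unchanged'
    unit: str = ""

    @property
    def magnitude(self) -> float:
        """Fold magnitude >= 1 regardless of direction."""
        return self.ratio if self.ratio >= 1 else 1.0 / self.ratio

    @property
    def label(self) -> str:
        """Human label: nearest integer above 10-fold, one decimal below."""
        m = self.magnitude
        text = f"{round(m)}-fold" if m >= 10 else f"{m:.1f}-fold"
        return f"{text} {self.direction}" if self.direction != "unchanged" else text


def fold_change(a: float, b: float, unit_a: str = "", unit_b: str = "") -> FoldChange:
    """Direction-annotated ratio a/b.

    Satisfies reciprocal antisymmetry: fold_change(a, b).ratio *
    fold_change(b, a).ratio == 1.
    """
    if unit_a != unit_b:
        raise ValueError(f"unit mismatch: {unit_a!r} vs {unit_b!r}")
    if a <= 0 or b <= 0 or not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError("fold change requires positive finite values")
    if a > b:
        direction = "increase"
    elif a < b:
        direction = "decrease"
    else:
        direction = "unchanged"
    return FoldChange(ratio=a / b, direction=direction, unit=unit_a)


def records_from_frame(frame: pd.DataFrame) -> list[ConstructRecord]:
    """Build construct records from a tidy wide table (see data/table1.csv)."""
    records = []
    for _, row in frame.iterrows():
        params, sems = {}, {}
        for key, unit in PARAMETERS.items():
            val = row.get(f"{key}_{unit}")
            if pd.notna(val):
                params[key] = float(val)
            sem = row.get(f"{key}_sem")
            if pd.notna(sem):
                sems[key] = float(sem)
        records.append(ConstructRecord(
            construct=str(row["construct"]),
            subtype=str(row["subtype"]),
            is_wild_type=bool(row["is_wild_type"]),
            params=params, sems=sems,
            provenance=str(row.get("provenance", "")),
        ))
    return records


def load_packaged_records() -> list[ConstructRecord]:
    """Load the packaged per-construct parameter table."""
    with resources.files("symport.data").joinpath("table1.csv").open() as fh:
        frame = pd.read_csv(fh)
    return records_from_frame(frame)


@dataclass
class SelectivityReport:
    selectivity: pd.DataFrame    # per inhibitor: K_i(hSGLT1)/K_i(hSGLT2)
    fold_changes: pd.DataFrame   # per mutant x parameter vs subtype wild-type
    flagged: list[str] = field(default_factory=list)

    def to_markdown(self) -> str:
        lines = ["# Transporter selectivity report", "",
                 "## Inhibitor subtype selectivity (K_i hSGLT1 / K_i hSGLT2)", ""]
        if self.selectivity.empty:
            lines.append("(no inhibitor measured in both subtypes)")
        else:
            lines.append("| inhibitor | K_i hSGLT1 (uM) | K_i hSGLT2 (uM) | selectivity | label |")
            lines.append("|---|---|---|---|---|")
            for _, r in self.selectivity.iterrows():
                lines.append(
                    f"| {r['inhibitor']} | {r['ki_sglt1']:g} | {r['ki_sglt2']:g} "
                    f"| {r['selectivity']:.4g} | {r['label']} |")
        lines += ["", "## Mutant fold changes vs wild-type", ""]
        if self.fold_changes.empty:
            lines.append("(no mutant/wild-type pair available)")
        else:
            lines.append("| construct | parameter | mutant | wild-type | ratio | label |")
            lines.append("|---|---|---|---|---|---|")
            for _, r in self.fold_changes.iterrows():
                lines.append(
                    f"| {r['construct']} | {r['parameter']} | {r['mutant_value']:g} "
                    f"| {r['wildtype_value']:g} | {r['ratio']:.4g} | {r['label']} |")
        for note in self.flagged:
            lines.append(f"\n> flagged: {note}")
        return "\n".join(lines) + "\n"


def build_selectivity_table(records: list[ConstructRecord]) -> SelectivityReport:
    """Compute subtype selectivity and mutant fold changes.

    Selectivity is computed between the two wild-type records for every
    inhibitor measured in both.  Each mutant is compared against the wild type
    of its own subtype on every shared parameter; a mutant lacking its
    wild-type reference is flagged, not dropped.  Row order is deterministic
    (inhibitor order as declared; constructs and parameters sorted).
    """
    wild_types = {r.subtype: r for r in records if r.is_wild_type}
    flagged: list[str] = []

    sel_rows = []
    wt1, wt2 = wild_types.get("hSGLT1"), wild_types.get("hSGLT2")
    if wt1 and wt2:
        for inh in INHIBITOR_PARAMS:
            if inh in wt1.params and inh in wt2.params:
                fc = fold_change(wt1.params[inh], wt2.params[inh],
                                 PARAMETERS[inh], PARAMETERS[inh])
                sel_rows.append((inh.removeprefix("ki_"), wt1.params[inh],
                                 wt2.params[inh], fc.ratio, fc.label))
    selectivity = pd.DataFrame(
        sel_rows, columns=["inhibitor", "ki_sglt1", "ki_sglt2",
                           "selectivity", "label"])

    fc_rows = []
    for rec in sorted((r for r in records if not r.is_wild_type),
                      key=lambda r: r.construct):
        wt = wild_types.get(rec.subtype)
        if wt is None:
            flagged.append(f"{rec.construct}: no {rec.subtype} wild-type reference")
            continue
        for param in sorted(set(rec.params) & set(wt.params)):
            fc = fold_change(rec.params[param], wt.params[param],
                             PARAMETERS[param], PARAMETERS[param])
            fc_rows.append((rec.construct, param, rec.params[param],
                            wt.params[param], fc.ratio, fc.magnitude,
                            fc.label))
    fold_changes = pd.DataFrame(
        fc_rows, columns=["construct", "parameter", "mutant_value",
                          "wildtype_value", "ratio", "fold", "label"])
    return SelectivityReport(selectivity=selectivity,
                             fold_changes=fold_changes, flagged=flagged)
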