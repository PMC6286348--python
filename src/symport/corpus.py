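"""Corpus assembly: structure reading, quality filters, redundancy removal.

Reproduces the selection protocol for a survey of Na+-containing crystal
structures: X-ray entries at resolution <= 2.5 Angstrom with R_obs <= 0.3,
at least one protein chain of 40-100000 residues, no nucleic-acid chains,
and at least one Na+ ion — followed by greedy clustering at 50% pairwise
sequence identity to keep one representative per family.

Identity here is matches / alignment columns (terminal gaps excluded) from a
global alignment (match +1, mismatch 0, affine gaps); a local definition is
needed because the original selection delegated clustering to a web service.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import gemmi
import pandas as pd
from Bio import Align

logger = logging.getLogger(__name__)

__all__ = [
    "StructureMeta",
    "FilterCriteria",
    "read_structure",
    "read_metadata",
    "passes_quality_filters",
    "pairwise_identity",
    "select_representatives",
    "prune_altlocs",
    "expand_assembly",
]


@dataclass(frozen=True)
class StructureMeta:
    """Sidecar metadata for one deposited entry."""

    entry_id: str
    method: str                # 'xray' or 'other'
    resolution: float | None   # Angstrom
    r_obs: float | None
    chain_lengths: tuple[int, ...]
    has_nucleic: bool
    contains_na: bool

    def __post_init__(self):
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")
        if self.r_obs is not None and not (0.0 <= self.r_obs <= 1.0):
            raise ValueError("r_obs must be in [0, 1]")


@dataclass(frozen=True)
class FilterCriteria:
    """Corpus selection thresholds; defaults are the survey's settings."""

    resolution_max: float = 2.5      # inclusive upper bound, lower bound open at 0
    r_obs_max: float = 0.3           # inclusive
    chain_length_min: int = 40
    chain_length_max: int = 100000
    require_xray: bool = True
    exclude_nucleic: bool = True
    require_na: bool = True


def read_structure(path: str | Path, dialect: str | None = None) -> gemmi.Structure:
    """Read a PDB or mmCIF file into a gemmi.Structure.

    ``dialect`` forces the format ('pdb' or 'mmcif'); by default it is
    inferred from the extension.  Waters, metals and altlocs are retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        None: gemmi.CoorFormat.Detect,
    }[dialect]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path.name}: {exc}") from exc
    if st[0].count_atom_sites() == 0:
        raise ValueError(f"cannot parse {path.name}: no atoms found")
    st.setup_entities()
    return st


def prune_altlocs(structure: gemmi.Structure) -> gemmi.Structure:
    """Keep one conformer per atom: highest occupancy, ties broken by altloc.

    Guarantees a single coordination shell per ion downstream.
    """
    for model in structure:
        for chain in model:
            for residue in chain:
                by_name: dict[str, list] = {}
                for atom in residue:
                    by_name.setdefault(atom.name, []).append(atom)
                keep_altloc: dict[str, str] = {}
                for name, atoms in by_name.items():
                    if len(atoms) > 1:
                        best = min(atoms, key=lambda a: (-a.occ, a.altloc))
                        keep_altloc[name] = best.altloc
                if not keep_altloc:
                    continue
                for name, altloc in keep_altloc.items():
                    for atom in list(residue):
                        if atom.name == name and atom.altloc != altloc:
                            residue.remove_atom(atom.name, atom.altloc,
                                                atom.element)
                    for atom in residue:
                        if atom.name == name:
                            atom.altloc = "\0"
    return structure


def expand_assembly(structure: gemmi.Structure,
                    assembly_name: str | None = None) -> gemmi.Structure:
    """Expand the biological assembly when operators are present.

    Falls back to the asymmetric unit (with a logged note) when the file
    carries no assembly definitions.
    """
    if len(structure.assemblies) == 0:
        logger.info("%s: no assembly operators; using asymmetric unit",
                    structure.name)
        return structure
    name = assembly_name or structure.assemblies[0].name
    expanded = structure.clone()
    expanded.transform_to_assembly(name, gemmi.HowToNameCopiedChain.AddNumber)
    return expanded


def read_metadata(path: str | Path) -> list[StructureMeta]:
    """Load entry metadata from a CSV or JSON sidecar.

    Required fields: entry_id, method, resolution, r_obs, chain_lengths
    (';'-separated in CSV), has_nucleic, contains_na.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict("records")
    out = []
    for rec in records:
        lengths = rec["chain_lengths"]
        if isinstance(lengths, str):
            lengths = tuple(int(t) for t in lengths.split(";") if t)
        elif isinstance(lengths, (int, float)):
            lengths = (int(lengths),)
        out.append(StructureMeta(
            entry_id=str(rec["entry_id"]),
            method=str(rec["method"]),
            resolution=None if pd.isna(rec["resolution"]) else float(rec["resolution"]),
            r_obs=None if pd.isna(rec["r_obs"]) else float(rec["r_obs"]),
            chain_lengths=tuple(lengths),
            has_nucleic=bool(rec["has_nucleic"]),
            contains_na=bool(rec["contains_na"]),
        ))
    return out


def passes_quality_filters(meta: StructureMeta,
                           criteria: FilterCriteria | None = None) -> bool:
    """True iff the entry satisfies every corpus-selection criterion.

    Bounds are inclusive at the stated maxima (resolution 2.5 and R_obs 0.30
    both pass); missing required metadata raises rather than silently passing.
    """
    c = criteria or FilterCriteria()
    if c.require_xray and meta.method != "xray":
        return False
    if meta.resolution is None:
        raise ValueError(f"{meta.entry_id}: resolution missing")
    if not (0.0 < meta.resolution <= c.resolution_max):
        return False
    if meta.r_obs is None:
        raise ValueError(f"{meta.entry_id}: r_obs missing")
    if meta.r_obs > c.r_obs_max:
        return False
    if not any(c.chain_length_min <= ln <= c.chain_length_max
               for ln in meta.chain_lengths):
        return False
    if c.exclude_nucleic and meta.has_nucleic:
        return False
    if c.require_na and not meta.contains_na:
        return False
    return True


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    # terminal gaps are free so the identity denominator trims overhangs
    aligner.end_gap_score = 0.0
    return aligner


def pairwise_identity(seq_a: str, seq_b: str,
                      aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matches / columns, terminal gaps excluded."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = aligner or _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    # trim terminal-gap columns
    start = 0
    end = len(a)
    while start < end and (a[start] == "-" or b[start] == "-"):
        start += 1
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    if end == start:
        return 0.0
    matches = sum(1 for i in range(start, end) if a[i] == b[i])
    return matches / (end - start)


def select_representatives(sequences: list[tuple[str, str]],
                           identity_threshold: float = 0.5) -> list[str]:
    """Greedy redundancy clustering; returns one representative id per cluster.

    Sequences are visited in order of descending length (ties broken by id so
    the result is deterministic); each joins the first existing cluster whose
    representative it matches at >= the identity threshold, else it founds a
    new cluster.
    """
    if not sequences:
        raise ValueError("no sequences given")
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity threshold must be in (0, 1]")
    for sid, seq in sequences:
        if not seq:
            raise ValueError(f"empty sequence for {sid!r}")
    aligner = _make_aligner()
    ordered = sorted(sequences, key=lambda kv: (-len(kv[1]), kv[0]))
    reps: list[tuple[str, str]] = []
    for sid, seq in ordered:
        for rep_id, rep_seq in reps:
            if pairwise_identity(seq, rep_seq, aligner) >= identity_threshold:
                break
        else:
            reps.append((sid, seq))
    return [sid for sid, _ in reps]
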