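"""Na+ coordination-shell detection, contact classification, census statistics.

A coordination shell is the set of O/N donor atoms within a distance cutoff
of a Na+ ion (default 3.0 Angstrom; typical Na-O bonds are 2.3-2.5).  Each
contact is classified as a side-chain donor, a main-chain carbonyl, a water,
or other hetero atom, and acidic residues donating both carboxylate oxygens
to the same ion are flagged as bidentate.  Corpus-level statistics summarize
coordination-number distributions, residue-type rankings and motif counts.

Waters count toward the coordination number but are tracked as their own
class, so protein-only statistics are reported alongside the all-donor ones.
Hydrogens are ignored throughout: no criterion here depends on H positions.
Donors are restricted to O and N because Na+ is a hard cation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Contact",
    "NaSite",
    "CensusSummary",
    "detect_na_sites",
    "classify_contacts",
    "summarize_census",
    "contacts_to_frame",
]

#: named side-chain O/N donors of the standard residues
SIDE_CHAIN_DONORS = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
    ("SER", "OG"), ("THR", "OG1"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("TYR", "OH"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}

#: residues whose carboxylate can chelate an ion with both oxygens
BIDENTATE_PAIRS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

WATER_NAMES = {"HOH", "WAT", "DOD"}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


@dataclass
class Contact:
    """One donor atom in a coordination shell."""

    atom: str
    residue_name: str
    residue_number: int
    icode: str
    chain: str
    distance: float                 # Angstrom, recorded to 1e-3
    rel_pos: np.ndarray             # donor position relative to the ion
    ligand_class: str = "unclassified"
    is_protein: bool = False


@dataclass
class NaSite:
    """One Na+ ion and its coordination shell."""

    entry_id: str
    chain: str
    residue_number: int
    contacts: list[Contact] = field(default_factory=list)
    bidentate_residues: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def coordination_number(self) -> int:
        return len(self.contacts)

    @property
    def protein_coordination_number(self) -> int:
        return sum(1 for c in self.contacts if c.is_protein)

    def residue_keys(self, ligand_class: str | None = None):
        keys = []
        for c in self.contacts:
            if ligand_class is None or c.ligand_class == ligand_class:
                keys.append((c.chain, c.residue_number, c.icode, c.residue_name))
        return keys


def _is_water(residue_name: str) -> bool:
    return residue_name.upper() in WATER_NAMES


def detect_na_sites(structure: gemmi.Structure, cutoff: float = 3.0,
                    entry_id: str | None = None) -> list[NaSite]:
    """Find every Na+ ion with at least one protein-derived donor contact.

    Donors are O or N atoms (including water O) within ``cutoff`` of the ion;
    other metal atoms never count as donors.  Ions with no protein-derived
    contact are dropped.  Distances are recorded to 1e-3 Angstrom.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    entry_id = entry_id or structure.name or "entry"
    model = structure[0]

    ions = []
    donors = []  # (chain, residue, atom, pos)
    for chain in model:
        for residue in chain:
            for atom in residue:
                el = atom.element.name
                if el == "Na" and residue.name.upper() in ("NA", "SOD"):
                    ions.append((chain.name, residue, atom))
                elif el in ("O", "N") and not atom.element.is_metal:
                    donors.append((chain.name, residue, atom))

    sites = []
    for chain_name, ion_res, ion_atom in ions:
        site = NaSite(entry_id=entry_id, chain=chain_name,
                      residue_number=ion_res.seqid.num)
        ion_pos = np.array([ion_atom.pos.x, ion_atom.pos.y, ion_atom.pos.z])
        for dchain, dres, datom in donors:
            dist = ion_atom.pos.dist(datom.pos)
            if dist > cutoff:
                continue
            pos = np.array([datom.pos.x, datom.pos.y, datom.pos.z])
            is_protein = (dres.het_flag == "A"
                          or dres.name.upper() in AMINO_ACIDS)
            site.contacts.append(Contact(
                atom=datom.name,
                residue_name=dres.name,
                residue_number=dres.seqid.num,
                icode=dres.seqid.icode.strip() if dres.seqid.icode else "",
                chain=dchain,
                distance=round(dist, 3),
                rel_pos=pos - ion_pos,
                is_protein=is_protein,
            ))
        if any(c.is_protein for c in site.contacts):
            site.contacts.sort(key=lambda c: (c.distance, c.chain,
                                              c.residue_number, c.atom))
            sites.append(site)
    return sites


def classify_contacts(site: NaSite,
                      structure: gemmi.Structure | None = None) -> NaSite:
    """Assign a ligand class to every contact and populate the bidentate list.

    Classes: ``side_chain`` (named side-chain O/N of a standard residue),
    ``main_chain_carbonyl`` (backbone O, including OXT), ``water`` (water O),
    ``other_hetero`` (anything else, logged but never dropped).
    """
    for c in site.contacts:
        rname = c.residue_name.upper()
        if _is_water(rname):
            c.ligand_class = "water"
        elif c.is_protein and c.atom in ("O", "OXT"):
            c.ligand_class = "main_chain_carbonyl"
        elif (rname, c.atom) in SIDE_CHAIN_DONORS:
            c.ligand_class = "side_chain"
        else:
            if c.is_protein:
                logger.warning("%s %s/%s%d: unrecognized donor %s/%s -> "
                               "other_hetero", site.entry_id, c.chain,
                               rname, c.residue_number, rname, c.atom)
            c.ligand_class = "other_hetero"

    site.bidentate_residues = []
    by_residue: dict[tuple, set[str]] = {}
    for c in site.contacts:
        if c.ligand_class != "side_chain":
            continue
        key = (c.chain, c.residue_number, c.icode, c.residue_name.upper())
        by_residue.setdefault(key, set()).add(c.atom)
    for (chain, num, icode, rname), atoms in sorted(by_residue.items()):
        pair = BIDENTATE_PAIRS.get(rname)
        if pair and set(pair) <= atoms:
            site.bidentate_residues.append((chain, num, rname))
    return site


@dataclass
class CensusSummary:
    """Corpus-level statistics over classified coordination sites."""

    n_sites: int
    cn_histogram: dict[int, int]
    cn_mean: float
    cn_mode: int
    cn_histogram_protein: dict[int, int]
    cn_mean_protein: float
    cn_mode_protein: int
    side_chain_residue_counts: dict[str, int]
    main_chain_residue_counts: dict[str, int]
    main_chain_contact_counts: dict[str, int]
    bidentate_fraction: dict[str, float]
    serthr_adjacent_sites: int
    cutoff_note: str = ""

    @staticmethod
    def _ranking(counts: dict[str, int]) -> list[tuple[str, int]]:
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def side_chain_ranking(self) -> list[tuple[str, int]]:
        """Residue types by number of residues donating a side-chain contact,
        descending; ties broken alphabetically."""
        return self._ranking(self.side_chain_residue_counts)

    def main_chain_ranking(self, per_contact: bool = False) -> list[tuple[str, int]]:
        counts = (self.main_chain_contact_counts if per_contact
                  else self.main_chain_residue_counts)
        return self._ranking(counts)

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "cn_histogram": {str(k): v for k, v in sorted(self.cn_histogram.items())},
            "cn_mean": self.cn_mean,
            "cn_mode": self.cn_mode,
            "cn_histogram_protein": {str(k): v for k, v
                                     in sorted(self.cn_histogram_protein.items())},
            "cn_mean_protein": self.cn_mean_protein,
            "cn_mode_protein": self.cn_mode_protein,
            "side_chain_residue_counts": dict(self.side_chain_ranking()),
            "main_chain_residue_counts": dict(self.main_chain_ranking()),
            "main_chain_contact_counts": dict(self.main_chain_ranking(True)),
            "bidentate_fraction": self.bidentate_fraction,
            "serthr_adjacent_sites": self.serthr_adjacent_sites,
            "cutoff_note": self.cutoff_note,
        }


def _mode(counter: Counter) -> int:
    # deterministic: highest count, smallest coordination number on ties
    return min(counter, key=lambda k: (-counter[k], k))


def summarize_census(sites: list[NaSite], cutoff_note: str = "") -> CensusSummary:
    """Aggregate classified sites into a census summary.

    Residue rankings count distinct residues (per site) contributing at least
    one contact of the given class; the per-contact main-chain variant is also
    reported.  Bidentate fractions are per acidic residue type: bidentate
    residues over all residues of that type donating any side-chain contact.
    """
    from .similarity import has_serthr_adjacent

    if not sites:
        raise ValueError("empty site list")
    if any(c.ligand_class == "unclassified"
           for site in sites for c in site.contacts):
        raise ValueError("sites must be classified first (classify_contacts)")

    cn_all = Counter(s.coordination_number for s in sites)
    cn_prot = Counter(s.protein_coordination_number for s in sites)

    side_counts: Counter = Counter()
    main_res_counts: Counter = Counter()
    main_contact_counts: Counter = Counter()
    acidic_total: Counter = Counter()
    acidic_bidentate: Counter = Counter()
    serthr = 0

    for site in sites:
        for key in set(site.residue_keys("side_chain")):
            side_counts[key[3].upper()] += 1
        for key in set(site.residue_keys("main_chain_carbonyl")):
            main_res_counts[key[3].upper()] += 1
        for c in site.contacts:
            if c.ligand_class == "main_chain_carbonyl":
                main_contact_counts[c.residue_name.upper()] += 1
        bident = {(ch, num) for ch, num, _ in site.bidentate_residues}
        for key in set(site.residue_keys("side_chain")):
            rname = key[3].upper()
            if rname in BIDENTATE_PAIRS:
                acidic_total[rname] += 1
                if (key[0], key[1]) in bident:
                    acidic_bidentate[rname] += 1
        if has_serthr_adjacent(site):
            serthr += 1

    n = len(sites)
    return CensusSummary(
        n_sites=n,
        cn_histogram=dict(cn_all),
        cn_mean=sum(k * v for k, v in cn_all.items()) / n,
        cn_mode=_mode(cn_all),
        cn_histogram_protein=dict(cn_prot),
        cn_mean_protein=sum(k * v for k, v in cn_prot.items()) / n,
        cn_mode_protein=_mode(cn_prot),
        side_chain_residue_counts=dict(side_counts),
        main_chain_residue_counts=dict(main_res_counts),
        main_chain_contact_counts=dict(main_contact_counts),
        bidentate_fraction={r: acidic_bidentate[r] / acidic_total[r]
                            for r in acidic_total},
        serthr_adjacent_sites=serthr,
        cutoff_note=cutoff_note,
    )


def contacts_to_frame(sites: list[NaSite]) -> pd.DataFrame:
    """Tidy per-contact table (one row per donor atom) for CSV export."""
    rows = []
    for s in sites:
        for c in s.contacts:
            rows.append((s.entry_id, s.chain, s.residue_number, c.chain,
                         c.residue_name, c.residue_number, c.icode, c.atom,
                         c.distance, c.ligand_class))
    return pd.DataFrame(rows, columns=[
        "entry_id", "ion_chain", "ion_residue", "chain", "residue_name",
        "residue_number", "icode", "atom", "distance_A", "ligand_class"])
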