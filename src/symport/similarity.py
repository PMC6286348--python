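"""Comparison and search of Na+ coordination sites.

A site is reduced to a fingerprint — ligand-class and residue-type multisets,
bidentate/Ser-Thr-adjacency flags, and the donor-atom coordinates relative to
the ion — which is invariant to rigid motion of the parent structure.  Two
fingerprints are compared by least-squares superposition of the ion-centered
donor clouds over *proper* rotations only (reflections would silently match a
site to its mirror image, which is chemically distinct), minimizing over all
class-preserving donor correspondences.  Coordination numbers are small
(<= 8), so exhaustive correspondence search is cheap and exact.

Census search filters on the motif flags (bidentate acidic residue,
Ser/Thr at consecutive positions) and optionally on an RMSD ceiling, the
computable analog of "structurally similar coordination site".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .census import NaSite

__all__ = [
    "SiteFingerprint",
    "SearchCriteria",
    "Match",
    "IncomparableSitesError",
    "fingerprint_from_site",
    "superpose_sites",
    "has_serthr_adjacent",
    "find_similar_sites",
]


class IncomparableSitesError(ValueError):
    """Raised when two sites cannot be superposed at all (different ligand
    class multisets) — distinct from being comparable but dissimilar."""


@dataclass
class SiteFingerprint:
    entry_id: str
    ligand_classes: tuple[str, ...]        # per donor, parallel to coords
    residue_types: tuple[str, ...]
    has_bidentate_acidic: bool
    has_serthr_adjacent: bool
    coords: np.ndarray                      # (n, 3), ion at the origin

    @property
    def coordination_number(self) -> int:
        return len(self.ligand_classes)

    def class_multiset(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.ligand_classes:
            out[c] = out.get(c, 0) + 1
        return out


def has_serthr_adjacent(site: "NaSite") -> bool:
    """True iff two contacts are Ser/Thr side-chain oxygens on one chain at
    consecutive author numbers (no insertion codes in between)."""
    hydroxyls = []
    for c in site.contacts:
        rname = c.residue_name.upper()
        if ((rname == "SER" and c.atom == "OG")
                or (rname == "THR" and c.atom == "OG1")):
            if not c.icode:
                hydroxyls.append((c.chain, c.residue_number))
    positions = set(hydroxyls)
    return any((chain, num + 1) in positions for chain, num in positions)


def fingerprint_from_site(site: "NaSite") -> SiteFingerprint:
    """Fingerprint a classified coordination site."""
    if any(c.ligand_class == "unclassified" for c in site.contacts):
        raise ValueError("classify_contacts must run before fingerprinting")
    coords = np.array([c.rel_pos for c in site.contacts], dtype=float)
    return SiteFingerprint(
        entry_id=site.entry_id,
        ligand_classes=tuple(c.ligand_class for c in site.contacts),
        residue_types=tuple(c.residue_name.upper() for c in site.contacts),
        has_bidentate_acidic=bool(site.bidentate_residues),
        has_serthr_adjacent=has_serthr_adjacent(site),
        coords=coords,
    )


def _proper_rotation_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares RMSD of b onto a over proper rotations about the origin
    (the ion position), via the determinant-corrected Kabsch solution."""
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = (rot @ b.T).T - a
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def superpose_sites(a: SiteFingerprint, b: SiteFingerprint) -> float:
    """Minimal RMSD between two sites over class-preserving correspondences.

    Raises :class:`IncomparableSitesError` when the ligand-class multisets
    differ (sites of different composition are not comparable, as opposed to
    comparable-but-dissimilar).
    """
    if a.class_multiset() != b.class_multiset():
        raise IncomparableSitesError(
            f"not comparable: ligand-class multisets differ "
            f"({a.class_multiset()} vs {b.class_multiset()})")
    classes = sorted(a.class_multiset())
    a_groups = [[i for i, c in enumerate(a.ligand_classes) if c == cls]
                for cls in classes]
    b_groups = [[i for i, c in enumerate(b.ligand_classes) if c == cls]
                for cls in classes]
    a_order = [i for grp in a_groups for i in grp]
    a_pts = a.coords[a_order]

    best = np.inf
    for perm_combo in itertools.product(
            *(itertools.permutations(grp) for grp in b_groups)):
        b_order = [i for grp in perm_combo for i in grp]
        rmsd = _proper_rotation_rmsd(a_pts, b.coords[b_order])
        if rmsd < best:
            best = rmsd
    return best


@dataclass(frozen=True)
class SearchCriteria:
    require_bidentate_acidic: bool = False
    require_serthr_adjacent: bool = False
    rmsd_max: float | None = None


@dataclass
class Match:
    entry_id: str
    ion_chain: str
    ion_residue: int
    rmsd: float | None
    shared_features: int
    has_bidentate_acidic: bool
    has_serthr_adjacent: bool


def _shared_features(query: SiteFingerprint, fp: SiteFingerprint) -> int:
    """Feature-count similarity used when no geometric ceiling is requested:
    agreement on the two motif flags plus multiset overlap of ligand classes
    and residue types."""
    score = int(query.has_bidentate_acidic == fp.has_bidentate_acidic)
    score += int(query.has_serthr_adjacent == fp.has_serthr_adjacent)
    fp_classes = fp.class_multiset()
    for k, v in query.class_multiset().items():
        score += min(v, fp_classes.get(k, 0))
    qr, fr = list(query.residue_types), list(fp.residue_types)
    for r in qr:
        if r in fr:
            fr.remove(r)
            score += 1
    return score


def find_similar_sites(query: SiteFingerprint, census: list["NaSite"],
                       criteria: SearchCriteria | None = None) -> list[Match]:
    """Search a classified census for sites similar to a query fingerprint.

    Sites failing any required boolean criterion are excluded.  With an RMSD
    ceiling, sites whose composition is not comparable to the query are
    excluded and survivors are ranked by RMSD ascending; otherwise ranking is
    by shared-feature count descending.  Ties break on entry id, then ion
    identity, so the output is independent of census ordering.
    """
    criteria = criteria or SearchCriteria()
    matches: list[Match] = []
    for site in census:
        fp = fingerprint_from_site(site)
        if criteria.require_bidentate_acidic and not fp.has_bidentate_acidic:
            continue
        if criteria.require_serthr_adjacent and not fp.has_serthr_adjacent:
            continue
        rmsd = None
        if criteria.rmsd_max is not None:
            try:
                rmsd = superpose_sites(query, fp)
            except IncomparableSitesError:
                continue
            if rmsd > criteria.rmsd_max:
                continue
        matches.append(Match(
            entry_id=site.entry_id, ion_chain=site.chain,
            ion_residue=site.residue_number, rmsd=rmsd,
            shared_features=_shared_features(query, fp),
            has_bidentate_acidic=fp.has_bidentate_acidic,
            has_serthr_adjacent=fp.has_serthr_adjacent))
    if criteria.rmsd_max is not None:
        matches.sort(key=lambda m: (m.rmsd, m.entry_id, m.ion_chain,
                                    m.ion_residue))
    else:
        matches.sort(key=lambda m: (-m.shared_features, m.entry_id,
                                    m.ion_chain, m.ion_residue))
    return matches
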