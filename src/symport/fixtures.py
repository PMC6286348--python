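"""Synthetic Na+ coordination-site structures for exercising the census.

Builds idealized coordination polyhedra around a single Na+ ion and writes
them as standard PDB/mmCIF files.  Ligand residues are minimal
chemically-plausible stubs: the coordinating atom sits exactly at the
requested bond length from the ion (before jitter) and the remaining backbone
and side-chain atoms are placed radially outward so that only the designated
donor atoms fall inside a typical coordination cutoff.

The ``na3_motif`` geometry reproduces the composition of the putative Na3
site of hSGLT1: a bidentate aspartate (both carboxylate oxygens coordinate,
as D204 does), Thr and Ser side-chain oxygens at consecutive residue numbers
(T395/S396), and one main-chain carbonyl oxygen (from the S392 backbone) —
five donor atoms in all.

Positional jitter is isotropic Gaussian per ligand atom; the ion itself is
never jittered, so Na-donor distances stay directly interpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "LigandSpec",
    "SiteFixtureSpec",
    "GEOMETRIES",
    "make_site_fixture",
    "write_structure",
]

_SQ3 = 1.0 / math.sqrt(3.0)

#: unit vectors of each ideal polyhedron (na3_motif is handled separately)
GEOMETRY_VERTICES: dict[str, np.ndarray] = {
    "octahedral": np.array([
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
    ], dtype=float),
    "trigonal_bipyramidal": np.array([
        [1, 0, 0],
        [-0.5, math.sqrt(3) / 2, 0],
        [-0.5, -math.sqrt(3) / 2, 0],
        [0, 0, 1], [0, 0, -1],
    ], dtype=float),
    "square_pyramidal": np.array([
        [1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0], [0, 0, 1],
    ], dtype=float),
    "tetrahedral": np.array([
        [1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1],
    ], dtype=float) * _SQ3,
}

GEOMETRIES = tuple(GEOMETRY_VERTICES) + ("na3_motif",)


@dataclass(frozen=True)
class LigandSpec:
    """One coordinating ligand: residue name, donor atom, and contact kind."""

    residue: str
    atom: str
    kind: str  # 'side_chain' | 'main_chain' | 'water'

    def __post_init__(self):
        if self.kind not in ("side_chain", "main_chain", "water"):
            raise ValueError(f"unknown ligand kind {self.kind!r}")


_DEFAULT_COMPOSITIONS: dict[str, tuple[LigandSpec, ...]] = {
    "tetrahedral": (
        LigandSpec("ASP", "OD1", "side_chain"),
        LigandSpec("SER", "OG", "side_chain"),
        LigandSpec("GLY", "O", "main_chain"),
        LigandSpec("HOH", "O", "water"),
    ),
    "trigonal_bipyramidal": (
        LigandSpec("ASP", "OD1", "side_chain"),
        LigandSpec("SER", "OG", "side_chain"),
        LigandSpec("THR", "OG1", "side_chain"),
        LigandSpec("GLY", "O", "main_chain"),
        LigandSpec("HOH", "O", "water"),
    ),
    "square_pyramidal": (
        LigandSpec("ASP", "OD1", "side_chain"),
        LigandSpec("SER", "OG", "side_chain"),
        LigandSpec("THR", "OG1", "side_chain"),
        LigandSpec("GLY", "O", "main_chain"),
        LigandSpec("HOH", "O", "water"),
    ),
    "octahedral": (
        LigandSpec("ASP", "OD1", "side_chain"),
        LigandSpec("SER", "OG", "side_chain"),
        LigandSpec("THR", "OG1", "side_chain"),
        LigandSpec("GLY", "O", "main_chain"),
        LigandSpec("HOH", "O", "water"),
        LigandSpec("HOH", "O", "water"),
    ),
}


@dataclass
class SiteFixtureSpec:
    geometry: str = "octahedral"
    bond_length: float = 2.4
    jitter_sigma: float = 0.0
    composition: list[LigandSpec] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.geometry not in GEOMETRIES:
            raise ValueError(
                f"unknown geometry {self.geometry!r}; choose from {GEOMETRIES}")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")
        if self.geometry == "na3_motif":
            if self.composition is not None:
                raise ValueError("na3_motif composition is fixed")
        else:
            n = len(GEOMETRY_VERTICES[self.geometry])
            comp = self.composition
            if comp is not None and len(comp) != n:
                raise ValueError(
                    f"{self.geometry} has {n} vertices, composition lists "
                    f"{len(comp)} ligands")


def _perp(u: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to u."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    p = np.cross(u, ref)
    return p / np.linalg.norm(p)


# (atom_name, radial offset beyond the donor, perpendicular offset) per residue;
# offsets are rough bond-geometry values — only donor placement must be exact.
_SIDE_CHAIN_STUBS: dict[str, tuple[tuple[str, float, float], ...]] = {
    "SER": (("OG", 0.0, 0.0), ("CB", 1.3, 0.5), ("CA", 2.4, 0.9),
            ("N", 3.0, 2.1), ("C", 3.3, 0.2), ("O", 4.0, -0.6)),
    "THR": (("OG1", 0.0, 0.0), ("CB", 1.3, 0.5), ("CG2", 1.8, 1.7),
            ("CA", 2.4, 0.9), ("N", 3.0, 2.1), ("C", 3.3, 0.2),
            ("O", 4.0, -0.6)),
    "ASP": (("OD1", 0.0, 0.0), ("CG", 1.0, 0.75), ("OD2", 1.25, 1.95),
            ("CB", 2.3, 0.9), ("CA", 3.4, 1.3), ("N", 4.0, 2.5),
            ("C", 4.3, 0.6), ("O", 5.0, -0.2)),
    "GLU": (("OE1", 0.0, 0.0), ("CD", 1.0, 0.75), ("OE2", 1.25, 1.95),
            ("CG", 2.3, 0.9), ("CB", 3.4, 1.3), ("CA", 4.5, 1.7),
            ("N", 5.1, 2.9), ("C", 5.4, 1.0), ("O", 6.1, 0.2)),
    "ASN": (("OD1", 0.0, 0.0), ("CG", 1.0, 0.75), ("ND2", 1.25, 1.95),
            ("CB", 2.3, 0.9), ("CA", 3.4, 1.3), ("N", 4.0, 2.5),
            ("C", 4.3, 0.6), ("O", 5.0, -0.2)),
    "GLN": (("OE1", 0.0, 0.0), ("CD", 1.0, 0.75), ("NE2", 1.25, 1.95),
            ("CG", 2.3, 0.9), ("CB", 3.4, 1.3), ("CA", 4.5, 1.7),
            ("N", 5.1, 2.9), ("C", 5.4, 1.0), ("O", 6.1, 0.2)),
    "TYR": (("OH", 0.0, 0.0), ("CZ", 1.4, 0.0), ("CE1", 2.1, 1.2),
            ("CE2", 2.1, -1.2), ("CG", 4.2, 0.0), ("CB", 5.3, 0.5),
            ("CA", 6.4, 0.9), ("N", 7.0, 2.1), ("C", 7.3, 0.2),
            ("O", 8.0, -0.6)),
}

_MAIN_CHAIN_STUB: tuple[tuple[str, float, float], ...] = (
    ("O", 0.0, 0.0), ("C", 1.23, 0.0), ("CA", 2.1, 1.1),
    ("N", 2.8, 2.3), ("CB", 2.9, 0.1),
)

_ELEMENT_BY_INITIAL = {"O": "O", "N": "N", "C": "C"}


def _element_of(atom_name: str) -> gemmi.Element:
    return gemmi.Element(_ELEMENT_BY_INITIAL[atom_name[0]])


def _new_residue(name: str, number: int, het: bool) -> gemmi.Residue:
    res = gemmi.Residue()
    res.name = name
    res.seqid = gemmi.SeqId(number, " ")
    res.het_flag = "H" if het else "A"
    return res


def _add_atom(res: gemmi.Residue, name: str, pos: np.ndarray,
              element: gemmi.Element | None = None) -> None:
    atom = gemmi.Atom()
    atom.name = name
    atom.element = element or _element_of(name)
    atom.pos = gemmi.Position(*map(float, pos))
    atom.occ = 1.0
    atom.b_iso = 0.0
    res.add_atom(atom)


def _stub_residue(lig: LigandSpec, u: np.ndarray, d: float,
                  number: int) -> gemmi.Residue:
    """Build one ligand residue with its donor atom at d along u."""
    if lig.kind == "water":
        res = _new_residue("HOH", number, het=True)
        _add_atom(res, "O", d * u)
        return res
    p = _perp(u)
    if lig.kind == "main_chain":
        template = _MAIN_CHAIN_STUB
        if lig.residue == "GLY":  # glycine has no CB
            template = template[:-1]
        res = _new_residue(lig.residue, number, het=False)
        for name, radial, perp in template:
            _add_atom(res, name, (d + radial) * u + perp * p)
        return res
    # side chain
    template = _SIDE_CHAIN_STUBS.get(lig.residue)
    if template is None or template[0][0] != lig.atom:
        # minimal generic fallback: donor + backbone
        template = ((lig.atom, 0.0, 0.0), ("CB", 1.4, 0.5), ("CA", 2.5, 0.9),
                    ("N", 3.1, 2.1), ("C", 3.4, 0.2), ("O", 4.1, -0.6))
    res = _new_residue(lig.residue, number, het=False)
    for name, radial, perp in template:
        _add_atom(res, name, (d + radial) * u + perp * p)
    return res


def _bidentate_asp(number: int, d: float) -> gemmi.Residue:
    """Asp whose OD1 and OD2 both sit at d from the origin, straddling +x."""
    half_oo = 1.1  # half the carboxylate O...O separation (Angstrom)
    if d <= half_oo:
        raise ValueError("bond_length too short for a bidentate carboxylate")
    sin_t = half_oo / d
    cos_t = math.sqrt(1.0 - sin_t**2)
    res = _new_residue("ASP", number, het=False)
    _add_atom(res, "OD1", np.array([d * cos_t, half_oo, 0.0]))
    _add_atom(res, "OD2", np.array([d * cos_t, -half_oo, 0.0]))
    cg_x = d * cos_t + math.sqrt(max(1.25**2 - half_oo**2, 0.0))
    _add_atom(res, "CG", np.array([cg_x, 0.0, 0.0]))
    _add_atom(res, "CB", np.array([cg_x + 1.5, 0.0, 0.3]))
    _add_atom(res, "CA", np.array([cg_x + 2.7, 0.0, 0.8]))
    _add_atom(res, "N", np.array([cg_x + 3.3, 0.0, 2.0]))
    _add_atom(res, "C", np.array([cg_x + 3.6, 0.0, -0.5]))
    _add_atom(res, "O", np.array([cg_x + 4.3, 0.0, -1.2]))
    return res


def _na3_residues(d: float) -> list[gemmi.Residue]:
    """Five-donor Na3-like site: bidentate Asp204, Thr395 OG1, Ser396 OG,
    and the Ser392 backbone carbonyl."""
    sq3 = math.sqrt(3) / 2
    residues = [
        _bidentate_asp(204, d),
        _stub_residue(LigandSpec("SER", "O", "main_chain"),
                      np.array([0.0, 0.0, 1.0]), d, 392),
        _stub_residue(LigandSpec("THR", "OG1", "side_chain"),
                      np.array([-0.5, sq3, 0.0]), d, 395),
        _stub_residue(LigandSpec("SER", "OG", "side_chain"),
                      np.array([-0.5, -sq3, 0.0]), d, 396),
    ]
    return residues


def make_site_fixture(spec: SiteFixtureSpec) -> gemmi.Structure:
    """Build a one-ion coordination-site structure from a fixture spec.

    With ``jitter_sigma == 0`` every designated donor atom lies exactly at
    ``bond_length`` from the ion, which sits at the origin.
    """
    if spec.geometry == "na3_motif":
        residues = _na3_residues(spec.bond_length)
    else:
        vertices = GEOMETRY_VERTICES[spec.geometry]
        comp = list(spec.composition
                    if spec.composition is not None
                    else _DEFAULT_COMPOSITIONS[spec.geometry])
        residues = []
        prot_num, wat_num = 101, 301
        for lig, u in zip(comp, vertices):
            if lig.kind == "water":
                residues.append(_stub_residue(lig, u, spec.bond_length, wat_num))
                wat_num += 1
            else:
                residues.append(_stub_residue(lig, u, spec.bond_length, prot_num))
                prot_num += 1

    rng = np.random.default_rng(spec.seed)
    if spec.jitter_sigma > 0:
        for res in residues:
            for atom in res:
                shift = rng.normal(0.0, spec.jitter_sigma, 3)
                atom.pos = gemmi.Position(atom.pos.x + shift[0],
                                          atom.pos.y + shift[1],
                                          atom.pos.z + shift[2])

    na_res = _new_residue("NA", 501, het=True)
    _add_atom(na_res, "NA", np.zeros(3), element=gemmi.Element("NA"))

    st = gemmi.Structure()
    st.name = spec.geometry
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for res in sorted(residues, key=lambda r: r.seqid.num):
        chain.add_residue(res)
    chain.add_residue(na_res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: gemmi.Structure, path: str,
                    dialect: str | None = None) -> None:
    """Write a structure as PDB or mmCIF (inferred from extension if not given)."""
    path = str(path)
    if dialect is None:
        dialect = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    if dialect == "pdb":
        structure.write_pdb(path)
    elif dialect == "mmcif":
        structure.make_mmcif_document().write_file(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
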