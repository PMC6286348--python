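"""Site fingerprints, proper-rotation superposition, motif detection, search."""

import numpy as np
import pytest

from symport import (IncomparableSitesError, SearchCriteria, SiteFixtureSpec,
                     classify_contacts, detect_na_sites, find_similar_sites,
                     fingerprint_from_site, has_serthr_adjacent,
                     make_site_fixture, superpose_sites)
from symport.similarity import SiteFingerprint


def _rotation_matrix(seed):
    """Random proper rotation via QR decomposition."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _chiral_fingerprint(entry="chiral"):
    """Five donors at distinct radii forming a chirally unambiguous cloud."""
    coords = np.array([
        [2.0, 0.0, 0.0],
        [0.0, 2.2, 0.0],
        [0.0, 0.0, 2.4],
        [-1.8, -1.1, 0.9],
        [1.2, -1.6, -1.4],
    ])
    return SiteFingerprint(entry_id=entry, ligand_classes=("side_chain",) * 5,
                           residue_types=("SER",) * 5,
                           has_bidentate_acidic=False,
                           has_serthr_adjacent=False, coords=coords)


def _transformed(fp, rot):
    return SiteFingerprint(entry_id=fp.entry_id + "_rot",
                           ligand_classes=fp.ligand_classes,
                           residue_types=fp.residue_types,
                           has_bidentate_acidic=fp.has_bidentate_acidic,
                           has_serthr_adjacent=fp.has_serthr_adjacent,
                           coords=fp.coords @ rot.T)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def test_identical_fingerprints_have_zero_rmsd(na3_site):
    fp = fingerprint_from_site(na3_site)
    assert superpose_sites(fp, fp) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_rigid_motion_is_recovered(seed):
    """A rotated copy superposes back to RMSD < 1e-6."""
    fp = _chiral_fingerprint()
    rotated = _transformed(fp, _rotation_matrix(seed))
    assert superpose_sites(fp, rotated) < 1e-6


def test_rmsd_is_symmetric():
    fp = _chiral_fingerprint()
    other = _transformed(fp, _rotation_matrix(9))
    other.coords = other.coords + 0.3  # no longer an exact copy
    assert superpose_sites(fp, other) == pytest.approx(
        superpose_sites(other, fp), abs=1e-9)


def test_mirror_image_of_chiral_site_has_positive_rmsd():
    """Proper rotations cannot superpose a chiral cloud onto its mirror.

    Oracle: brute force over many sampled proper rotations (and all donor
    correspondences implicitly, since superpose_sites is exhaustive) never
    reaches zero.
    """
    fp = _chiral_fingerprint()
    mirrored = SiteFingerprint(
        entry_id="mirror", ligand_classes=fp.ligand_classes,
        residue_types=fp.residue_types, has_bidentate_acidic=False,
        has_serthr_adjacent=False, coords=fp.coords * np.array([1, 1, -1]))
    rmsd = superpose_sites(fp, mirrored)
    assert rmsd > 0.1

    # rotation-grid oracle with the identity correspondence
    rng = np.random.default_rng(0)
    best = np.inf
    for _ in range(500):
        rot = _rotation_matrix(rng.integers(2**31))
        diff = mirrored.coords @ rot.T - fp.coords
        best = min(best, float(np.sqrt(np.mean(np.sum(diff**2, axis=1)))))
    assert best > 0.1


def test_incompatible_class_multisets_raise(na3_site, octahedral_site):
    a = fingerprint_from_site(na3_site)       # 4 side-chain + 1 main-chain
    b = fingerprint_from_site(octahedral_site)  # includes waters
    with pytest.raises(IncomparableSitesError, match="not comparable"):
        superpose_sites(a, b)


def test_fingerprint_invariant_to_rigid_motion_of_structure():
    """Jitter-free fixtures built at different seeds produce equal coordinates,
    and the fingerprint depends only on ion-relative positions."""
    st = make_site_fixture(SiteFixtureSpec(geometry="na3_motif"))
    (site,) = detect_na_sites(st, entry_id="x")
    fp = fingerprint_from_site(classify_contacts(site, st))
    assert fp.coordination_number == len(fp.coords) == 5


# ---------------------------------------------------------------------------
# Ser/Thr adjacency
# ---------------------------------------------------------------------------

def test_na3_fixture_has_adjacent_serthr(na3_site):
    assert has_serthr_adjacent(na3_site)


def test_gap_of_two_is_not_adjacent(site_factory):
    site = site_factory("gap", [("SER", "OG", True), ("THR", "OG1", True)])
    # factory numbers residues 10 apart
    assert not has_serthr_adjacent(site)


def test_single_hydroxyl_not_adjacent(site_factory):
    site = site_factory("one", [("THR", "OG1", True), ("ASP", "OD1", True)])
    assert not has_serthr_adjacent(site)


def test_adjacent_pair_detected_when_constructed(site_factory):
    site = site_factory("adj", [("THR", "OG1", True), ("SER", "OG", True)])
    site.contacts[1].residue_number = site.contacts[0].residue_number + 1
    assert has_serthr_adjacent(site)


# ---------------------------------------------------------------------------
# census search
# ---------------------------------------------------------------------------

def _classified(structure, entry):
    (site,) = detect_na_sites(structure, entry_id=entry)
    return classify_contacts(site, structure)


def test_query_retrieves_only_the_matching_motif():
    """Na3-style query against {na3 copy, octahedral} with both flags required
    returns exactly the na3 copy."""
    na3 = _classified(make_site_fixture(SiteFixtureSpec("na3_motif")), "q")
    copy = _classified(make_site_fixture(SiteFixtureSpec("na3_motif")), "copy")
    octa = _classified(make_site_fixture(SiteFixtureSpec("octahedral")), "octa")
    criteria = SearchCriteria(require_bidentate_acidic=True,
                              require_serthr_adjacent=True)
    matches = find_similar_sites(fingerprint_from_site(na3), [octa, copy],
                                 criteria)
    assert [m.entry_id for m in matches] == ["copy"]


def test_rmsd_zero_ceiling_matches_identical_site():
    na3 = _classified(make_site_fixture(SiteFixtureSpec("na3_motif")), "q")
    copy = _classified(make_site_fixture(SiteFixtureSpec("na3_motif")), "copy")
    matches = find_similar_sites(fingerprint_from_site(na3), [copy],
                                 SearchCriteria(rmsd_max=0.0))
    assert len(matches) == 1
    assert matches[0].rmsd == pytest.approx(0.0, abs=1e-9)


def test_empty_census_returns_empty_list(na3_site):
    assert find_similar_sites(fingerprint_from_site(na3_site), []) == []


def test_search_invariant_under_census_permutation(na3_site):
    sites = []
    for k, geom in enumerate(["na3_motif", "octahedral", "square_pyramidal"]):
        sites.append(_classified(make_site_fixture(SiteFixtureSpec(geom)),
                                 f"e{k}"))
    fp = fingerprint_from_site(na3_site)
    a = find_similar_sites(fp, sites)
    b = find_similar_sites(fp, list(reversed(sites)))
    assert [m.entry_id for m in a] == [m.entry_id for m in b]


def test_relaxing_criteria_never_removes_matches(na3_site):
    sites = [
        _classified(make_site_fixture(SiteFixtureSpec("na3_motif")), "a"),
        _classified(make_site_fixture(SiteFixtureSpec("octahedral")), "b"),
        _classified(make_site_fixture(SiteFixtureSpec("tetrahedral")), "c"),
    ]
    fp = fingerprint_from_site(na3_site)
    strict = find_similar_sites(fp, sites, SearchCriteria(
        require_bidentate_acidic=True, require_serthr_adjacent=True))
    relaxed_sets = [
        find_similar_sites(fp, sites, SearchCriteria(require_bidentate_acidic=True)),
        find_similar_sites(fp, sites, SearchCriteria(require_serthr_adjacent=True)),
        find_similar_sites(fp, sites, SearchCriteria()),
    ]
    strict_ids = {m.entry_id for m in strict}
    for relaxed in relaxed_sets:
        assert strict_ids <= {m.entry_id for m in relaxed}
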