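import numpy as np
import pytest

from symport import (SiteFixtureSpec, classify_contacts, detect_na_sites,
                     make_site_fixture)
from symport.census import Contact, NaSite


@pytest.fixture
def na3_site():
    """Classified Na3-like site (bidentate Asp204, Thr395/Ser396, backbone O)."""
    st = make_site_fixture(SiteFixtureSpec(geometry="na3_motif"))
    (site,) = detect_na_sites(st, entry_id="na3")
    return classify_contacts(site, st)


@pytest.fixture
def octahedral_site():
    st = make_site_fixture(SiteFixtureSpec(geometry="octahedral"))
    (site,) = detect_na_sites(st, entry_id="octa")
    return classify_contacts(site, st)


# directions of a square pyramid, used to give hand-built sites coordinates
_PYRAMID = np.array([
    [1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0], [0, 0, 1]], dtype=float)


@pytest.fixture
def site_factory():
    """Factory building a classified NaSite directly from ligand tuples.

    Each ligand is (residue_name, atom_name, is_protein); donor atoms are
    placed 2.4 A from the ion on square-pyramid vertices (cycled), residues
    numbered from 100 in steps of 10 on chain A so that no pair is at
    consecutive author numbers unless built that way on purpose.
    """

    def build(entry_id, ligands, distance=2.4):
        site = NaSite(entry_id=entry_id, chain="A", residue_number=501)
        num = 100
        prev = None
        for k, (rname, aname, is_protein) in enumerate(ligands):
            # both oxygens of one bidentate residue share a residue number
            if prev and prev[0] == rname and prev[1] != aname \
                    and {prev[1], aname} in ({"OD1", "OD2"}, {"OE1", "OE2"}):
                res_num = num - 10
            else:
                res_num = num
                num += 10
            u = _PYRAMID[k % len(_PYRAMID)]
            site.contacts.append(Contact(
                atom=aname, residue_name=rname, residue_number=res_num,
                icode="", chain="A", distance=distance,
                rel_pos=distance * u + 0.01 * k, is_protein=is_protein))
            prev = (rname, aname)
        return classify_contacts(site)

    return build
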