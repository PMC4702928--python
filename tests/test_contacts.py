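"""Contact detection: unit behaviour plus a naive all-pairs oracle."""

import numpy as np
import pytest

from dnabind.contacts import (detect_hydrogen_bonds,
                              detect_hydrophobic_contacts,
                              hydrogen_bond_power, hydrophobic_clusters,
                              line_of_sight, nonpolar_atoms)
from dnabind.params import DEFAULT, VDW_RADII, VDW_DEFAULT
from dnabind.structure import (AtomRef, Structure, domain_residues,
                               is_amino_acid, nucleotide_base)

from conftest import random_rotation


def make_structure(rows):
    """rows: (chain, res_seq, res_name, atom_name, element, xyz)."""
    atoms = [AtomRef(i, ch, rs, "", rn, an, el, False)
             for i, (ch, rs, rn, an, el, _) in enumerate(rows)]
    coords = np.array([r[5] for r in rows], dtype=float)
    return Structure("t", "1", atoms, coords)


# --------------------------------------------------------------------------
# independent naive implementations (the oracle)
# --------------------------------------------------------------------------

def oracle_nonpolar(structure):
    out = set()
    for a in structure.atoms:
        if nucleotide_base(a.res_name) is not None:
            if a.element == "C":
                out.add(a.index)
        elif is_amino_acid(a.res_name):
            if a.element in ("C", "S"):
                if all(structure.atoms[j].element not in ("O", "N")
                       for j in structure.bonds[a.index]):
                    out.add(a.index)
    return out


def oracle_line_of_sight(structure, i, j):
    a, b = structure.coords[i], structure.coords[j]
    u = b - a
    length = np.linalg.norm(u)
    u = u / length
    for k in range(len(structure)):
        if k in (i, j) or structure.atoms[k].element == "H":
            continue
        p = structure.coords[k]
        t = float((p - a) @ u)
        if not (1e-9 < t < length - 1e-9):
            continue
        perp = np.linalg.norm(p - (a + t * u))
        if perp < VDW_RADII.get(structure.atoms[k].element, VDW_DEFAULT):
            return False
    return True


def oracle_clusters(structure):
    npset = sorted(oracle_nonpolar(structure))
    parent = {i: i for i in npset}

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for ii, i in enumerate(npset):
        for j in npset[ii + 1:]:
            d = np.linalg.norm(structure.coords[i] - structure.coords[j])
            if d < DEFAULT.cluster_linkage_dist and \
                    oracle_line_of_sight(structure, i, j):
                parent[find(i)] = find(j)
    comps = {}
    for i in npset:
        comps.setdefault(find(i), set()).add(i)
    keep = [c for c in comps.values() if len(c) >= DEFAULT.cluster_min_size]
    label = {}
    for ci, c in enumerate(keep):
        for i in c:
            label[i] = ci
    return label


def oracle_contacts(structure, protein_atoms, dna_atoms):
    """All-pairs/all-blockers hydrogen-bond + hydrophobic detection."""
    hbonds = set()
    for i in protein_atoms:
        if structure.atoms[i].element not in ("N", "O"):
            continue
        for j in dna_atoms:
            if structure.atoms[j].element not in ("N", "O"):
                continue
            d = np.linalg.norm(structure.coords[i] - structure.coords[j])
            if d < DEFAULT.hbond_max_dist and \
                    hydrogen_bond_power(structure, i, j) > \
                    DEFAULT.hbond_power_min:
                hbonds.add((i, j))
    label = oracle_clusters(structure)
    phobic = set()
    for i in protein_atoms:
        if i not in label:
            continue
        for j in dna_atoms:
            if j not in label or label[i] != label[j]:
                continue
            d = np.linalg.norm(structure.coords[i] - structure.coords[j])
            if d < DEFAULT.hydrophobic_max_dist and \
                    oracle_line_of_sight(structure, i, j):
                phobic.add((i, j))
    return hbonds, phobic


def pipeline_contacts(structure, protein_atoms, dna_atoms):
    npset = nonpolar_atoms(structure)
    _, label = hydrophobic_clusters(structure, npset)
    hb = {(h.protein_atom, h.dna_atom)
          for h in detect_hydrogen_bonds(structure, protein_atoms, dna_atoms)}
    ph = {(h.protein_atom, h.dna_atom)
          for h in detect_hydrophobic_contacts(structure, protein_atoms,
                                               dna_atoms, label)}
    return hb, ph


def split_atoms(structure):
    prot = [a.index for a in structure.atoms if is_amino_acid(a.res_name)]
    dna = [a.index for a in structure.atoms
           if nucleotide_base(a.res_name) is not None]
    return prot, dna


# --------------------------------------------------------------------------
# unit behaviour
# --------------------------------------------------------------------------

def test_nonpolar_rules(helix_mj_fixture):
    st, _, _ = helix_mj_fixture
    npset = nonpolar_atoms(st)
    for a in st.atoms:
        if a.res_name == "ALA" and a.atom_name == "C":
            assert a.index not in npset        # carbonyl C bonded to O
        if a.res_name == "ALA" and a.atom_name == "CB":
            assert a.index in npset
        if a.atom_name == "C3'":
            assert a.index in npset            # every DNA carbon counts


def test_met_sd_is_nonpolar():
    rows = [("A", 1, "MET", n, e, c) for n, e, c in [
        ("N", "N", (0, 0, 0)), ("CA", "C", (1.46, 0, 0)),
        ("C", "C", (2.0, 1.4, 0)), ("O", "O", (1.3, 2.4, 0)),
        ("CB", "C", (2.0, -0.8, 1.2)), ("CG", "C", (3.5, -0.9, 1.3)),
        ("SD", "S", (4.2, -2.4, 1.9)), ("CE", "C", (6.0, -2.1, 2.0))]]
    st = make_structure(rows)
    npset = nonpolar_atoms(st)
    names = {st.atoms[i].atom_name for i in npset}
    assert "SD" in names and "CE" in names and "CB" in names
    assert "CA" not in names and "C" not in names


def test_power_distance_ramp():
    # two hydroxyl-like oxygens facing each other head-on
    def pair(d):
        rows = [("A", 1, "SER", "CB", "C", (-1.417, 0, 0)),
                ("A", 1, "SER", "OG", "O", (0, 0, 0)),
                ("D", 1, "DT", "O4", "O", (d, 0, 0)),
                ("D", 1, "DT", "C4", "C", (d + 1.23, 0, 0))]
        return make_structure(rows)
    assert hydrogen_bond_power(pair(2.9), 1, 2) == pytest.approx(1.0)
    assert hydrogen_bond_power(pair(3.35), 1, 2) == pytest.approx(0.5)
    assert hydrogen_bond_power(pair(3.8), 1, 2) == 0.0


def test_power_rejects_non_polar_atoms():
    st = make_structure([("A", 1, "ALA", "CB", "C", (0, 0, 0)),
                         ("D", 1, "DT", "O4", "O", (3, 0, 0))])
    with pytest.raises(ValueError):
        hydrogen_bond_power(st, 0, 1)


def test_distance_cutoff_is_strict():
    rows = [("A", 1, "SER", "CB", "C", (-1.417, 0, 0)),
            ("A", 1, "SER", "OG", "O", (0, 0, 0)),
            ("D", 1, "DT", "O4", "O", (3.7, 0, 0)),
            ("D", 1, "DT", "C4", "C", (4.93, 0, 0))]
    st = make_structure(rows)
    assert detect_hydrogen_bonds(st, [0, 1], [2, 3]) == []


def test_designed_hbond_detected(helix_mj_fixture):
    st, dom, truth = helix_mj_fixture
    prot, dna = split_atoms(st)
    hb = detect_hydrogen_bonds(st, prot, dna)
    assert len(hb) >= 1
    assert all(h.distance < DEFAULT.hbond_max_dist and
               h.power > DEFAULT.hbond_power_min for h in hb)


class TestLineOfSight:
    def base(self, extra):
        rows = [("A", 1, "ALA", "CB", "C", (0.0, 0, 0)),
                ("D", 1, "DT", "C7", "C", (5.0, 0, 0))] + extra
        return make_structure(rows)

    def test_empty_surroundings_clear(self):
        st = self.base([])
        assert line_of_sight(st, 0, 1)

    def test_midpoint_blocker_blocks(self):
        st = self.base([("X", 9, "LIG", "C1", "C", (2.5, 0, 0))])
        assert not line_of_sight(st, 0, 1)

    def test_off_axis_blocker_clears(self):
        st = self.base([("X", 9, "LIG", "C1", "C", (2.5, 2.0, 0))])
        assert line_of_sight(st, 0, 1)   # clearance 2.0 > C radius 1.7

    def test_matches_oracle_on_random_points(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            extra = [("X", 9, "LIG", f"C{k}", "C",
                      tuple(rng.uniform(-2, 7, 3))) for k in range(1, 6)]
            st = self.base(extra)
            assert line_of_sight(st, 0, 1) == oracle_line_of_sight(st, 0, 1)


class TestClusters:
    def test_isolated_atom_below_min_size(self):
        st = make_structure([("A", 1, "ALA", "CB", "C", (0, 0, 0))])
        clusters, label = hydrophobic_clusters(st)
        assert clusters == [] and label == {}

    def test_two_separated_patches(self):
        rows = []
        for base_x, chain in ((0.0, "A"), (20.0, "B")):
            for k in range(5):
                rows.append((chain, k + 1, "ALA", "CB", "C",
                             (base_x + 1.2 * k, 0.3 * (k % 2), 0)))
        st = make_structure(rows)
        clusters, _ = hydrophobic_clusters(st)
        assert len(clusters) == 2
        assert all(c.size == 5 for c in clusters)

    def test_leucine_thymine_methyl_shared_cluster(self, loop_phobic_fixture):
        st, _, _ = loop_phobic_fixture
        clusters, label = hydrophobic_clusters(st)
        # the designed pair shares a cluster: MET/LEU side chain + methyl
        sides = {st.atoms[i].res_name for c in clusters
                 for i in c.member_atoms}
        assert any(
            {"DT"} & {st.atoms[i].res_name for i in c.member_atoms} and
            {"MET", "LEU"} & {st.atoms[i].res_name for i in c.member_atoms}
            for c in clusters)


def test_hydrophobic_distance_strict(loop_phobic_fixture):
    st, _, _ = loop_phobic_fixture
    prot, dna = split_atoms(st)
    npset = nonpolar_atoms(st)
    _, label = hydrophobic_clusters(st, npset)
    for h in detect_hydrophobic_contacts(st, prot, dna, label):
        assert h.distance < DEFAULT.hydrophobic_max_dist


def test_different_clusters_no_contact():
    # two nonpolar groups near in distance but separated by a polar wall
    rows = []
    for k in range(5):
        rows.append(("A", k + 1, "ALA", "CB", "C", (1.2 * k, 0, 0)))
    for k in range(5):
        rows.append(("D", k + 1, "DA", "C2'", "C", (1.2 * k, 5.0, 0)))
    # wall of oxygens between the rows blocks every line of sight
    for k in range(9):
        rows.append(("W", k + 1, "DA", "O4'", "O", (0.6 * k, 2.5, 0)))
    st = make_structure(rows)
    npset = nonpolar_atoms(st)
    _, label = hydrophobic_clusters(st, npset)
    prot = [a.index for a in st.atoms if a.chain_id == "A"]
    dna = [a.index for a in st.atoms if a.chain_id == "D"]
    assert detect_hydrophobic_contacts(st, prot, dna, label) == []


def test_blocking_atom_removes_contact(loop_phobic_fixture):
    st, dom, truth = loop_phobic_fixture
    prot, dna = split_atoms(st)
    hb0, ph0 = pipeline_contacts(st, prot, dna)
    assert ph0, "fixture should have a hydrophobic contact"
    # block the first hydrophobic contact at its midpoint with a free C
    i, j = sorted(ph0)[0]
    mid = 0.5 * (st.coords[i] + st.coords[j])
    atoms = list(st.atoms) + [AtomRef(len(st), "Z", 1, "", "LIG", "C1",
                                      "C", True)]
    coords = np.vstack([st.coords, mid])
    st2 = Structure(st.id, st.assembly_id, atoms, coords)
    hb1, ph1 = pipeline_contacts(st2, prot, dna)
    assert hb1 == hb0                    # hydrogen bonds untouched
    assert (i, j) not in ph1
    assert ph1 <= ph0


def test_oracle_equivalence_small_fixture(helix_mj_fixture):
    st, _, _ = helix_mj_fixture
    prot, dna = split_atoms(st)
    assert pipeline_contacts(st, prot, dna) == oracle_contacts(st, prot, dna)


def test_contacts_rigid_invariance(helix_mj_fixture):
    st, _, _ = helix_mj_fixture
    prot, dna = split_atoms(st)
    base = pipeline_contacts(st, prot, dna)
    rng = np.random.default_rng(4)
    moved = st.transformed(random_rotation(rng), np.array([-8.0, 3.0, 12.0]))
    assert pipeline_contacts(moved, prot, dna) == base


def test_no_water_contacts(tmp_path, helix_mj_fixture):
    from dnabind.structure import load_structure, write_pdb
    st, _, _ = helix_mj_fixture
    p = tmp_path / "w.pdb"
    write_pdb(st, p)
    # append a water next to the designed contact
    lines = p.read_text().splitlines()
    lines.insert(-1, "HETATM 9999  O   HOH W   1      "
                 f"{st.coords[0][0]:8.3f}{st.coords[0][1]:8.3f}"
                 f"{st.coords[0][2]:8.3f}  1.00  0.00           O")
    p.write_text("\n".join(lines) + "\n")
    st2 = load_structure(p)
    assert not any(a.res_name == "HOH" for a in st2.atoms)
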