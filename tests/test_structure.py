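import numpy as np
import pytest

from dnabind.fixtures import build_ideal_bdna
from dnabind.structure import (DomainTableError, Structure, covalent_neighbors,
                               load_domain_definitions, load_structure,
                               write_pdb)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.152  -4.965  1.00  0.00           C
ATOM      4  O   ALA A   1      13.560   7.406  -5.807  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.247   4.676  -4.940  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1      1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   SER A   1      2.000   1.420   0.000  1.00  0.00           C
ATOM      4  O   SER A   1      1.300   2.430   0.000  1.00  0.00           O
ATOM      5  CB ASER A   1      2.000  -0.760   1.220  0.60  0.00           C
ATOM      6  CB BSER A   1      2.000  -0.780   1.250  0.40  0.00           C
ATOM      7  OG ASER A   1      1.500  -2.090   1.300  0.60  0.00           O
ATOM      8  OG BSER A   1      1.480  -2.110   1.330  0.40  0.00           O
END
"""


def test_minimal_pdb_atom_count(tmp_path):
    p = tmp_path / "ala.pdb"
    p.write_text(MINIMAL_PDB)
    st = load_structure(p)
    assert len(st) == 5
    assert {a.atom_name for a in st.atoms} == {"N", "CA", "C", "O", "CB"}


def test_duplex_file_round_trip(tmp_path, ideal_12mer):
    p = tmp_path / "dna.pdb"
    write_pdb(ideal_12mer, p)
    st = load_structure(p)
    assert len(st) == len(ideal_12mer)
    assert sorted({a.chain_id for a in st.atoms}) == ["D", "E"]
    # 12 nucleotides per strand, as generated
    assert len(st.chain_residues("D")) == 12
    assert len(st.chain_residues("E")) == 12
    assert np.abs(st.coords - ideal_12mer.coords).max() < 1e-3


def test_altloc_highest_occupancy_kept(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(ALTLOC_PDB)
    st = load_structure(p)
    names = [a.atom_name for a in st.atoms]
    assert names.count("CB") == 1
    cb = st.coords[names.index("CB")]
    assert np.allclose(cb, [2.000, -0.760, 1.220], atol=1e-3)  # occ 0.6 wins


def test_unknown_assembly_raises(tmp_path):
    p = tmp_path / "ala.pdb"
    p.write_text(MINIMAL_PDB)
    with pytest.raises(KeyError):
        load_structure(p, assembly_id="5")


def test_serine_cb_neighbors(tmp_path):
    p = tmp_path / "ser.pdb"
    p.write_text(ALTLOC_PDB)
    st = load_structure(p)
    by_name = {a.atom_name: a.index for a in st.atoms}
    nb = {st.atoms[i].atom_name for i in st.bonds[by_name["CB"]]}
    assert nb == {"CA", "OG"}


def test_phosphodiester_link(ideal_12mer):
    st = ideal_12mer
    keys = st.chain_residues("D")
    for prev, cur in zip(keys, keys[1:]):
        o3 = st.find_atom(prev, "O3'")
        p = st.find_atom(cur, "P")
        assert st.bonded(o3, p)


def test_unknown_residue_distance_rule():
    from dnabind.structure import AtomRef
    atoms = [AtomRef(0, "X", 1, "", "LIG", "C1", "C", True),
             AtomRef(1, "X", 1, "", "LIG", "C2", "C", True),
             AtomRef(2, "X", 1, "", "LIG", "C3", "C", True)]
    coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [4.0, 0, 0]])
    st = Structure("t", "1", atoms, coords)
    bonds = covalent_neighbors(st)
    assert bonds[0] == {1}          # 1.5 A -> bonded
    assert bonds[2] == set()        # 2.5 A from C2 -> not bonded


def test_bond_relation_symmetric_irreflexive(ideal_12mer):
    bonds = ideal_12mer.bonds
    for i, nb in enumerate(bonds):
        assert i not in nb
        for j in nb:
            assert i in bonds[j]


class TestDomainTable:
    def test_parse_row(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text("1BDT\tA\tA\t1\t53\td1bdta_\ta.43.1.1\n")
        (d,) = load_domain_definitions(f)
        assert (d.structure_id, d.chain_id, d.start, d.end) == \
            ("1BDT", "A", 1, 53)
        assert d.family_id == "a.43.1.1"

    def test_range_form(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text("1BDT A 1-53 d1bdta_ a.43.1.1\n")
        (d,) = load_domain_definitions(f)
        assert (d.start, d.end, d.assembly_id) == (1, 53, "1")

    def test_empty_file(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text("")
        assert load_domain_definitions(f) == []

    def test_inconsistent_family_rejected(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text("1AAA\t1\tA\t1\t50\tdomX\ta.1.1.1\n"
                     "1BBB\t1\tB\t1\t50\tdomX\tb.2.2.2\n")
        with pytest.raises(DomainTableError, match="famil"):
            load_domain_definitions(f)

    def test_duplicate_row_rejected(self, tmp_path):
        f = tmp_path / "d.tsv"
        row = "1AAA\t1\tA\t1\t50\tdomX\ta.1.1.1\n"
        f.write_text(row + row)
        with pytest.raises(DomainTableError, match="duplicate"):
            load_domain_definitions(f)

    def test_unknown_chain_rejected(self, tmp_path, ideal_12mer):
        f = tmp_path / "d.tsv"
        f.write_text("fixture\t1\tZ\t1\t10\tdomX\ta.1.1.1\n")
        with pytest.raises(DomainTableError, match="chain"):
            load_domain_definitions(f, {"fixture": ideal_12mer})

    def test_empty_range_rejected(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text("1AAA\t1\tA\t50\t10\tdomX\ta.1.1.1\n")
        with pytest.raises(DomainTableError):
            load_domain_definitions(f)
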