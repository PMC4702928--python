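"""Atomic data model: structures, covalent connectivity, domain definitions.

Structures are read with gemmi from PDB or mmCIF files.  The analysis unit
is a biological assembly; by default the first assembly defined in the file
is expanded, falling back to the asymmetric unit when none is defined.
Waters are always removed (water-mediated contacts are outside the contact
definitions), only the first model of multi-model entries is used, and for
alternate conformations only the highest-occupancy conformer is kept.

Covalent bonds come from per-residue chemical templates for the standard
amino acids and nucleotides plus inter-residue peptide / phosphodiester /
disulfide links; atoms of unknown residues are bonded by a 2.0 A distance
rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .params import Params, DEFAULT

log = logging.getLogger("dnabind")

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: modified residues mapped to their standard parent (editable)
MODIFIED_PARENT = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR", "MLY": "LYS",
    "CSO": "CYS", "HYP": "PRO",
    "5CM": "DC", "5MC": "DC", "6MA": "DA", "6OG": "DG", "8OG": "DG",
    "BRU": "DT", "5IU": "DT", "UMP": "DU",
}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: nucleotide residue-name aliases -> one-letter base
NUCLEOTIDE_ALIASES = {
    "DA": "A", "DT": "T", "DG": "G", "DC": "C", "DU": "U",
    "ADE": "A", "THY": "T", "GUA": "G", "CYT": "C", "URA": "U",
    "A": "A", "T": "T", "G": "G", "C": "C", "U": "U",
    "DA3": "A", "DT3": "T", "DG3": "G", "DC3": "C",
    "DA5": "A", "DT5": "T", "DG5": "G", "DC5": "C",
}


def parent_residue_name(name: str) -> str:
    """Resolve modified-residue aliases to the standard parent name."""
    name = name.strip().upper()
    return MODIFIED_PARENT.get(name, name)


def is_amino_acid(res_name: str) -> bool:
    return parent_residue_name(res_name) in AMINO_ACIDS


def nucleotide_base(res_name: str) -> Optional[str]:
    """One-letter base code for (possibly modified) nucleotides, else None."""
    return NUCLEOTIDE_ALIASES.get(parent_residue_name(res_name))


# --------------------------------------------------------------------------
# atoms and structures
# --------------------------------------------------------------------------

ResidueKey = Tuple[str, int, str]  # (chain_id, residue_number, insertion code)


@dataclass(frozen=True)
class AtomRef:
    """One atom of a parsed model (coordinates live in Structure.coords)."""

    index: int
    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    is_hetero: bool

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.icode)


class Structure:
    """Atomic model of one biological assembly with covalent connectivity."""

    def __init__(self, entry_id: str, assembly_id: str,
                 atoms: Sequence[AtomRef], coords: np.ndarray):
        if len(atoms) != len(coords):
            raise ValueError("atoms and coords length mismatch")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.id = entry_id
        self.assembly_id = assembly_id
        self.atoms: List[AtomRef] = list(atoms)
        self.coords = np.asarray(coords, dtype=float)
        self._bonds: Optional[List[Set[int]]] = None
        self._residues: Optional[Dict[ResidueKey, List[int]]] = None

    def __len__(self) -> int:
        return len(self.atoms)

    # -- residue bookkeeping ------------------------------------------------
    @property
    def residues(self) -> Dict[ResidueKey, List[int]]:
        """Atom indices grouped by residue, in file order."""
        if self._residues is None:
            res: Dict[ResidueKey, List[int]] = {}
            for a in self.atoms:
                res.setdefault(a.residue_key, []).append(a.index)
            self._residues = res
        return self._residues

    def residue_name(self, key: ResidueKey) -> str:
        return self.atoms[self.residues[key][0]].res_name

    def find_atom(self, key: ResidueKey, atom_name: str) -> Optional[int]:
        for i in self.residues.get(key, ()):
            if self.atoms[i].atom_name == atom_name:
                return i
        return None

    def chain_residues(self, chain_id: str) -> List[ResidueKey]:
        """Residue keys of one chain, in file order."""
        seen: List[ResidueKey] = []
        have: Set[ResidueKey] = set()
        for a in self.atoms:
            if a.chain_id == chain_id and a.residue_key not in have:
                seen.append(a.residue_key)
                have.add(a.residue_key)
        return seen

    # -- bonds --------------------------------------------------------------
    @property
    def bonds(self) -> List[Set[int]]:
        if self._bonds is None:
            self._bonds = covalent_neighbors(self)
        return self._bonds

    def bonded(self, i: int, j: int) -> bool:
        return j in self.bonds[i]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid-body copy (bonds are recomputed lazily)."""
        new = Structure(self.id, self.assembly_id, self.atoms,
                        self.coords @ np.asarray(rotation).T + translation)
        return new


# --------------------------------------------------------------------------
# loading
# --------------------------------------------------------------------------

def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.upper()
    if el in ("", "X"):
        name = atom.name.strip()
        el = next((c for c in name if c.isalpha()), "C").upper()
    return el


def load_structure(path, assembly_id: Optional[str] = None) -> Structure:
    """Read a PDB/mmCIF file into a Structure.

    assembly_id selects a biological assembly defined in the file; the
    default is the first defined assembly, falling back to the asymmetric
    unit.  Waters are dropped, only the first model is kept and alternate
    locations are reduced to the highest-occupancy conformer.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read structure file {path}: {exc}") from exc
    st.setup_entities()
    st.remove_waters()
    while len(st) > 1:           # first model only
        del st[1]

    names = [a.name for a in st.assemblies]
    if assembly_id is None:
        use = names[0] if names else None
    elif assembly_id in names:
        use = assembly_id
    elif not names and assembly_id in ("1", "asu", None):
        use = None
    else:
        raise KeyError(f"{path}: unknown assembly id {assembly_id!r} "
                       f"(file defines {names or 'none'})")
    model = st[0]
    if use is not None:
        how = gemmi.HowToNameCopiedChain.AddNumber
        model = gemmi.make_assembly(st.assemblies[names.index(use)], model, how)

    atoms: List[AtomRef] = []
    coords: List[Tuple[float, float, float]] = []
    for chain in model:
        for res in chain:
            if res.name.strip().upper() in WATER_NAMES:
                continue
            best: Dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in res.first_conformer():
                at = best.get(at.name, at)
                atoms.append(AtomRef(
                    index=len(atoms),
                    chain_id=chain.name,
                    res_seq=res.seqid.num,
                    icode=(res.seqid.icode or " ").strip() or "",
                    res_name=res.name.strip().upper(),
                    atom_name=at.name.strip(),
                    element=_element_of(at),
                    is_hetero=(res.het_flag == "H"),
                ))
                coords.append((at.pos.x, at.pos.y, at.pos.z))
    entry = st.name or path.stem
    return Structure(entry, use or "asu", atoms, np.array(coords, dtype=float))


def write_pdb(structure: Structure, path) -> None:
    """Write the structure as plain PDB text (coordinates to 1e-3 A)."""
    lines = []
    for a in structure.atoms:
        x, y, z = structure.coords[a.index]
        rec = "HETATM" if a.is_hetero else "ATOM  "
        name = a.atom_name
        # PDB atom-name column convention: element right-aligned in 13-14
        fname = f" {name:<3s}" if len(name) < 4 and len(a.element) == 1 else f"{name:<4s}"
        lines.append(
            f"{rec}{(a.index + 1) % 100000:5d} {fname:4s} {a.res_name:<3s} "
            f"{a.chain_id[:1]:1s}{a.res_seq:4d}{a.icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# covalent connectivity
# --------------------------------------------------------------------------

_BACKBONE_AA = [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"), ("C", "OXT")]

_SIDECHAINS = {
    "ALA": [],
    "ARG": [("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CB", "SG")],
    "GLN": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "GLU": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "MET": [("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CB", "OG")],
    "THR": [("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"), ("CE2", "CZ2"),
            ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")],
    "VAL": [("CB", "CG1"), ("CB", "CG2")],
}

_SUGAR = [("C1'", "C2'"), ("C2'", "C3'"), ("C3'", "C4'"), ("C4'", "O4'"),
          ("O4'", "C1'"), ("C3'", "O3'"), ("C4'", "C5'"), ("C5'", "O5'"),
          ("O5'", "P"), ("P", "OP1"), ("P", "OP2"), ("P", "O1P"),
          ("P", "O2P"), ("P", "OP3"), ("C2'", "O2'")]

_PURINE = [("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"),
           ("C6", "N1"), ("N1", "C2"), ("C2", "N3"), ("N3", "C4"),
           ("C4", "C5"), ("C4", "N9"), ("C1'", "N9")]
_PYRIMIDINE = [("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"),
               ("C5", "C6"), ("C6", "N1"), ("C2", "O2"), ("C1'", "N1")]

_BASE_EXTRA = {
    "A": [("C6", "N6")],
    "G": [("C6", "O6"), ("C2", "N2")],
    "C": [("C4", "N4")],
    "T": [("C4", "O4"), ("C5", "C7"), ("C5", "C5M")],
    "U": [("C4", "O4")],
}


def residue_bond_template(res_name: str) -> Optional[List[Tuple[str, str]]]:
    """Intra-residue bond list for a standard residue, or None if unknown."""
    parent = parent_residue_name(res_name)
    if parent in AMINO_ACIDS:
        return _BACKBONE_AA + _SIDECHAINS[parent]
    base = nucleotide_base(res_name)
    if base is not None:
        ring = _PURINE if base in ("A", "G") else _PYRIMIDINE
        return _SUGAR + ring + _BASE_EXTRA[base]
    return None


def covalent_neighbors(structure: Structure,
                       params: Params = DEFAULT) -> List[Set[int]]:
    """Symmetric, irreflexive covalent-bond relation over atom indices.

    Standard residues use chemical templates (pairs further than
    ``bond_link_max`` apart are rejected as broken); unknown residues use
    a plain distance rule on non-hydrogen atoms.
    """
    n = len(structure)
    bonds: List[Set[int]] = [set() for _ in range(n)]
    coords = structure.coords

    def add(i: int, j: int, max_d: float) -> None:
        if i != j and np.linalg.norm(coords[i] - coords[j]) < max_d:
            bonds[i].add(j)
            bonds[j].add(i)

    unknown_atoms: List[int] = []
    per_chain: Dict[str, List[ResidueKey]] = {}
    for key, idxs in structure.residues.items():
        per_chain.setdefault(key[0], []).append(key)
        template = residue_bond_template(structure.residue_name(key))
        if template is None:
            log.debug("%s: unknown residue %s, distance-rule bonds",
                      structure.id, structure.residue_name(key))
            unknown_atoms.extend(i for i in idxs
                                 if structure.atoms[i].element != "H")
            continue
        named = {structure.atoms[i].atom_name: i for i in idxs}
        for a, b in template:
            if a in named and b in named:
                add(named[a], named[b], params.bond_link_max)

    # inter-residue links: peptide C-N, phosphodiester O3'-P, disulfide
    for chain_keys in per_chain.values():
        for prev, cur in zip(chain_keys, chain_keys[1:]):
            c = structure.find_atom(prev, "C")
            nn = structure.find_atom(cur, "N")
            if c is not None and nn is not None:
                add(c, nn, params.bond_link_max)
            o3 = structure.find_atom(prev, "O3'")
            p = structure.find_atom(cur, "P")
            if o3 is not None and p is not None:
                add(o3, p, params.bond_link_max)
    sg = [i for i, a in enumerate(structure.atoms)
          if a.atom_name == "SG" and parent_residue_name(a.res_name) == "CYS"]
    for ii, i in enumerate(sg):
        for j in sg[ii + 1:]:
            add(i, j, 2.3)

    if unknown_atoms:
        tree = cKDTree(coords)
        heavier = [i for i in range(n) if structure.atoms[i].element != "H"]
        hv = set(heavier)
        for i in unknown_atoms:
            for j in tree.query_ball_point(coords[i], params.bond_fallback_dist):
                if j != i and j in hv:
                    d = np.linalg.norm(coords[i] - coords[j])
                    if d < params.bond_fallback_dist:
                        bonds[i].add(j)
                        bonds[j].add(i)
    return bonds


# --------------------------------------------------------------------------
# domain definitions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainDefinition:
    """One instance of a structural protein domain (SCOP-style)."""

    structure_id: str
    assembly_id: str
    chain_id: str
    start: int
    end: int
    domain_id: str
    family_id: str
    start_icode: str = ""
    end_icode: str = ""

    def __post_init__(self):
        if (self.end, self.end_icode) < (self.start, self.start_icode):
            raise ValueError(f"{self.domain_id}: empty residue range "
                             f"{self.start}-{self.end}")

    def contains(self, res_seq: int, icode: str = "") -> bool:
        lo = (self.start, self.start_icode)
        hi = (self.end, self.end_icode or "~")
        return lo <= (res_seq, icode) <= hi

    @property
    def instance_id(self) -> str:
        return (f"{self.structure_id}/{self.assembly_id}/{self.chain_id}"
                f":{self.start}-{self.end}")


def _parse_resnum(token: str) -> Tuple[int, str]:
    token = token.strip()
    if token and token[-1].isalpha():
        return int(token[:-1]), token[-1].upper()
    return int(token), ""


class DomainTableError(ValueError):
    pass


def load_domain_definitions(path,
                            structures: Optional[Dict[str, Structure]] = None
                            ) -> List[DomainDefinition]:
    """Parse a domain-definition table (TSV).

    Columns: structure_id, assembly_id, chain_id, start, end, domain_id,
    family_id.  A 5-column whitespace form
    ``structure chain start-end domain family`` is also accepted (assembly
    defaults to "1").  Rows naming chains absent from the supplied
    structures are rejected with row-level messages; a domain_id must map
    to a single family_id across the whole table.
    """
    defs: List[DomainDefinition] = []
    errors: List[str] = []
    fam_of: Dict[str, str] = {}
    seen: Set[Tuple[str, str, str, int, int]] = set()
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        try:
            if len(fields) == 7:
                sid, asm, chain, start_s, end_s, dom, fam = fields
                start, s_ic = _parse_resnum(start_s)
                end, e_ic = _parse_resnum(end_s)
            elif len(fields) == 5:
                sid, chain, rng, dom, fam = fields
                asm = "1"
                lo, _, hi = rng.rpartition("-")
                start, s_ic = _parse_resnum(lo)
                end, e_ic = _parse_resnum(hi)
            else:
                raise ValueError(f"expected 5 or 7 columns, got {len(fields)}")
            d = DomainDefinition(sid.strip(), asm.strip(), chain.strip(),
                                 start, end, dom.strip(), fam.strip(),
                                 s_ic, e_ic)
        except ValueError as exc:
            errors.append(f"line {ln}: {exc}")
            continue
        key = (d.structure_id, d.assembly_id, d.chain_id, d.start, d.end)
        if key in seen:
            errors.append(f"line {ln}: duplicate domain row {key}")
            continue
        seen.add(key)
        if d.domain_id in fam_of and fam_of[d.domain_id] != d.family_id:
            errors.append(
                f"line {ln}: domain {d.domain_id} assigned to families "
                f"{fam_of[d.domain_id]!r} and {d.family_id!r}")
            continue
        fam_of[d.domain_id] = d.family_id
        if structures is not None:
            st = structures.get(d.structure_id)
            if st is not None and not any(a.chain_id == d.chain_id
                                          for a in st.atoms):
                errors.append(f"line {ln}: chain {d.chain_id!r} not found in "
                              f"structure {d.structure_id}")
                continue
        defs.append(d)
    if errors:
        raise DomainTableError("; ".join(errors))
    return defs


def domain_residues(structure: Structure, dom: DomainDefinition
                    ) -> List[ResidueKey]:
    """Residue keys of the structure covered by a domain definition."""
    return [k for k in structure.chain_residues(dom.chain_id)
            if dom.contains(k[1], k[2])]
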