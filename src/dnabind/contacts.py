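"""Atomic DNA-protein contacts: hydrogen bonds and hydrophobic clusters.

Two N/O atoms, one from protein and one from DNA, form a hydrogen bond
when they are closer than 3.7 A and their bonding power exceeds 0.1;
electrostatic (ion) pairs such as Lys NZ against a phosphate oxygen are
particular cases of this rule, and water never participates (waters are
removed at load time).  The bonding-power score multiplies a linear
distance ramp by the angular plausibility of each partner, derived from
its covalent neighbors; an alternative formula can be plugged in through
Params.hbond_power_fn.

A hydrophobic contact joins two non-polar atoms (protein carbon/sulfur
with no O/N neighbor; any DNA carbon) closer than 5.4 A, with a clear
line of sight, belonging to the same hydrophobic cluster.  Clusters are
single-linkage components over all non-polar atoms under the same
distance + line-of-sight edge rule, keeping components of at least five
atoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .dna import DnaElement
from .params import Params, DEFAULT, VDW_DEFAULT
from .protein import ProteinElement
from .structure import Structure, ResidueKey, is_amino_acid, nucleotide_base

__all__ = [
    "HBond", "HydrophobicCluster", "HydrophobicContact", "Contact",
    "nonpolar_atoms", "hydrogen_bond_power", "detect_hydrogen_bonds",
    "line_of_sight", "hydrophobic_clusters", "detect_hydrophobic_contacts",
]


@dataclass(frozen=True)
class HBond:
    protein_atom: int
    dna_atom: int
    distance: float
    power: float


@dataclass(frozen=True)
class HydrophobicCluster:
    member_atoms: FrozenSet[int]

    @property
    def size(self) -> int:
        return len(self.member_atoms)


@dataclass(frozen=True)
class HydrophobicContact:
    protein_atom: int
    dna_atom: int
    distance: float
    cluster_id: int


@dataclass(frozen=True)
class Contact:
    """One typed interface contact (H-bond or hydrophobic)."""

    kind: str                       # "hbond" | "hydrophobic"
    protein_residue: ResidueKey
    dna_residue: ResidueKey
    protein_atom: int
    dna_atom: int
    distance: float
    protein_element: ProteinElement
    dna_element: DnaElement


# --------------------------------------------------------------------------
# non-polar atom set
# --------------------------------------------------------------------------

def nonpolar_atoms(structure: Structure, params: Params = DEFAULT) -> Set[int]:
    """Indices of non-polar atoms.

    Protein: carbon and sulfur atoms with no covalently bonded oxygen or
    nitrogen (this removes the carbonyl C, CA and any carbon carrying a
    polar substituent).  DNA: every carbon, unconditionally.
    """
    bonds = structure.bonds
    out: Set[int] = set()
    for a in structure.atoms:
        if nucleotide_base(a.res_name) is not None:
            if a.element == "C":
                out.add(a.index)
        elif is_amino_acid(a.res_name):
            if a.element in ("C", "S") and not any(
                    structure.atoms[j].element in ("O", "N")
                    for j in bonds[a.index]):
                out.add(a.index)
    return out


# --------------------------------------------------------------------------
# hydrogen bonds
# --------------------------------------------------------------------------

def _angular_factor(structure: Structure, atom: int, partner_pos: np.ndarray
                    ) -> float:
    """Cosine fall-off between the contact vector and the idealized
    donor/acceptor direction (away from the mean covalent-neighbor
    direction); zero beyond 90 degrees, one for an atom with no
    heavy-atom neighbors or a symmetric environment."""
    pos = structure.coords[atom]
    neigh = [j for j in structure.bonds[atom]
             if structure.atoms[j].element != "H"]
    if not neigh:
        return 1.0
    vecs = structure.coords[neigh] - pos
    norms = np.linalg.norm(vecs, axis=1)
    mean_dir = (vecs / norms[:, None]).sum(axis=0)
    nm = np.linalg.norm(mean_dir)
    if nm < 1e-6:
        return 1.0
    ideal = -mean_dir / nm
    v = partner_pos - pos
    cosv = float(np.dot(ideal, v) / np.linalg.norm(v))
    return max(0.0, cosv)


def hydrogen_bond_power(structure: Structure, atom_a: int, atom_b: int,
                        params: Params = DEFAULT) -> float:
    """Bonding power of a candidate N/O-N/O pair, in [0, 1].

    power = f(d) * g(a) * g(b): f ramps linearly from 1 to 0 over
    [ramp_start, max_dist] and g is each atom's angular factor.
    Deterministic; raises for non-N/O atoms.
    """
    for atom in (atom_a, atom_b):
        if structure.atoms[atom].element not in ("N", "O"):
            raise ValueError(
                f"hydrogen-bond power needs N or O atoms, got "
                f"{structure.atoms[atom].element} "
                f"({structure.atoms[atom].atom_name})")
    d = float(np.linalg.norm(structure.coords[atom_a]
                             - structure.coords[atom_b]))
    if d <= params.hbond_ramp_start:
        fd = 1.0
    elif d >= params.hbond_max_dist:
        fd = 0.0
    else:
        fd = (params.hbond_max_dist - d) / (params.hbond_max_dist
                                            - params.hbond_ramp_start)
    ga = _angular_factor(structure, atom_a, structure.coords[atom_b])
    gb = _angular_factor(structure, atom_b, structure.coords[atom_a])
    if params.hbond_power_fn is not None:
        return float(params.hbond_power_fn(d, ga, gb))
    return fd * ga * gb


def detect_hydrogen_bonds(structure: Structure,
                          protein_atoms: Sequence[int],
                          dna_atoms: Sequence[int],
                          params: Params = DEFAULT) -> List[HBond]:
    """All protein-N/O x DNA-N/O pairs passing distance and power cuts."""
    p_idx = [i for i in protein_atoms
             if structure.atoms[i].element in ("N", "O")]
    d_idx = [i for i in dna_atoms
             if structure.atoms[i].element in ("N", "O")]
    if not p_idx or not d_idx:
        return []
    tree = cKDTree(structure.coords[d_idx])
    out: List[HBond] = []
    for i in p_idx:
        for jj in tree.query_ball_point(structure.coords[i],
                                        params.hbond_max_dist):
            j = d_idx[jj]
            d = float(np.linalg.norm(structure.coords[i]
                                     - structure.coords[j]))
            if d >= params.hbond_max_dist:
                continue
            power = hydrogen_bond_power(structure, i, j, params)
            if power > params.hbond_power_min:
                out.append(HBond(i, j, d, power))
    out.sort(key=lambda h: (h.protein_atom, h.dna_atom))
    return out


# --------------------------------------------------------------------------
# line of sight
# --------------------------------------------------------------------------

def line_of_sight(structure: Structure, atom_a: int, atom_b: int,
                  params: Params = DEFAULT,
                  _tree: Optional[cKDTree] = None) -> bool:
    """True when no third atom's van der Waals sphere blocks the segment.

    A blocker must stand between the endpoints: the perpendicular foot of
    its center falls strictly inside the open segment and its distance to
    the segment axis is below its vdW radius.  Hydrogens never block; the
    two endpoint atoms are excluded.
    """
    coords = structure.coords
    a, b = coords[atom_a], coords[atom_b]
    ab = b - a
    length = float(np.linalg.norm(ab))
    if length < 1e-9:
        return True
    u = ab / length
    max_r = max(params.vdw_radii.values())
    if _tree is None:
        _tree = cKDTree(coords)
    cand = _tree.query_ball_point(0.5 * (a + b), 0.5 * length + max_r)
    cand = [c for c in cand if c not in (atom_a, atom_b)
            and structure.atoms[c].element != "H"]
    if not cand:
        return True
    pts = coords[cand]
    t = (pts - a) @ u
    inside = (t > 1e-9) & (t < length - 1e-9)
    if not np.any(inside):
        return True
    perp = np.linalg.norm(pts[inside] - (a + np.outer(t[inside], u)), axis=1)
    radii = np.array([params.vdw_radii.get(structure.atoms[c].element,
                                           VDW_DEFAULT)
                      for c, keep in zip(cand, inside) if keep])
    return not np.any(perp < radii)


# --------------------------------------------------------------------------
# hydrophobic clusters and contacts
# --------------------------------------------------------------------------

def hydrophobic_clusters(structure: Structure,
                         nonpolar: Optional[Set[int]] = None,
                         params: Params = DEFAULT
                         ) -> Tuple[List[HydrophobicCluster], Dict[int, int]]:
    """Single-linkage clusters of non-polar atoms.

    Edge rule: distance below the linkage cutoff and a clear line of
    sight.  Components smaller than cluster_min_size are discarded.
    Returns the clusters and an atom -> cluster-id map.
    """
    if nonpolar is None:
        nonpolar = nonpolar_atoms(structure, params)
    idx = sorted(nonpolar)
    if not idx:
        return [], {}
    pos = {g: i for i, g in enumerate(idx)}
    coords = structure.coords
    sub = cKDTree(coords[idx])
    full = cKDTree(coords)
    rows, cols = [], []
    for ii, jj in sub.query_pairs(params.cluster_linkage_dist):
        gi, gj = idx[ii], idx[jj]
        d = float(np.linalg.norm(coords[gi] - coords[gj]))
        if d < params.cluster_linkage_dist and \
                line_of_sight(structure, gi, gj, params, _tree=full):
            rows.append(ii)
            cols.append(jj)
    n = len(idx)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    clusters: List[HydrophobicCluster] = []
    atom_cluster: Dict[int, int] = {}
    for comp in range(n_comp):
        members = [idx[i] for i in np.flatnonzero(labels == comp)]
        if len(members) >= params.cluster_min_size:
            cid = len(clusters)
            clusters.append(HydrophobicCluster(frozenset(members)))
            for m in members:
                atom_cluster[m] = cid
    return clusters, atom_cluster


def detect_hydrophobic_contacts(structure: Structure,
                                protein_atoms: Sequence[int],
                                dna_atoms: Sequence[int],
                                atom_cluster: Dict[int, int],
                                params: Params = DEFAULT
                                ) -> List[HydrophobicContact]:
    """Protein x DNA non-polar pairs meeting distance, occlusion and
    same-cluster criteria."""
    p_idx = [i for i in protein_atoms if i in atom_cluster]
    d_idx = [i for i in dna_atoms if i in atom_cluster]
    if not p_idx or not d_idx:
        return []
    coords = structure.coords
    tree = cKDTree(coords[d_idx])
    full = cKDTree(coords)
    out: List[HydrophobicContact] = []
    for i in p_idx:
        for jj in tree.query_ball_point(coords[i],
                                        params.hydrophobic_max_dist):
            j = d_idx[jj]
            if atom_cluster[i] != atom_cluster[j]:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d >= params.hydrophobic_max_dist:
                continue
            if line_of_sight(structure, i, j, params, _tree=full):
                out.append(HydrophobicContact(i, j, d, atom_cluster[i]))
    out.sort(key=lambda h: (h.protein_atom, h.dna_atom))
    return out


def contact_table(structure: Structure, contacts: Sequence[Contact]) -> str:
    """TSV rendering of typed contacts (one row per atomic contact)."""
    header = ("kind\tprot_chain\tprot_res\tprot_atom\tdna_chain\tdna_res\t"
              "dna_atom\tdistance\tprotein_element\tdna_element")
    rows = [header]
    for c in contacts:
        pa = structure.atoms[c.protein_atom]
        da = structure.atoms[c.dna_atom]
        rows.append("\t".join([
            c.kind, pa.chain_id, f"{pa.res_seq}{pa.icode}", pa.atom_name,
            da.chain_id, f"{da.res_seq}{da.icode}", da.atom_name,
            f"{c.distance:.2f}", c.protein_element.name, c.dna_element.name,
        ]))
    return "\n".join(rows) + "\n"
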