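"""DNA double-helix detection and structural-element classification.

A duplex is a run of ten or more stacked base pairs; single-nucleotide
loops or excisions inside the contact area are bridged.  Every DNA atom
of a standard deoxynucleotide belongs to exactly one of three interacting
elements: the sugar-phosphate backbone, the major-groove base edge or the
minor-groove base edge, with the ring junction atoms (purine N9/pyrimidine
N1 glycosidic nitrogens and purine C4/N1...) outside the published lists
left unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .params import Params, DEFAULT
from .structure import Structure, ResidueKey, nucleotide_base

__all__ = [
    "DnaElement", "BasePair", "Duplex", "classify_dna_atom",
    "detect_base_pairs", "detect_duplexes", "STANDARD_BASE_COORDS",
]


class DnaElement(Enum):
    BACKBONE = "Bb"
    MAJOR = "Mj"
    MINOR = "Mn"


#: deoxyribose + phosphate atoms (the backbone element), enumerated
BACKBONE_ATOMS = {
    "P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P",
    "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
}

#: per-base major/minor groove atom lists
MAJOR_GROOVE = {
    "A": {"C5", "C6", "N6", "N7", "C8"},
    "T": {"C4", "O4", "C5", "C6", "C7", "C5M"},
    "G": {"C5", "C6", "O6", "N7", "C8"},
    "C": {"C4", "N4", "C5", "C6"},
    "U": {"C4", "O4", "C5", "C6"},
}
MINOR_GROOVE = {
    "A": {"N1", "C2", "N3", "C4"},
    "T": {"C2", "O2", "N3"},
    "G": {"N1", "C2", "N2", "N3", "C4"},
    "C": {"C2", "O2", "N3"},
    "U": {"C2", "O2", "N3"},
}


def classify_dna_atom(res_name: str, atom_name: str) -> Optional[DnaElement]:
    """Element of one DNA atom, or None for atoms outside the lists.

    Backbone membership is decided first (deoxyribose and phosphate atom
    names), then the per-base groove lists; e.g. purine N9 belongs to no
    element and contacts through it carry no contact type.
    """
    base = nucleotide_base(res_name)
    if base is None:
        raise KeyError(f"unknown nucleotide residue {res_name!r}")
    atom_name = atom_name.strip().upper().replace("*", "'")
    if atom_name in BACKBONE_ATOMS:
        return DnaElement.BACKBONE
    if atom_name in MAJOR_GROOVE[base]:
        return DnaElement.MAJOR
    if atom_name in MINOR_GROOVE[base]:
        return DnaElement.MINOR
    return None


# --------------------------------------------------------------------------
# standard base geometry (used for pairing planes and base-pair frames)
# --------------------------------------------------------------------------

#: Idealized base atom coordinates in the standard base reference frame
#: (x toward the major-groove edge, y toward the glycosidic bond, base in
#: the z=0 plane); C1' included as the idealized in-plane position.
STANDARD_BASE_COORDS: Dict[str, Dict[str, Tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.0), "N9": (-1.291, 4.498, 0.0),
        "C8": (-0.024, 4.897, 0.0), "N7": (0.877, 3.902, 0.0),
        "C5": (0.071, 2.771, 0.0), "C6": (0.369, 1.398, 0.0),
        "N6": (1.611, 0.909, 0.0), "N1": (-0.668, 0.532, 0.0),
        "C2": (-1.912, 1.023, 0.0), "N3": (-2.320, 2.290, 0.0),
        "C4": (-1.267, 3.124, 0.0),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.0), "N9": (-1.289, 4.551, 0.0),
        "C8": (-0.023, 4.962, 0.0), "N7": (0.870, 3.969, 0.0),
        "C5": (0.071, 2.833, 0.0), "C6": (0.424, 1.460, 0.0),
        "O6": (1.554, 0.955, 0.0), "N1": (-0.700, 0.641, 0.0),
        "C2": (-1.999, 1.087, 0.0), "N2": (-2.949, 0.139, 0.0),
        "N3": (-2.342, 2.364, 0.0), "C4": (-1.265, 3.177, 0.0),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.0), "N1": (-1.285, 4.542, 0.0),
        "C2": (-1.472, 3.158, 0.0), "O2": (-2.628, 2.709, 0.0),
        "N3": (-0.391, 2.344, 0.0), "C4": (0.837, 2.868, 0.0),
        "N4": (1.875, 2.027, 0.0), "C5": (1.056, 4.275, 0.0),
        "C6": (-0.023, 5.068, 0.0),
    },
    "T": {
        "C1'": (-2.481, 5.354, 0.0), "N1": (-1.284, 4.500, 0.0),
        "C2": (-1.462, 3.135, 0.0), "O2": (-2.562, 2.608, 0.0),
        "N3": (-0.298, 2.407, 0.0), "C4": (0.994, 2.897, 0.0),
        "O4": (1.944, 2.119, 0.0), "C5": (1.106, 4.338, 0.0),
        "C7": (2.466, 4.961, 0.0), "C6": (-0.024, 5.057, 0.0),
    },
}
STANDARD_BASE_COORDS["U"] = {
    k: v for k, v in STANDARD_BASE_COORDS["T"].items() if k != "C7"
}

WC_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}


# --------------------------------------------------------------------------
# base pairing
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BasePair:
    """Two paired nucleotides with summary pairing geometry."""

    nt1: ResidueKey
    nt2: ResidueKey
    c1_distance: float
    plane_angle: float       # degrees between base planes
    n_hbonds: int            # inter-base N/O pairs within H-bond range

    @property
    def nucleotides(self) -> Tuple[ResidueKey, ResidueKey]:
        return (self.nt1, self.nt2)


@dataclass
class Duplex:
    """An ordered run of stacked base pairs (a detected double helix)."""

    pairs: List[BasePair]
    gaps: List[int] = field(default_factory=list)   # step indices bridged

    @property
    def length(self) -> int:
        return len(self.pairs)

    @property
    def nucleotides(self) -> Set[ResidueKey]:
        out: Set[ResidueKey] = set()
        for p in self.pairs:
            out.update(p.nucleotides)
        return out

    def strand_order(self, strand: int) -> List[ResidueKey]:
        return [(p.nt1 if strand == 0 else p.nt2) for p in self.pairs]


def _nucleotide_info(structure: Structure):
    """Collect per-nucleotide C1' position, base-plane normal, base N/O."""
    info = {}
    coords = structure.coords
    for key in structure.residues:
        base = nucleotide_base(structure.residue_name(key))
        if base is None:
            continue
        c1 = structure.find_atom(key, "C1'")
        if c1 is None:
            c1 = structure.find_atom(key, "C1*")
        if c1 is None:
            continue
        ring_names = set(STANDARD_BASE_COORDS[base]) - {"C1'"}
        ring_idx = [i for i in structure.residues[key]
                    if structure.atoms[i].atom_name.replace("*", "'")
                    in ring_names]
        if len(ring_idx) < 4:
            continue
        pts = coords[ring_idx]
        center = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - center)
        normal = vt[2]
        polar = [i for i in ring_idx
                 if structure.atoms[i].element in ("N", "O")]
        info[key] = {
            "base": base, "c1": coords[c1], "center": center,
            "normal": normal, "polar": polar, "c1_idx": c1,
        }
    return info


def detect_base_pairs(structure: Structure,
                      params: Params = DEFAULT) -> List[BasePair]:
    """Geometric base-pair detection.

    A candidate pair must have its C1'-C1' distance inside the configured
    window, base planes within the angular tolerance and at least two
    inter-base N/O-N/O distances in hydrogen-bond range; each nucleotide
    joins at most one pair (best-scoring candidates first).  Pairing is
    purely geometric, so non-Watson-Crick pairs that meet the criteria
    are accepted.
    """
    info = _nucleotide_info(structure)
    keys = list(info)
    if len(keys) < 2:
        return []
    c1 = np.array([info[k]["c1"] for k in keys])
    tree = cKDTree(c1)
    coords = structure.coords
    candidates = []
    for i, j in tree.query_pairs(params.pair_c1_max):
        ki, kj = keys[i], keys[j]
        if ki[0] == kj[0] and abs(ki[1] - kj[1]) <= 1:
            continue                     # chain neighbors cannot pair
        d = float(np.linalg.norm(c1[i] - c1[j]))
        if d < params.pair_c1_min:
            continue
        cosang = abs(float(np.dot(info[ki]["normal"], info[kj]["normal"])))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if angle > params.pair_plane_angle_max:
            continue
        pi = coords[info[ki]["polar"]]
        pj = coords[info[kj]["polar"]]
        dm = np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=2)
        n_hb = int((dm <= params.pair_hbond_dist).sum())
        if n_hb < params.pair_min_hbonds:
            continue
        score = 10.0 * n_hb - abs(d - 10.4) - angle / params.pair_plane_angle_max
        candidates.append((score, ki, kj, d, angle, n_hb))

    candidates.sort(key=lambda t: -t[0])
    used: Set[ResidueKey] = set()
    pairs = []
    for _, ki, kj, d, angle, n_hb in candidates:
        if ki in used or kj in used:
            continue
        used.update((ki, kj))
        if (kj, ki) < (ki, kj):
            ki, kj = kj, ki
        pairs.append(BasePair(ki, kj, d, angle, n_hb))
    return pairs


def read_base_pair_table(path, structure: Structure) -> List[BasePair]:
    """Import an externally determined base-pair list (overrides the
    internal detection).

    Tab- or space-separated rows: ``chain1 res1 chain2 res2`` (insertion
    codes appended to the residue number).  Pair geometry is measured on
    the structure.
    """
    from pathlib import Path
    info = _nucleotide_info(structure)
    pairs: List[BasePair] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        if len(f) != 4:
            raise ValueError(f"{path} line {ln}: expected 4 fields")

        def reskey(ch, token):
            ic = ""
            if token[-1].isalpha():
                token, ic = token[:-1], token[-1]
            return (ch, int(token), ic)
        k1, k2 = reskey(f[0], f[1]), reskey(f[2], f[3])
        for k in (k1, k2):
            if k not in info:
                raise KeyError(f"{path} line {ln}: nucleotide {k} not found")
        d = float(np.linalg.norm(info[k1]["c1"] - info[k2]["c1"]))
        cosang = abs(float(np.dot(info[k1]["normal"], info[k2]["normal"])))
        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if (k2, k1) < (k1, k2):
            k1, k2 = k2, k1
        pairs.append(BasePair(k1, k2, d, ang, 0))
    return pairs


def duplex_report(duplexes: Sequence[Duplex]) -> str:
    """TSV summary: one row per duplex (length, gaps, terminal pairs)."""
    rows = ["duplex\tlength\tn_gaps\tfirst_pair\tlast_pair"]
    for i, d in enumerate(duplexes):
        def fmt(p):
            return (f"{p.nt1[0]}:{p.nt1[1]}{p.nt1[2]}-"
                    f"{p.nt2[0]}:{p.nt2[1]}{p.nt2[2]}")
        rows.append(f"{i}\t{d.length}\t{len(d.gaps)}\t{fmt(d.pairs[0])}\t"
                    f"{fmt(d.pairs[-1])}")
    return "\n".join(rows) + "\n"


def _pair_midpoint(structure: Structure, info, pair: BasePair) -> np.ndarray:
    return 0.5 * (info[pair.nt1]["c1"] + info[pair.nt2]["c1"])


def detect_duplexes(structure: Structure, base_pairs: Sequence[BasePair],
                    params: Params = DEFAULT) -> List[Duplex]:
    """Chain base pairs into double helices by stacking.

    Adjacent pairs stack when their C1'-C1' midpoints are within the
    stacking window; a single-nucleotide interruption may be bridged (a
    recorded gap).  Runs shorter than the minimum length are discarded.
    """
    if not base_pairs:
        return []
    info = _nucleotide_info(structure)
    mids = np.array([_pair_midpoint(structure, info, p) for p in base_pairs])
    n = len(base_pairs)
    # candidate stacking edges, flagged as plain or bridged
    edges: Dict[int, List[Tuple[int, bool]]] = {i: [] for i in range(n)}
    tree = cKDTree(mids)
    for i, j in sorted(tree.query_pairs(params.gap_bridge_dist)):
        d = float(np.linalg.norm(mids[i] - mids[j]))
        bridged = d > params.stack_mid_dist
        edges[i].append((j, bridged))
        edges[j].append((i, bridged))

    def nearest_sorted(i):
        return sorted(edges[i],
                      key=lambda t: np.linalg.norm(mids[i] - mids[t[0]]))

    visited = [False] * n
    duplexes: List[Duplex] = []
    for start in range(n):
        if visited[start]:
            continue
        # grow a path from this pair in both directions, preferring
        # un-bridged (stacked) steps and nearest midpoints
        path = [start]
        visited[start] = True
        for direction in (0, 1):
            cur = path[-1] if direction == 0 else path[0]
            while True:
                nxt = next((j for j, _ in nearest_sorted(cur)
                            if not visited[j]), None)
                if nxt is None:
                    break
                visited[nxt] = True
                path.append(nxt) if direction == 0 else path.insert(0, nxt)
                cur = nxt
        pairs = [base_pairs[i] for i in path]
        gap_steps = []
        for s in range(len(pairs) - 1):
            d = float(np.linalg.norm(
                _pair_midpoint(structure, info, pairs[s]) -
                _pair_midpoint(structure, info, pairs[s + 1])))
            if d > params.stack_mid_dist:
                gap_steps.append(s)
        if len(pairs) >= params.duplex_min_bp:
            duplexes.append(Duplex(pairs, gap_steps))
    return duplexes
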