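"""Protein secondary structure and the three interacting elements.

Residues are grouped into helix (alpha or 3-10, plus pi), beta-strand,
or loop (turns, isolated bridges and unstructured segments).  The
internal assignment follows the classic backbone H-bond pattern method:
an electrostatic N-H...O=C energy below -0.5 kcal/mol defines a hydrogen
bond, consecutive n-turns define helices and bridge ladders define
strands.  Assignments made by external programs (Stride or DSSP report
files) can be imported instead, and the source is recorded, because
short 3-10 segments are known to flip between sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .structure import Structure, ResidueKey, is_amino_acid

__all__ = [
    "ProteinElement", "SSAssignment", "assign_secondary_structure",
    "map_ss_to_element", "import_external_ss",
]


class ProteinElement(Enum):
    HELIX = "H"
    STRAND = "S"
    LOOP = "L"


#: raw code -> element; alpha (H), 3-10 (G) and pi (I) helices count as
#: Helix, extended strand (E) as Strand, everything else (turn T, bend S,
#: isolated bridge B, coil C/-) as Loop.
_CODE_MAP = {
    "H": ProteinElement.HELIX, "G": ProteinElement.HELIX,
    "I": ProteinElement.HELIX,
    "E": ProteinElement.STRAND,
    "B": ProteinElement.LOOP, "b": ProteinElement.LOOP,
    "T": ProteinElement.LOOP, "S": ProteinElement.LOOP,
    "C": ProteinElement.LOOP, "-": ProteinElement.LOOP,
    " ": ProteinElement.LOOP,
}


def map_ss_to_element(raw_code: str) -> ProteinElement:
    """Map a raw secondary-structure letter to one of the three elements."""
    try:
        return _CODE_MAP[raw_code.strip() or "C"]
    except KeyError:
        raise KeyError(f"unknown secondary-structure code {raw_code!r}")


@dataclass
class SSAssignment:
    """Per-residue raw codes and elements for one structure."""

    codes: Dict[ResidueKey, str] = field(default_factory=dict)
    source: str = "internal"

    def element(self, key: ResidueKey) -> ProteinElement:
        return map_ss_to_element(self.codes.get(key, "C"))

    def merge(self, other: "SSAssignment") -> None:
        self.codes.update(other.codes)


# --------------------------------------------------------------------------
# internal assignment (backbone H-bond pattern)
# --------------------------------------------------------------------------

_HB_ENERGY_CUTOFF = -0.5   # kcal/mol
_Q1Q2_F = 0.084 * 332.0


def _chain_segments(structure: Structure, chain: str
                    ) -> List[List[ResidueKey]]:
    """Consecutive peptide-bonded runs of amino-acid residues."""
    keys = [k for k in structure.chain_residues(chain)
            if is_amino_acid(structure.residue_name(k))]
    segments: List[List[ResidueKey]] = []
    for k in keys:
        if segments:
            prev = segments[-1][-1]
            c = structure.find_atom(prev, "C")
            n = structure.find_atom(k, "N")
            if (c is not None and n is not None and
                    np.linalg.norm(structure.coords[c] -
                                   structure.coords[n]) < 2.5):
                segments[-1].append(k)
                continue
        segments.append([k])
    return segments


def _assign_all(structure: Structure, res: List[ResidueKey],
                seg_id: List[int]) -> Dict[ResidueKey, str]:
    """Joint assignment over every peptide segment of the model.

    Backbone H-bonds are evaluated across segments and chains (sheets
    are frequently inter-chain); n-turns are sequence-local.
    """
    coords = structure.coords
    n = len(res)
    N = np.full((n, 3), np.nan)
    C = np.full((n, 3), np.nan)
    O = np.full((n, 3), np.nan)
    for i, k in enumerate(res):
        for name, arr in (("N", N), ("C", C), ("O", O)):
            idx = structure.find_atom(k, name)
            if idx is not None:
                arr[i] = coords[idx]
    # amide H: 1.0 A from N, anti-parallel to the preceding C=O
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        if seg_id[i] == seg_id[i - 1] and not (
                np.any(np.isnan(N[i])) or np.any(np.isnan(C[i - 1]))
                or np.any(np.isnan(O[i - 1]))):
            v = C[i - 1] - O[i - 1]
            H[i] = N[i] + v / np.linalg.norm(v)

    acc: List[Set[int]] = [set() for _ in range(n)]
    ok_acc = ~(np.isnan(C).any(axis=1) | np.isnan(O).any(axis=1))
    ok_don = ~(np.isnan(N).any(axis=1) | np.isnan(H).any(axis=1))
    for i in range(n):              # acceptor C=O of residue i
        if not ok_acc[i]:
            continue
        near = np.flatnonzero(ok_don & (np.linalg.norm(N - O[i], axis=1) < 5.2))
        for j in near:
            if j == i or (seg_id[i] == seg_id[j] and abs(i - j) == 1):
                continue
            r_on = np.linalg.norm(O[i] - N[j])
            r_ch = np.linalg.norm(C[i] - H[j])
            r_oh = np.linalg.norm(O[i] - H[j])
            r_cn = np.linalg.norm(C[i] - N[j])
            energy = _Q1Q2_F * (1.0 / r_on + 1.0 / r_ch
                                - 1.0 / r_oh - 1.0 / r_cn)
            if energy < _HB_ENERGY_CUTOFF:
                acc[i].add(int(j))

    def hbond(acceptor: int, donor: int) -> bool:
        return 0 <= acceptor < n and 0 <= donor < n and donor in acc[acceptor]

    def contiguous(i0: int, i1: int) -> bool:
        return (0 <= i0 and i1 < n
                and all(seg_id[k] == seg_id[i0] for k in range(i0, i1 + 1)))

    turns = {t: [contiguous(i, i + t) and hbond(i, i + t)
                 for i in range(n)] + [False] * t for t in (3, 4, 5)}

    # bridges / ladders (sequence separation >= 3 within a segment;
    # any separation across segments or chains)
    pairs: Set[Tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if seg_id[i] == seg_id[j] and j - i < 3:
                continue
            parallel = ((contiguous(i - 1, i + 1)
                         and hbond(i - 1, j) and hbond(j, i + 1)) or
                        (contiguous(j - 1, j + 1)
                         and hbond(j - 1, i) and hbond(i, j + 1)))
            anti = ((hbond(i, j) and hbond(j, i)) or
                    (contiguous(i - 1, i + 1) and contiguous(j - 1, j + 1)
                     and hbond(i - 1, j + 1) and hbond(j - 1, i + 1)))
            if parallel or anti:
                pairs.add((i, j))
    ladder = [False] * n
    bridge = [False] * n
    for i, j in pairs:
        bridge[i] = bridge[j] = True
        if any((i + di, j + dj) in pairs or (j + dj, i + di) in pairs
               for di in (-1, 1) for dj in (-1, 1)):
            ladder[i] = ladder[j] = True

    codes = ["C"] * n
    # 4-helix (alpha): two consecutive 4-turns
    for i in range(1, n - 4):
        if turns[4][i - 1] and turns[4][i]:
            for k in range(i, i + 4):
                codes[k] = "H"
    # strand (ladder) and isolated bridge
    for i in range(n):
        if codes[i] == "C" and ladder[i]:
            codes[i] = "E"
        elif codes[i] == "C" and bridge[i]:
            codes[i] = "B"
    # 3-10 and pi helices
    for t, code in ((3, "G"), (5, "I")):
        for i in range(1, n - t):
            if turns[t][i - 1] and turns[t][i]:
                for k in range(i, i + t):
                    if codes[k] == "C":
                        codes[k] = code
    # remaining turn positions
    for t in (3, 4, 5):
        for i in range(n - t):
            if turns[t][i]:
                for k in range(i + 1, i + t):
                    if codes[k] == "C":
                        codes[k] = "T"
    return dict(zip(res, codes))


def assign_secondary_structure(structure: Structure,
                               chain: Optional[str] = None) -> SSAssignment:
    """Backbone H-bond-pattern assignment for one chain (or all chains).

    Residues missing backbone atoms are reported as coil (-> Loop).
    Deterministic for a fixed input.  Even when a single chain is
    requested, H-bond partners from every protein chain are considered.
    """
    chains = sorted({a.chain_id for a in structure.atoms
                     if is_amino_acid(a.res_name)})
    res: List[ResidueKey] = []
    seg_id: List[int] = []
    seg = 0
    for ch in chains:
        for segment in _chain_segments(structure, ch):
            res.extend(segment)
            seg_id.extend([seg] * len(segment))
            seg += 1
    codes = _assign_all(structure, res, seg_id)
    out = SSAssignment(source="internal")
    for key, code in codes.items():
        if chain is None or key[0] == chain:
            out.codes[key] = code
    return out


# --------------------------------------------------------------------------
# external assignments
# --------------------------------------------------------------------------

def _parse_stride(text: str) -> Dict[Tuple[str, int, str], str]:
    codes = {}
    for line in text.splitlines():
        if not line.startswith("ASG"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"malformed Stride ASG line: {line!r}")
        chain = fields[2]
        num = fields[3]
        icode = ""
        if num and num[-1].isalpha():
            num, icode = num[:-1], num[-1]
        code = fields[5].upper()
        codes[(chain if chain != "-" else "", int(num), icode)] = code
    return codes


def _parse_dssp(text: str) -> Dict[Tuple[str, int, str], str]:
    codes = {}
    in_table = False
    for line in text.splitlines():
        if line.startswith("  #  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(line) < 17:
            continue
        if line[13] == "!":          # chain break marker
            continue
        num = line[5:10].strip()
        if not num:
            continue
        icode = line[10].strip()
        chain = line[11].strip()
        code = line[16] if line[16] != " " else "C"
        codes[(chain, int(num), icode)] = code
    return codes


def import_external_ss(path, fmt: str,
                       structure: Optional[Structure] = None) -> SSAssignment:
    """Read a Stride or DSSP report and map codes to elements.

    When a structure is supplied, every assigned residue must exist in
    it; the first mismatch is reported by name.
    """
    text = Path(path).read_text()
    if fmt.lower() == "stride":
        codes = _parse_stride(text)
    elif fmt.lower() == "dssp":
        codes = _parse_dssp(text)
    else:
        raise ValueError(f"unknown secondary-structure format {fmt!r}")
    if not codes:
        raise ValueError(f"{path}: no residue assignments found")
    for code in codes.values():
        map_ss_to_element(code)      # validate early
    if structure is not None:
        known = set(structure.residues)
        for key in codes:
            if key not in known:
                raise ValueError(
                    f"{path}: residue {key[0]}:{key[1]}{key[2]} not present "
                    f"in structure {structure.id}")
    return SSAssignment(codes=dict(codes), source=fmt.lower())
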