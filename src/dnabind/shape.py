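"""DNA shape parameters in domain contact zones.

The contact zone of a domain is the set of duplex nucleotides either in
contact with the domain or within two positions along the chain of a
contacting nucleotide (clipped at chain breaks and duplex ends).  When
the zone covers at least three base pairs, five parameters are computed:

* Ax-bend: per step, the local helix axis is the screw axis of the
  transform between consecutive base-pair reference frames; Ax-bend is
  the mean angle between consecutive local axes, in degrees.
* Groove width: cubic splines are run through the phosphorus atoms of
  each strand; a groove width is the minimal inter-spline distance on
  that groove's side minus 5.8 A (twice the phosphate-group reduction of
  the reference method).  Undefined when a strand spline has fewer than
  three P atoms or the groove's minimum is not bracketed by the zone.
* Groove depth: radial distance of the width-segment midpoint from the
  local helix axis minus the mean radial extent of the groove-side base
  atoms, less a per-groove offset calibrated so the ideal fiber duplex
  reproduces the reference values; may be negative for a splayed groove.

Base-pair frames come from least-squares fits of the standard base
coordinates (the strand II frame is flipped about x before averaging),
so every quantity is rigid-body invariant by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .contacts import Contact
from .dna import (BasePair, DnaElement, Duplex, MAJOR_GROOVE, MINOR_GROOVE,
                  STANDARD_BASE_COORDS)
from .params import Params, DEFAULT
from .structure import Structure, ResidueKey, nucleotide_base

__all__ = [
    "ContactZone", "GrooveShape", "FamilyShapeStats", "contact_zone",
    "base_pair_frames", "ax_bend", "groove_geometry", "aggregate_shape",
]

PARAM_NAMES = ("ax_bend", "minor_width", "minor_depth",
               "major_width", "major_depth")


@dataclass
class ContactZone:
    domain_instance: str
    nucleotides: Set[ResidueKey]
    zone_pairs: List[BasePair]          # duplex restriction, in duplex order

    @property
    def n_bp(self) -> int:
        return len(self.zone_pairs)


@dataclass
class GrooveShape:
    """Shape parameters of one contact zone; None marks undefined values."""

    ax_bend: Optional[float] = None
    minor_width: Optional[float] = None
    minor_depth: Optional[float] = None
    major_width: Optional[float] = None
    major_depth: Optional[float] = None

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {k: getattr(self, k) for k in PARAM_NAMES}


@dataclass
class FamilyShapeStats:
    """avg/min/max across domains of per-domain (across-structure) means."""

    family_id: str
    per_domain: Dict[str, Dict[str, Optional[float]]]
    average: Dict[str, Optional[float]] = field(default_factory=dict)
    minimum: Dict[str, Optional[float]] = field(default_factory=dict)
    maximum: Dict[str, Optional[float]] = field(default_factory=dict)


# --------------------------------------------------------------------------
# contact zones
# --------------------------------------------------------------------------

def contact_zone(domain_instance: str, contacts: Sequence[Contact],
                 duplex: Duplex, structure: Structure,
                 params: Params = DEFAULT,
                 contacted_residues: Optional[Set[ResidueKey]] = None
                 ) -> ContactZone:
    """Contacting nucleotides expanded +-2 along each chain.

    Expansion walks residue order within the duplex on the same chain and
    stops at chain breaks and duplex ends.  ``contacted_residues`` may
    supply the contacted set directly (the zone is defined by any atomic
    contact, including contacts through atoms outside the element lists).
    """
    dup_nts = duplex.nucleotides
    if contacted_residues is None:
        contacted_residues = {c.dna_residue for c in contacts}
    contacted = {k for k in contacted_residues if k in dup_nts}
    zone: Set[ResidueKey] = set(contacted)
    # residue order per chain, restricted to this duplex
    per_chain: Dict[str, List[ResidueKey]] = {}
    for key in sorted(dup_nts):
        per_chain.setdefault(key[0], [])
    for ch in per_chain:
        per_chain[ch] = [k for k in structure.chain_residues(ch)
                         if k in dup_nts]
    for nt in contacted:
        order = per_chain.get(nt[0], [])
        if nt not in order:
            continue
        i = order.index(nt)
        for step in (1, -1):
            j = i
            for _ in range(params.zone_pad_nt):
                jn = j + step
                if jn < 0 or jn >= len(order):
                    break
                # clip at chain breaks (non-consecutive residue numbers
                # are allowed only when covalently linked)
                prev, cur = (order[j], order[jn])[::step]
                o3 = structure.find_atom(prev, "O3'")
                p = structure.find_atom(cur, "P")
                if o3 is None or p is None or \
                        np.linalg.norm(structure.coords[o3]
                                       - structure.coords[p]) > params.bond_link_max:
                    break
                zone.add(order[jn])
                j = jn
    zone_pairs = [p for p in duplex.pairs
                  if p.nt1 in zone or p.nt2 in zone]
    return ContactZone(domain_instance, zone, zone_pairs)


# --------------------------------------------------------------------------
# base-pair reference frames
# --------------------------------------------------------------------------

def _kabsch(ref: np.ndarray, obs: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Rotation R, translation t with obs ~ ref @ R.T + t (right-handed)."""
    rc = ref.mean(axis=0)
    oc = obs.mean(axis=0)
    h = (ref - rc).T @ (obs - oc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = oc - r @ rc
    return r, t


_FLIP_X = np.diag([1.0, -1.0, -1.0])


def _base_frame(structure: Structure, key: ResidueKey
                ) -> Optional[Tuple[np.ndarray, np.ndarray]]:
    base = nucleotide_base(structure.residue_name(key))
    if base is None:
        return None
    std = STANDARD_BASE_COORDS[base]
    ref, obs = [], []
    for i in structure.residues[key]:
        name = structure.atoms[i].atom_name.replace("*", "'")
        if name in std and name != "C1'":
            ref.append(std[name])
            obs.append(structure.coords[i])
    if len(ref) < 4:
        return None
    r, t = _kabsch(np.array(ref), np.array(obs))
    origin = r @ np.zeros(3) + t
    return r, origin


def _orthonormalize(m: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(m)
    r = u @ vt
    if np.linalg.det(r) < 0:
        r = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    return r


def base_pair_frames(structure: Structure, pairs: Sequence[BasePair]
                     ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Ordered (rotation, origin) reference frames, one per base pair.

    Each base is fitted to its standard coordinates; the second strand's
    frame is rotated 180 degrees about x and the two are averaged, giving
    a right-handed frame whose z axis points along the helix.
    """
    frames = []
    for p in pairs:
        f1 = _base_frame(structure, p.nt1)
        f2 = _base_frame(structure, p.nt2)
        if f1 is None and f2 is None:
            continue
        if f1 is None:
            r2, o2 = f2
            frames.append((_orthonormalize(r2 @ _FLIP_X), o2))
            continue
        if f2 is None:
            frames.append(f1)
            continue
        r1, o1 = f1
        r2, o2 = f2
        r2f = r2 @ _FLIP_X
        # keep both frames on the same hemisphere before averaging
        if np.dot(r1[:, 2], r2f[:, 2]) < 0:
            r2f = r2f @ np.diag([-1.0, 1.0, -1.0])
        frames.append((_orthonormalize(r1 + r2f), 0.5 * (o1 + o2)))
    return frames


# --------------------------------------------------------------------------
# Ax-bend
# --------------------------------------------------------------------------

def local_helix_axes(frames: Sequence[Tuple[np.ndarray, np.ndarray]]
                     ) -> List[np.ndarray]:
    """One local helix axis per step.

    The base-pair normal (frame z) tracks the local helix axis in a
    double helix; the step axis is the mean of the two flanking normals.
    (The raw screw axis of the step transform is unsuitable here: for a
    step that combines a ~36 degree twist with a small kink it tilts by
    far more than the kink itself.)  Each axis is oriented along the
    rise.
    """
    axes = []
    for (r1, o1), (r2, o2) in zip(frames, frames[1:]):
        ax = r1[:, 2] + r2[:, 2]
        n = np.linalg.norm(ax)
        ax = (r1[:, 2] if n < 1e-9 else ax / n)
        rise_dir = o2 - o1
        if np.dot(ax, rise_dir) < 0:
            ax = -ax
        axes.append(ax)
    return axes


def ax_bend(frames: Sequence[Tuple[np.ndarray, np.ndarray]]
            ) -> Optional[float]:
    """Mean angle (degrees) between consecutive local helix axes."""
    axes = local_helix_axes(frames)
    if len(axes) < 2:
        return None
    angles = []
    for a, b in zip(axes, axes[1:]):
        cosv = float(np.clip(np.dot(a, b), -1.0, 1.0))
        angles.append(math.degrees(math.acos(cosv)))
    return float(np.mean(angles))


# --------------------------------------------------------------------------
# grooves
# --------------------------------------------------------------------------

def _strand_p_spline(structure: Structure, order: List[ResidueKey],
                     params: Params) -> Optional[CubicSpline]:
    pts = []
    for key in order:
        p = structure.find_atom(key, "P")
        if p is not None:
            pts.append(structure.coords[p])
    if len(pts) < params.groove_min_p:
        return None
    pts = np.array(pts)
    t = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    return CubicSpline(t, pts, axis=0)


def _groove_side_atoms(structure: Structure, pairs: Sequence[BasePair],
                       side: str) -> List[int]:
    table = MINOR_GROOVE if side == "minor" else MAJOR_GROOVE
    out = []
    for p in pairs:
        for key in p.nucleotides:
            base = nucleotide_base(structure.residue_name(key))
            if base is None:
                continue
            for i in structure.residues[key]:
                if structure.atoms[i].atom_name.replace("*", "'") \
                        in table[base]:
                    out.append(i)
    return out


def _min_distance_segments(s1: CubicSpline, s2: CubicSpline,
                           n_samples: int = 160):
    """Local minima of the inter-spline distance: (midpoint, distance,
    endpoints) per local minimum over the strand-1 parameter."""
    t1 = np.linspace(s1.x[0], s1.x[-1], n_samples)
    t2 = np.linspace(s2.x[0], s2.x[-1], n_samples)
    p1 = s1(t1)
    p2 = s2(t2)
    d = np.linalg.norm(p1[:, None, :] - p2[None, :, :], axis=2)
    best_j = d.argmin(axis=1)
    best_d = d.min(axis=1)
    minima = []
    for i in range(1, n_samples - 1):
        # tolerance-inclusive so flat, near-degenerate basins are all
        # refined regardless of floating-point noise in the grid scan
        if best_d[i] <= best_d[i - 1] + 1e-3 and \
                best_d[i] <= best_d[i + 1] + 1e-3:
            # refine in the continuous parameters
            def f(u):
                a = s1(u)

                def g(v):
                    return float(np.linalg.norm(a - s2(v)))
                r = minimize_scalar(g, bounds=(s2.x[0], s2.x[-1]),
                                    method="bounded",
                                    options={"xatol": 1e-10})
                return r.fun, r.x
            lo = max(s1.x[0], t1[i - 1])
            hi = min(s1.x[-1], t1[i + 1])
            ru = minimize_scalar(lambda u: f(u)[0], bounds=(lo, hi),
                                 method="bounded",
                                 options={"xatol": 1e-10})
            dist, v = f(ru.x)
            a, b = s1(ru.x), s2(v)
            minima.append((0.5 * (a + b), float(dist), a, b))
    # deduplicate near-identical minima
    out = []
    for m in sorted(minima, key=lambda m: m[1]):
        if all(np.linalg.norm(m[0] - o[0]) > 2.0 for o in out):
            out.append(m)
    return out


def groove_geometry(structure: Structure, zone_pairs: Sequence[BasePair],
                    frames: Sequence[Tuple[np.ndarray, np.ndarray]],
                    params: Params = DEFAULT) -> GrooveShape:
    """Groove widths and depths of a zone duplex (Ax-bend included).

    Splines through each strand's P atoms; each local minimum of the
    inter-spline distance is attributed to the groove whose base-edge
    atoms lie nearer its midpoint; width is the smallest distance per
    side minus the phosphate reduction, depth the calibrated radial
    offset of the midpoint against the groove floor.
    """
    shape = GrooveShape()
    if len(zone_pairs) < params.zone_min_bp or len(frames) < 2:
        return shape
    shape.ax_bend = ax_bend(frames)

    order1 = [p.nt1 for p in zone_pairs]
    order2 = [p.nt2 for p in zone_pairs]
    s1 = _strand_p_spline(structure, order1, params)
    s2 = _strand_p_spline(structure, order2, params)
    if s1 is None or s2 is None:
        return shape
    minima = _min_distance_segments(s1, s2)
    if not minima:
        return shape

    minor_atoms = _groove_side_atoms(structure, zone_pairs, "minor")
    major_atoms = _groove_side_atoms(structure, zone_pairs, "major")
    if not minor_atoms or not major_atoms:
        return shape
    cmin = structure.coords[minor_atoms]
    cmaj = structure.coords[major_atoms]
    origins = np.array([o for _, o in frames])
    axes = local_helix_axes(frames)
    # per-pair floor atoms (selected by base-pair index, which is robust
    # against floating-point jitter in the width-minimum location)
    floor_by_pair = {"minor": [], "major": []}
    for p in zone_pairs:
        floor_by_pair["minor"].append(
            structure.coords[_groove_side_atoms(structure, [p], "minor")])
        floor_by_pair["major"].append(
            structure.coords[_groove_side_atoms(structure, [p], "major")])

    per_side: Dict[str, List[Tuple[float, np.ndarray]]] = {}
    for mid, dist, _, _ in minima:
        d_minor = np.min(np.linalg.norm(cmin - mid, axis=1))
        d_major = np.min(np.linalg.norm(cmaj - mid, axis=1))
        side = "minor" if d_minor < d_major else "major"
        per_side.setdefault(side, []).append((dist, mid))
    step_mids = 0.5 * (origins[:-1] + origins[1:])

    def depth_at(side: str, mid: np.ndarray) -> float:
        # nearest step: local axis line through the step midpoint
        k = int(np.argmin(np.linalg.norm(step_mids - mid, axis=1)))
        axis_pt, axis_dir = step_mids[k], axes[k]

        def radial(pts):
            rel = pts - axis_pt
            para = (rel @ axis_dir)[..., None] * axis_dir
            return np.linalg.norm(rel - para, axis=-1)
        # groove floor: base-edge atoms of the base pair nearest the
        # midpoint plus its two neighbors
        pk = int(np.argmin(np.linalg.norm(origins - mid, axis=1)))
        stack = [floor_by_pair[side][q]
                 for q in range(max(pk - 1, 0),
                                min(pk + 2, len(zone_pairs)))
                 if len(floor_by_pair[side][q])]
        near = np.vstack(stack) if stack else (cmin if side == "minor"
                                               else cmaj)
        return float(radial(mid[None, :])[0] - np.mean(radial(near)))

    for side, cands in per_side.items():
        dmin = min(c[0] for c in cands)
        width = max(dmin - params.groove_reduction, 0.0)
        # periodic duplexes show near-degenerate width minima at several
        # places along the helix; depth is a smoothly weighted mean over
        # them (weights decay with excess separation), so the value is
        # continuous in the coordinates and rigid-motion stable
        weights = np.array([math.exp(-(c[0] - dmin) / 0.01)
                            for c in cands])
        depths = np.array([depth_at(side, c[1]) for c in cands])
        depth_raw = float((weights * depths).sum() / weights.sum())
        offset = (params.depth_offset_minor if side == "minor"
                  else params.depth_offset_major)
        if side == "minor":
            shape.minor_width = width
            shape.minor_depth = depth_raw - offset
        else:
            shape.major_width = width
            shape.major_depth = depth_raw - offset
    return shape


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

def _mean_defined(values: List[Optional[float]]) -> Optional[float]:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def aggregate_shape(per_structure: Mapping[str, Sequence[GrooveShape]],
                    domain_family: Mapping[str, str]
                    ) -> Dict[str, FamilyShapeStats]:
    """Structure -> domain means, then domain -> family avg/min/max.

    ``per_structure`` maps domain_id to the shapes of its structures.
    Undefined values are skipped; a parameter undefined for every
    structure of every domain stays undefined (rendered as a dash).
    """
    domain_means: Dict[str, Dict[str, Optional[float]]] = {}
    for dom, shapes in per_structure.items():
        domain_means[dom] = {
            name: _mean_defined([getattr(s, name) for s in shapes])
            for name in PARAM_NAMES}
    families: Dict[str, FamilyShapeStats] = {}
    by_family: Dict[str, List[str]] = {}
    for dom in domain_means:
        by_family.setdefault(domain_family[dom], []).append(dom)
    for fam, doms in sorted(by_family.items()):
        stats = FamilyShapeStats(fam, {d: domain_means[d] for d in doms})
        for name in PARAM_NAMES:
            vals = [domain_means[d][name] for d in doms
                    if domain_means[d][name] is not None]
            stats.average[name] = float(np.mean(vals)) if vals else None
            stats.minimum[name] = float(np.min(vals)) if vals else None
            stats.maximum[name] = float(np.max(vals)) if vals else None
        families[fam] = stats
    return families


def shape_table(stats: Mapping[str, FamilyShapeStats]) -> str:
    """Family shape TSV (dash for parameters that cannot be computed)."""
    def fmt(v):
        return "-" if v is None else f"{v:.1f}"
    rows = ["family\tAx-bend\tMnW\tMnD\tMjW\tMjD"]
    for fam, st in sorted(stats.items()):
        rows.append("\t".join([fam] + [fmt(st.average[n])
                                       for n in PARAM_NAMES]))
    return "\n".join(rows) + "\n"
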