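"""Tunable thresholds for interface detection and DNA geometry.

All distance cutoffs are in Angstroms, angles in degrees.  The defaults
are the published decision boundaries of the interface protocol
(H-bond < 3.7 A with power > 0.1, hydrophobic < 5.4 A) together with
documented internal defaults for the steps the original pipeline
delegated to external programs (base pairing, clustering, grooves).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

#: van der Waals radii used by the line-of-sight (occlusion) test.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
VDW_DEFAULT = 1.70


@dataclass
class Params:
    """Configuration shared by all pipeline stages."""

    # --- hydrogen bonds ---
    hbond_max_dist: float = 3.7        # strict upper bound on N/O-N/O distance
    hbond_power_min: float = 0.1       # strict lower bound on bonding power
    hbond_ramp_start: float = 3.0      # distance factor is 1 below this
    # optional replacement for the built-in bonding-power formula;
    # signature: (distance, g_donor_side, g_acceptor_side) -> float
    hbond_power_fn: Optional[Callable[[float, float, float], float]] = None

    # --- hydrophobic contacts / clusters ---
    hydrophobic_max_dist: float = 5.4  # strict upper bound
    cluster_min_size: int = 5          # smallest hydrophobic cluster kept
    cluster_linkage_dist: float = 5.4  # single-linkage edge cutoff

    # --- base pairing ---
    pair_c1_min: float = 8.5           # C1'-C1' window
    pair_c1_max: float = 12.0
    pair_plane_angle_max: float = 35.0
    pair_hbond_dist: float = 3.5       # inter-base N/O-N/O distance
    pair_min_hbonds: int = 2

    # --- duplex chaining ---
    duplex_min_bp: int = 10
    stack_mid_dist: float = 5.5        # adjacent C1'-C1' midpoint distance
    gap_bridge_dist: float = 8.5       # one-nucleotide interruption bridge

    # --- covalent bonds ---
    bond_fallback_dist: float = 2.0    # unknown residues: non-H distance rule
    bond_link_max: float = 2.5         # sanity cap on template inter-residue links

    # --- contact zones and grooves ---
    zone_pad_nt: int = 2               # expansion along the chain
    zone_min_bp: int = 3               # smallest zone with defined shape
    groove_reduction: float = 5.8      # subtracted from P-spline separation
    groove_min_p: int = 3              # P atoms per strand needed for a spline
    # radial depth offsets calibrated on the ideal fiber duplex so that
    # the reference geometry reproduces minor 4.7 / major ~3.75 A depths
    depth_offset_minor: float = 1.18
    depth_offset_major: float = 0.55

    # --- misc ---
    vdw_radii: dict = field(default_factory=lambda: dict(VDW_RADII))


DEFAULT = Params()
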