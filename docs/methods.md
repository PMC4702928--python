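# Methods

This note documents the models and numerical choices behind `dnabind`:
what each pipeline stage computes, which parameters matter, what the
synthetic fixtures do and do not emulate, and where the design was
genuinely open.

## Structures and connectivity

Structures are read with gemmi. The analysis unit is one biological
assembly (the first defined in the file by default; the asymmetric unit
when none is defined). Only the first model of multi-model entries is
used; for alternate conformations the highest-occupancy conformer is
kept; waters are removed everywhere, including from occlusion tests —
water-mediated contacts are outside the contact definitions, and
retaining waters only in some structures would make occlusion depend on
resolution.

Covalent bonds come from per-residue chemical templates (20 amino
acids, deoxy- and ribonucleotides) plus peptide, phosphodiester and
disulfide links, each sanity-capped at 2.5 Å; atoms of unknown residues
fall back to a 2.0 Å distance rule. A small editable table maps common
modified residues to their parents (e.g. 5CM→DC, MSE→MET); unmapped
heteroatoms are kept — they can occlude contacts — but are never
classified into elements.

## Duplex detection

Base pairs are detected geometrically: C1′–C1′ distance in [8.5, 12.0]
Å, base-plane angle ≤ 35°, and at least two inter-base N/O–N/O
separations ≤ 3.5 Å; each nucleotide joins at most one pair, best
candidates (most H-bond-range separations, most canonical C1′–C1′
distance) first. Non-Watson–Crick pairs passing the criteria are
accepted. Pairs chain into duplexes when their C1′–C1′ midpoints are
within 5.5 Å; a single-nucleotide interruption (midpoint jump up to 8.5
Å) is bridged and recorded as a gap; longer breaks split the helix.
Runs shorter than 10 bp are discarded, and only contacts to surviving
duplexes enter the classification. All windows are `Params` fields.

## Protein elements

Residues map to three elements: helix (α, 3₁₀ and π), strand, loop
(turns, bends, isolated bridges and coil). Isolated β-bridges count as
loop because a single bridge does not make a strand segment. The
internal assignment is the classic backbone H-bond pattern method: an
electrostatic N–H···O=C energy below −0.5 kcal/mol defines a hydrogen
bond (the amide H is rebuilt 1 Å from N anti-parallel to the preceding
carbonyl); two consecutive n-turns define 3₁₀/α/π helices and bridge
ladders define strands. H-bonds are evaluated jointly across all chains
and segments, so inter-chain sheets assign correctly. Because short
3₁₀ segments are known to flip between assignment programs — and such
flips change interaction modes — Stride and DSSP report files can be
imported instead, and the source is recorded in the output.

## Contacts

Hydrogen bond: protein N/O and DNA N/O closer than 3.7 Å (strict) with
bonding power > 0.1. The power is f(d)·g(a)·g(b): f ramps linearly from
1 at 3.0 Å to 0 at 3.7 Å; g is the cosine of the angle between the
contact vector and the atom's idealized donor/acceptor direction (the
unit vector away from the mean of its covalent-neighbour directions),
clamped at zero beyond 90° and equal to 1 for atoms with no neighbours
or a symmetric environment. This form is a documented stand-in chosen
to preserve the published decision boundary (0.1 at ≤ 3.7 Å): a bond at
ideal geometry scores 1, mid-ramp ideal geometry scores 0.5, and badly
oriented pairs are rejected. An alternative formula can be plugged in
through `Params.hbond_power_fn`. Ion pairs (e.g. Lys NZ–phosphate O)
are particular cases of this rule.

Non-polar atoms are protein carbons/sulfurs with no covalently bonded
O/N, and all DNA carbons. Hydrophobic clusters are single-linkage
components over non-polar atoms, edge rule = distance < 5.4 Å *and*
clear line of sight; components under five atoms are discarded. A
hydrophobic contact joins a protein and a DNA non-polar atom meeting
the same distance and occlusion rules within one cluster. Linkage
cutoff and minimum size are configurable; single linkage with the
contact thresholds is the default.

**Line of sight.** A blocker obstructs a pair only when the
perpendicular foot of its centre falls strictly inside the open segment
and its distance to the segment axis is below its van der Waals radius
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å; hydrogens never block; the
two endpoint atoms are excluded). Requiring the foot inside the segment
is essential: every bonded neighbour's sphere contains a segment
endpoint (bond lengths are shorter than vdW radii), so a literal
"segment does not intersect any sphere" rule would reject every contact.

## Elements, modes, classes

Each contact is typed by (element of the protein residue, element of
the DNA atom). DNA elements are fixed atom lists: the sugar-phosphate
backbone (P, OP1/OP2/OP3, O5′, C5′, C4′, O4′, C3′, O3′, C2′, C1′, and
O2′ for ribose), and per-base major/minor groove edges (e.g. adenine
major {C5, C6, N6, N7, C8}, minor {N1, C2, N3, C4}). Ring-junction
atoms outside the lists (purine N9, pyrimidine N1 …) carry no element;
contacts through them are dropped from typing. Modes collapse contact
types by set semantics; a domain instance touching two duplexes in one
assembly contributes a single mode over the union. Classes are the
intersection of per-domain unions, computed only for families with at
least three distinct domain identifiers ("representatives" are domains,
not structures); the family label is free-form input, so curated
subfamily splits are data, not code.

## Contact zones and DNA shape

The contact zone is every duplex nucleotide in *any* atomic contact
with the domain (typed or not) plus nucleotides within two chain
positions, clipped at chain breaks and duplex ends. Shape is computed
when the zone covers ≥ 3 bp, on the duplex carrying the most contacts:

* **Base-pair frames** are least-squares fits of embedded standard base
  coordinates (strand II flipped 180° about x before averaging), so all
  downstream quantities are rigid-motion invariant by construction.
* **Ax-bend** is the mean angle between consecutive local helix axes,
  one axis per step, defined as the mean of the two flanking base-pair
  normals oriented along the rise. The raw screw axis of the step
  transform is *not* used: combining a ~36° twist with a small kink
  tilts the screw axis by roughly the kink divided by sin(twist/2) —
  about three times the kink itself — whereas the normal-mean axis
  spreads a single kink of β degrees over exactly β of summed
  inter-axis angle.
* **Groove widths** are minimal separations between cubic splines run
  through each strand's phosphorus atoms, minus 5.8 Å (twice the
  phosphate-group reduction of the reference convention), clamped at
  zero. Local minima of the inter-spline distance are located on a
  dense parameter grid (tolerance-inclusive, so flat basins are kept)
  and refined by bounded minimization; each minimum is attributed to
  the groove whose base-edge atoms lie nearer its midpoint. Undefined
  when a strand contributes fewer than three P atoms or a groove has no
  bracketed minimum (short zones often lose the major groove first).
* **Groove depths** are the radial offset of the width midpoint from
  the local helix axis minus the mean radial extent of the groove-side
  base atoms of the three nearest base pairs, less a per-groove
  constant (minor 1.18 Å, major 0.55 Å) calibrated once so that the
  ideal fiber duplex reports the reference depths (minor 4.7 Å, major
  ≈ 3.75 Å). Depths may be negative for splayed grooves. Periodic
  duplexes show several near-degenerate width minima; the depth is a
  smoothly weighted mean over them (weights decay with excess
  separation over 0.01 Å) so the value is continuous in the coordinates
  and stable under rigid motion. Depths are calibration-dependent and
  validated by sign and monotonicity, not by absolute reference values.

Aggregation: per domain, the mean of each parameter over its
structures (undefined values skipped); per family, average/minimum/
maximum over domains; a parameter undefined everywhere is reported as a
dash.

## Synthetic fixtures

The generator builds complexes entirely from embedded geometry.

* **Ideal B-DNA** repeats a single nucleotide unit (standard base
  coordinates plus a synthetic sugar-phosphate unit) along a 36°/3.38 Å
  helix; strand II is the dyad flip. The backbone unit is a
  least-squares fit of standard bond lengths/angles with the phosphorus
  pinned to the helix (radius 9.198 Å, phase 94.29°, offset −1.237 Å)
  whose continuous-spline groove separations equal the canonical fiber
  values (minor 11.7 Å, major 17.2 Å → widths 5.9/11.4 after the 5.8 Å
  reduction); the phosphodiester closure O3′(i)–P(i+1) comes out at
  1.61 Å. An optional single-step kink bends the fiber.
* **Peptide probes** are ideal-geometry fragments: a 12-residue
  poly-alanine α-helix, a two-strand antiparallel sheet (partner strand
  placed by a frozen rigid transform optimized once for the H-bond
  register), and a 6-residue irregular extended loop. The contact
  residue carries a long side chain — lysine (NZ) for hydrogen bonds,
  methionine (CE, leucine CD1 as fallback) for hydrophobic contacts —
  because shorter side chains cannot reach groove targets without
  pushing the fragment body into the groove walls. The probe approaches
  its designed DNA atom along a blend of the atom's idealized direction
  and the radially outward or groove-mouth direction, and orientations
  are searched (groove-aligned long axis first) until the placement is
  clash-free, realizes the designed contact with margin, and any
  incidental near-contact would map to an already-designed contact type
  through a secondary-structure-reliable (interior) residue. Placements
  that cannot satisfy this are refused rather than mislabelled.
* **Scope of the probe grid.** Minor-groove hydrophobic probes are
  generated only on loops, and helix/strand minor-groove H-bond
  fixtures underwind the duplex to 30° twist (opening the minor
  groove): in canonical fiber geometry no clash-free placement exists
  for bulky elements, mirroring how natural minor-groove readers deform
  their DNA. All nine contact types remain generatable, since a mode
  records elements, not interaction kinds.

Ground truth (designed mode, duplex length, contact/zone nucleotides)
follows from the recipe alone. The fixtures emulate geometry, not
physics: no thermal noise, no side-chain rotamer variety, no
crystallographic disorder, no solvent, and probe bodies are isolated
fragments rather than packed domains. Passing the fixture battery shows
that detection, typing and set algebra implement their definitions
exactly; it does not show robustness to the coordinate error or
conformational heterogeneity of experimental structures — for those,
the external secondary-structure import and the configurable thresholds
are the levers.

## Problem sizes

The randomized fixture battery uses 50 single-structure fixtures
(12–22 bp, 1–3 probes) and 20 family scenarios (2–4 domains, 1–2
structures each); oracle equivalence runs on ~450–560-atom complexes
against naive all-pairs implementations; invariance checks use 100
random rigid transforms per fixture. These sizes keep the full suite in
a few minutes while exercising every branch of the set algebra.

## Known limitations

* The bonding-power formula is a documented surrogate with the
  published threshold semantics, not the original database formula.
* Clustering parameters of the original hydrophobic-cluster program are
  unpublished; single linkage with the contact thresholds is assumed.
* Groove depths (not widths) depend on the calibration constants above.
* Assemblies are taken as stated in the file; no symmetry expansion
  beyond it, and NMR ensembles contribute only their first model.
* Corpus-scale results depend on the structure/domain snapshot supplied
  by the user; the package does not adjudicate corpus composition.
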