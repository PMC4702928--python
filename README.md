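# dnabind

Classification of protein domain–DNA interfaces from 3D structures.

Many DNA-binding proteins are curated into structural domain families,
but similar folds can read DNA in very different ways. `dnabind`
describes each domain–DNA complex by *which structural elements touch
which parts of the double helix*: protein **helices (H)**, **strands
(S)** and **loops (L)** versus the DNA **backbone (Bb)**, **major groove
(Mj)** and **minor groove (Mn)**. Crossing the two triples gives nine
**contact types** (H–Bb … L–Mn):

* the **interaction mode** of one domain in one structure is the set of
  contact types detected there — 2⁹ − 1 = 511 modes are formally
  possible;
* the **interaction class** of a domain family is the intersection, over
  the family's domains, of the union of each domain's modes: a type is
  *characteristic* when every domain shows it in at least one structure.
  An empty intersection makes the class *miscellaneous*; families with
  fewer than three distinct domains are not classified.

Contacts are atomic: a **hydrogen bond** joins a protein N/O to a DNA
N/O at < 3.7 Å with bonding power > 0.1 (a distance ramp times the
angular plausibility of both partners; salt bridges count as hydrogen
bonds); a **hydrophobic contact** joins two non-polar atoms (protein C/S
with no O/N neighbour; any DNA carbon) at < 5.4 Å with a clear line of
sight and shared membership in a single-linkage hydrophobic cluster of
at least five atoms. Only duplexes of ≥ 10 bp count, and the package
also reports DNA shape in each domain's **contact zone** (contacted
nucleotides ± 2 along the chain): Ax-bend and groove widths/depths from
splines through the phosphate backbones.

A synthetic-fixture generator builds ideal B-DNA plus placed peptide
probes with known ground truth, so the entire pipeline is testable
without downloading structures.

## Worked example

```python
from dnabind import (FixtureSpec, ProbeSpec, DnaElement,
                     analyze_structure, build_fixture)

# a 12-bp ideal duplex with one alpha-helix probe hydrogen-bonded to
# the major groove and one loop probe bonded to the backbone
spec = FixtureSpec("ATGCATGCATGC",
                   [ProbeSpec("helix", DnaElement.MAJOR, "hbond"),
                    ProbeSpec("loop", DnaElement.BACKBONE, "hbond")],
                   seed=7)
structure, domain, truth = build_fixture(spec)
result = analyze_structure(structure, [domain])
dr = result.domains[0]
print(dr.mode.label)
print(f"zone {dr.zone.n_bp} bp  MnW {dr.shape.minor_width:.2f} A  "
      f"MjW {dr.shape.major_width:.2f} A  Ax-bend {dr.shape.ax_bend:.2f} deg")
```

prints

```
(H-Mj) (L-Bb)
zone 11 bp  MnW 5.90 A  MjW 11.40 A  Ax-bend 0.00 deg
```

The mode string lists the detected contact types in canonical order
(protein element H < S < L, then DNA element Bb < Mj < Mn). The groove
widths are the fiber B-DNA reference values because the fixture duplex
is ideal and straight.

For real data, run the CLI on a directory of PDB/mmCIF files and a
domain-definition table (`structure_id  assembly  chain  start  end
domain_id  family_id`):

```bash
dnabind run --structures structs/ --domains domains.tsv --out report/ \
            --ss internal        # or stride/dssp with --ss-dir
dnabind make-fixtures --out demo_fixtures/
```

`report/` then contains per-structure modes (`modes.json`), per-family
classes (`classes.json`), the mode and class summary tables, and the
family shape table (Ax-bend, MnW, MnD, MjW, MjD; dashes where a
parameter cannot be computed).

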