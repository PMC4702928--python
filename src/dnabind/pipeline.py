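"""End-to-end analysis: structures + domain table -> modes, classes, shape.

For every domain instance the pipeline restricts contacts to detected
duplexes of at least ten base pairs, types each contact by the protein
element of its residue and the DNA element of its atom, collapses types
into the interaction mode, and aggregates modes into per-family
interaction classes.  DNA shape parameters are computed in each domain's
contact zone and aggregated per domain and per family.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .classify import (InteractionClass, InteractionMode, build_reports,
                       classify_corpus, interaction_mode, mode_label)
from .contacts import (Contact, detect_hydrogen_bonds,
                       detect_hydrophobic_contacts, hydrophobic_clusters,
                       nonpolar_atoms)
from .dna import DnaElement, Duplex, classify_dna_atom, detect_base_pairs, \
    detect_duplexes
from .params import Params, DEFAULT
from .protein import SSAssignment, assign_secondary_structure
from .shape import (ContactZone, FamilyShapeStats, GrooveShape,
                    aggregate_shape, base_pair_frames, contact_zone,
                    groove_geometry, shape_table)
from .structure import (DomainDefinition, Structure, domain_residues,
                        is_amino_acid, nucleotide_base)

log = logging.getLogger("dnabind")


@dataclass
class DomainResult:
    domain: DomainDefinition
    mode: InteractionMode
    contacts: List[Contact]
    zone: Optional[ContactZone]
    shape: GrooveShape


@dataclass
class StructureResult:
    structure: Structure
    duplexes: List[Duplex]
    ss: SSAssignment
    domains: List[DomainResult] = field(default_factory=list)


def _typed_contacts(structure: Structure, ss: SSAssignment,
                    raw: List[Tuple[str, int, int, float]]) -> List[Contact]:
    out: List[Contact] = []
    for kind, p_atom, d_atom, dist in raw:
        pa = structure.atoms[p_atom]
        da = structure.atoms[d_atom]
        element = classify_dna_atom(da.res_name, da.atom_name)
        if element is None:
            continue            # unlisted DNA atom: dropped from typing
        out.append(Contact(kind, pa.residue_key, da.residue_key,
                           p_atom, d_atom, dist,
                           ss.element(pa.residue_key), element))
    return out


def analyze_structure(structure: Structure,
                      domains: Sequence[DomainDefinition],
                      ss: Optional[SSAssignment] = None,
                      params: Params = DEFAULT) -> StructureResult:
    """Full single-structure analysis for its domain instances."""
    pairs = detect_base_pairs(structure, params)
    duplexes = detect_duplexes(structure, pairs, params)
    if ss is None:
        ss = assign_secondary_structure(structure)
    result = StructureResult(structure, duplexes, ss)
    if not duplexes:
        for dom in domains:
            result.domains.append(DomainResult(
                dom, interaction_mode(structure.id, dom.instance_id,
                                      dom.domain_id, dom.family_id, []),
                [], None, GrooveShape()))
        return result

    np_set = nonpolar_atoms(structure, params)
    _, atom_cluster = hydrophobic_clusters(structure, np_set, params)

    duplex_atoms: List[List[int]] = []
    for dup in duplexes:
        nts = dup.nucleotides
        duplex_atoms.append([a.index for a in structure.atoms
                             if a.residue_key in nts])

    for dom in domains:
        keys = [k for k in domain_residues(structure, dom)
                if is_amino_acid(structure.residue_name(k))]
        p_atoms = [i for k in keys for i in structure.residues[k]]
        raw: List[Tuple[str, int, int, float]] = []
        contacted_per_duplex: List[int] = []
        for dup, d_atoms in zip(duplexes, duplex_atoms):
            n_before = len(raw)
            for hb in detect_hydrogen_bonds(structure, p_atoms, d_atoms,
                                            params):
                raw.append(("hbond", hb.protein_atom, hb.dna_atom,
                            hb.distance))
            for hc in detect_hydrophobic_contacts(structure, p_atoms,
                                                  d_atoms, atom_cluster,
                                                  params):
                raw.append(("hydrophobic", hc.protein_atom, hc.dna_atom,
                            hc.distance))
            contacted_per_duplex.append(len(raw) - n_before)
        contacts = _typed_contacts(structure, ss, raw)
        mode = interaction_mode(structure.id, dom.instance_id,
                                dom.domain_id, dom.family_id, contacts)
        zone = None
        shape = GrooveShape()
        if raw:
            # shape on the duplex carrying the most contacts
            best = int(np.argmax(contacted_per_duplex))
            dup = duplexes[best]
            dup_nts = dup.nucleotides
            raw_residues = {structure.atoms[d].residue_key
                            for _, _, d, _ in raw}
            zone = contact_zone(dom.instance_id, [], dup, structure, params,
                                contacted_residues=raw_residues)
            if zone.n_bp >= params.zone_min_bp:
                frames = base_pair_frames(structure, zone.zone_pairs)
                shape = groove_geometry(structure, zone.zone_pairs, frames,
                                        params)
        result.domains.append(DomainResult(dom, mode, contacts, zone, shape))
    return result


@dataclass
class CorpusResult:
    modes: List[InteractionMode]
    classes: Dict[str, InteractionClass]
    skipped_families: Dict[str, str]
    shape_stats: Dict[str, FamilyShapeStats]
    per_structure: Dict[str, StructureResult]

    def tables(self):
        return build_reports(self.modes, self.classes)


def analyze_corpus(structures: Mapping[str, Structure],
                   domains: Sequence[DomainDefinition],
                   ss_by_structure: Optional[Mapping[str, SSAssignment]] = None,
                   params: Params = DEFAULT) -> CorpusResult:
    """Analyze a set of structures and classify their families."""
    by_structure: Dict[str, List[DomainDefinition]] = {}
    for d in domains:
        by_structure.setdefault(d.structure_id, []).append(d)
    modes: List[InteractionMode] = []
    per_structure: Dict[str, StructureResult] = {}
    shapes_by_domain: Dict[str, List[GrooveShape]] = {}
    domain_family: Dict[str, str] = {}
    for sid, doms in sorted(by_structure.items()):
        st = structures.get(sid)
        if st is None:
            log.warning("no structure loaded for %s; skipping its domains",
                        sid)
            continue
        ss = (ss_by_structure or {}).get(sid)
        res = analyze_structure(st, doms, ss, params)
        per_structure[sid] = res
        for dr in res.domains:
            modes.append(dr.mode)
            domain_family[dr.domain.domain_id] = dr.domain.family_id
            shapes_by_domain.setdefault(dr.domain.domain_id,
                                        []).append(dr.shape)
    classes, skipped = classify_corpus(modes)
    stats = aggregate_shape(shapes_by_domain, domain_family)
    return CorpusResult(modes, classes, skipped, stats, per_structure)


def write_reports(result: CorpusResult, out_dir) -> None:
    """JSON + TSV reports for a corpus analysis."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .classify import reports_to_tsv
    mode_table, class_table = result.tables()
    mt, ct = reports_to_tsv(mode_table, class_table)
    (out / "mode_table.tsv").write_text(mt)
    (out / "class_table.tsv").write_text(ct)
    (out / "shapes.tsv").write_text(shape_table(result.shape_stats))
    modes_json = [{
        "structure": m.structure_id, "domain_instance": m.domain_instance,
        "domain": m.domain_id, "family": m.family_id, "mode": m.label,
    } for m in result.modes]
    classes_json = {
        fam: {"class": cls.label, "miscellaneous": cls.miscellaneous,
              "n_domains": cls.n_domains, "n_structures": cls.n_structures}
        for fam, cls in result.classes.items()}
    classes_json.update({fam: {"class": reason}
                         for fam, reason in result.skipped_families.items()})
    (out / "modes.json").write_text(json.dumps(modes_json, indent=1))
    (out / "classes.json").write_text(json.dumps(classes_json, indent=1))
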