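"""Interaction modes of domain-DNA structures and classes of families.

A contact type is the pair (protein element, DNA element) through which
at least one atomic contact occurs; crossing {helix, strand, loop} with
{backbone, major groove, minor groove} gives exactly nine types.  The
interaction mode of a protein domain in one structure is the set of
contact types detected there (511 non-empty sets are formally possible).
The interaction class of a family is the intersection, over the family's
domains, of the union of each domain's modes: a contact type is
characteristic when every domain of the family shows it in at least one
structure.  An empty intersection makes the class "miscellaneous"; a
family with fewer than three distinct domains is not classified.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .contacts import Contact
from .dna import DnaElement
from .protein import ProteinElement

__all__ = [
    "ContactType", "InteractionMode", "InteractionClass",
    "contact_type", "interaction_mode", "enumerate_possible_modes",
    "domain_union", "family_interaction_class", "build_reports",
    "mode_label",
]

_P_ORDER = [ProteinElement.HELIX, ProteinElement.STRAND, ProteinElement.LOOP]
_D_ORDER = [DnaElement.BACKBONE, DnaElement.MAJOR, DnaElement.MINOR]


class ContactType(Enum):
    """The nine protein-element x DNA-element contact types."""

    H_BB = (ProteinElement.HELIX, DnaElement.BACKBONE)
    H_MJ = (ProteinElement.HELIX, DnaElement.MAJOR)
    H_MN = (ProteinElement.HELIX, DnaElement.MINOR)
    S_BB = (ProteinElement.STRAND, DnaElement.BACKBONE)
    S_MJ = (ProteinElement.STRAND, DnaElement.MAJOR)
    S_MN = (ProteinElement.STRAND, DnaElement.MINOR)
    L_BB = (ProteinElement.LOOP, DnaElement.BACKBONE)
    L_MJ = (ProteinElement.LOOP, DnaElement.MAJOR)
    L_MN = (ProteinElement.LOOP, DnaElement.MINOR)

    @property
    def protein_element(self) -> ProteinElement:
        return self.value[0]

    @property
    def dna_element(self) -> DnaElement:
        return self.value[1]

    @property
    def label(self) -> str:
        """ASCII machine label, e.g. 'H-Bb'."""
        return f"{self.value[0].value}-{self.value[1].value}"

    @property
    def display(self) -> str:
        """Report form, e.g. '(H - Bb)'."""
        return f"({self.value[0].value} - {self.value[1].value})"

    @property
    def sort_key(self) -> Tuple[int, int]:
        return (_P_ORDER.index(self.value[0]), _D_ORDER.index(self.value[1]))

    @classmethod
    def from_elements(cls, protein: ProteinElement, dna: DnaElement
                      ) -> "ContactType":
        return _BY_PAIR[(protein, dna)]


_BY_PAIR = {ct.value: ct for ct in ContactType}


def contact_type(contact: Contact) -> Optional[ContactType]:
    """Type of one contact; None (discard) when the DNA atom is outside
    the published element lists."""
    if contact.dna_element is None:
        return None
    return ContactType.from_elements(contact.protein_element,
                                     contact.dna_element)


def sorted_types(types: Iterable[ContactType]) -> List[ContactType]:
    return sorted(set(types), key=lambda t: t.sort_key)


def mode_label(types: Iterable[ContactType]) -> str:
    """Canonical rendering: protein element H<S<L, then DNA Bb<Mj<Mn."""
    return " ".join(f"({t.label})" for t in sorted_types(types))


@dataclass(frozen=True)
class InteractionMode:
    """Contact types of one domain instance in one structure."""

    structure_id: str
    domain_instance: str
    domain_id: str
    family_id: str
    types: FrozenSet[ContactType]

    @property
    def non_interacting(self) -> bool:
        return not self.types

    @property
    def label(self) -> str:
        return mode_label(self.types) if self.types else "non-interacting"


@dataclass(frozen=True)
class InteractionClass:
    family_id: str
    characteristic_types: FrozenSet[ContactType]
    n_domains: int
    n_structures: int

    @property
    def miscellaneous(self) -> bool:
        return not self.characteristic_types

    @property
    def label(self) -> str:
        return (mode_label(self.characteristic_types)
                if self.characteristic_types else "miscellaneous")


class TooFewDomains(ValueError):
    """Family has fewer than three distinct domains: not classified."""


def interaction_mode(structure_id: str, domain_instance: str,
                     domain_id: str, family_id: str,
                     contacts: Sequence[Contact]) -> InteractionMode:
    """Collapse the typed contacts of one domain instance into its mode.

    Contacts whose DNA atom carries no element are discarded; duplicate
    types collapse by set semantics.  A domain with no typed contacts
    yields the flagged empty (non-interacting) mode.
    """
    types = {contact_type(c) for c in contacts}
    types.discard(None)
    return InteractionMode(structure_id, domain_instance, domain_id,
                           family_id, frozenset(types))


def enumerate_possible_modes(n_types: int = len(ContactType)) -> int:
    """Number of formally possible (non-empty) interaction modes."""
    return 2 ** n_types - 1


def domain_union(modes: Sequence[InteractionMode]) -> FrozenSet[ContactType]:
    """Contact types possible for a domain: union over its structures."""
    if not modes:
        raise ValueError("domain union needs at least one mode")
    out: Set[ContactType] = set()
    for m in modes:
        out.update(m.types)
    return frozenset(out)


def family_interaction_class(per_domain_unions: Mapping[str,
                                                        FrozenSet[ContactType]],
                             family_id: str,
                             n_structures: int = 0) -> InteractionClass:
    """Intersection of per-domain unions; empty -> miscellaneous.

    Requires three or more distinct domains, else raises TooFewDomains.
    """
    if len(per_domain_unions) < 3:
        raise TooFewDomains(
            f"family {family_id}: unclassified (too few domains: "
            f"{len(per_domain_unions)})")
    unions = list(per_domain_unions.values())
    chars = frozenset(set.intersection(*[set(u) for u in unions]))
    return InteractionClass(family_id, chars, len(per_domain_unions),
                            n_structures)


# --------------------------------------------------------------------------
# corpus-level reports
# --------------------------------------------------------------------------

def classify_corpus(modes: Sequence[InteractionMode]
                    ) -> Tuple[Dict[str, InteractionClass], Dict[str, str]]:
    """Family classes from a corpus of modes.

    Returns (classes by family, skipped families -> reason).  Families
    with fewer than three distinct domains are reported as skipped.
    """
    by_family: Dict[str, List[InteractionMode]] = {}
    for m in modes:
        by_family.setdefault(m.family_id, []).append(m)
    classes: Dict[str, InteractionClass] = {}
    skipped: Dict[str, str] = {}
    for fam, fam_modes in sorted(by_family.items()):
        unions: Dict[str, Set[ContactType]] = {}
        for m in fam_modes:
            unions.setdefault(m.domain_id, set()).update(m.types)
        try:
            classes[fam] = family_interaction_class(
                {d: frozenset(u) for d, u in unions.items()},
                fam, n_structures=len(fam_modes))
        except TooFewDomains as exc:
            skipped[fam] = str(exc)
    return classes, skipped


def build_reports(modes: Sequence[InteractionMode],
                  classes: Mapping[str, InteractionClass]
                  ) -> Tuple[List[dict], List[dict]]:
    """Summary tables.

    Mode table rows: (mode, n_families, n_structures), sorted by family
    count descending then label.  Class table rows: (class, n_families,
    n_structures, n_domains).
    """
    mode_rows: Dict[str, dict] = {}
    for m in modes:
        if m.non_interacting:
            continue
        row = mode_rows.setdefault(m.label, {"mode": m.label,
                                             "families": set(),
                                             "n_structures": 0})
        row["families"].add(m.family_id)
        row["n_structures"] += 1
    mode_table = [{"mode": r["mode"], "n_families": len(r["families"]),
                   "n_structures": r["n_structures"]}
                  for r in mode_rows.values()]
    mode_table.sort(key=lambda r: (-r["n_families"], r["mode"]))

    class_rows: Dict[str, dict] = {}
    per_family_modes: Dict[str, List[InteractionMode]] = {}
    for m in modes:
        per_family_modes.setdefault(m.family_id, []).append(m)
    for fam, cls in classes.items():
        row = class_rows.setdefault(cls.label, {"class": cls.label,
                                                "n_families": 0,
                                                "n_structures": 0,
                                                "n_domains": 0})
        row["n_families"] += 1
        row["n_structures"] += cls.n_structures
        row["n_domains"] += cls.n_domains
    class_table = sorted(class_rows.values(),
                         key=lambda r: (-r["n_families"], r["class"]))
    return mode_table, class_table


def reports_to_tsv(mode_table: List[dict], class_table: List[dict]
                   ) -> Tuple[str, str]:
    mt = ["mode\tn_families\tn_structures"]
    mt += [f"{r['mode']}\t{r['n_families']}\t{r['n_structures']}"
           for r in mode_table]
    ct = ["class\tn_families\tn_structures\tn_domains"]
    ct += [f"{r['class']}\t{r['n_families']}\t{r['n_structures']}\t"
           f"{r['n_domains']}" for r in class_table]
    return "\n".join(mt) + "\n", "\n".join(ct) + "\n"
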