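"""Controlled vocabularies and the entity class hierarchy.

Three term namespaces annotate pathway models:

* ``ME_*`` — biological events carried by processes (phosphorylation,
  binding, translocation, ...).
* ``FT_*`` — feature types, i.e. modification states recorded on entities
  (e.g. ``FT_Phosphorylated``).
* ``CC_*`` — cell components, i.e. subcellular locations
  (e.g. ``CC_Nucleoplasm``).

Terms are plain namespace-prefixed strings compared by exact equality; the
vocabulary is open-world at load time (unknown terms are preserved and
reported as notices, never errors).
"""

from __future__ import annotations

import enum

ME = "ME"
FT = "FT"
CC = "CC"

_NAMESPACES = (ME, FT, CC)


class EntityClass(str, enum.Enum):
    """Molecule classes. All concrete classes are subclasses of Entity."""

    ENTITY = "Entity"
    PROTEIN = "Protein"
    DNA = "Dna"
    MRNA = "mRNA"
    SMALL_MOLECULE = "SmallMolecule"
    COMPLEX = "Complex"

    def __str__(self) -> str:  # serialize as the bare class name
        return self.value


#: every class except the root is a direct subclass of Entity
_SUBCLASSES = frozenset(EntityClass) - {EntityClass.ENTITY}


def is_a(cls: EntityClass, ancestor: EntityClass) -> bool:
    """Class-membership test respecting the hierarchy.

    ``is_a(Complex, Entity)`` is True; ``is_a(Protein, Complex)`` is False;
    every class is_a itself.
    """
    if cls == ancestor:
        return True
    return ancestor == EntityClass.ENTITY and cls in _SUBCLASSES


def namespace_of(term: str) -> str | None:
    """Return ME/FT/CC if *term* is namespace-prefixed, else None."""
    head, _, rest = term.partition("_")
    if head in _NAMESPACES and rest:
        return head
    return None


def is_valid_term(term: str, namespace: str) -> bool:
    return namespace_of(term) == namespace


# ---------------------------------------------------------------------------
# Biological-event roster.
#
# 36 events carry validation rules, organised into five constraint groups
# (the groups share a constraint template; see pathwayqc.events).

GROUP1_EVENTS = (
    "ME_Autocleavage",
    "ME_Binding",
    "ME_DNABinding",
    "ME_DNAReplication",
    "ME_Dissociation",
    "ME_GDP-GTPExchange",
    "ME_Isomerization",
    "ME_MetabolicReaction",
    "ME_ProteasomeDegradation",
    "ME_ProteinCleavage",
    "ME_UnknownDegradation",
)

GROUP2_EVENTS = (
    "ME_Acetylation",
    "ME_ADPRibosylation",
    "ME_Amidation",
    "ME_Glycosylation",
    "ME_Nitrosylation",
    "ME_Oxidation",
    "ME_Phosphorylation",
    "ME_Reduction",
    "ME_Sumoylation",
    "ME_Ubiquitination",
    "ME_UnknownActivation",
    "ME_UnknownInactivation",
    "ME_Autophosphorylation",
    "ME_Dephosphorylation",
    "ME_Deubiquitination",
)

GROUP3_EVENTS = (
    "ME_Dimerization",
    "ME_Oligomerization",
    "ME_Polymerization",
)

GROUP4_EVENTS = (
    "ME_Internalization",
    "ME_NuclearExport",
    "ME_Translocation",
)

GROUP5_EVENTS = (
    "ME_GeneExpression",
    "ME_IonTransportThroughIonChannel",
    "ME_Transcription",
    "ME_Translation",
)

RULE_COVERED_EVENTS: tuple[str, ...] = (
    GROUP1_EVENTS + GROUP2_EVENTS + GROUP3_EVENTS + GROUP4_EVENTS + GROUP5_EVENTS
)

#: events observed in curated models for which no rule exists — they have no
#: characteristics specific enough to constrain
UNCOVERED_EVENTS = (
    "ME_Cleavage",
    "ME_UnknownInteraction",
    "ME_UnknownTransition",
    "ME_Secretion",
    "ME_Recombination",
    "ME_Splicing",
    "ME_UnknownModification",
    "ME_Elongation",
)

#: events introduced by model complementation, never rule-checked
ME_UNKNOWN_PRODUCTION = "ME_UnknownProduction"
ME_UNKNOWN_DEGRADATION = "ME_UnknownDegradation"
ME_BINDING = "ME_Binding"

KNOWN_ME_TERMS = frozenset(
    RULE_COVERED_EVENTS + UNCOVERED_EVENTS + (ME_UNKNOWN_PRODUCTION,)
)

# Cell components referenced by the shipped constraint table.
CC_TERMS = (
    "CC_Extracellular",
    "CC_PlasmaMembrane",
    "CC_Cytosol",
    "CC_Cytoplasm",
    "CC_Nucleoplasm",
    "CC_Nucleus",
    "CC_Mitochondrion",
    "CC_EndoplasmicReticulum",
)
KNOWN_CC_TERMS = frozenset(CC_TERMS)
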