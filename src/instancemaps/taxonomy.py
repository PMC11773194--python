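"""Built-in node-kind registry.

An instance map describes an experimental workflow as a directed graph.
Twelve node kinds are available, grouped into four categories:

* **instance-family** — ``Instance`` (the test object in its medium at a
  moment in time), ``Material`` and ``Medium`` (the components that define
  an instance);
* **protocol** — transformation, sample-preparation, measurement and
  data-processing protocols, each linkable to an SOP, protocol document or
  ELN page;
* **property** — curated (taken from literature), computed (model- or
  algorithm-derived) and experimental (measured) properties;
* **data** — raw data (the first dataset an experiment produces) and
  processed data (anything derived downstream).

Each kind carries *requirement slots*: the pieces of supporting metadata a
node of that kind should carry, or link to, for the study description to be
considered complete.  The completeness engine in
:mod:`instancemaps.validation` scores nodes against these slots.

The historical NIKC curation vocabulary (five categories: instance,
material, medium, property, supplementary) predates this taxonomy; legacy
curation tables are translated through :func:`map_legacy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Union

from .errors import UnknownKindError, UnknownLegacyTermError

__all__ = [
    "NodeKind",
    "NodeCategory",
    "RequirementSlot",
    "KindSpec",
    "Taxonomy",
    "LEGACY_TERMS",
    "AttachmentDirective",
    "builtin_taxonomy",
    "requirements_for",
    "map_legacy",
    "taxonomy_reference",
    "CATEGORY_COLOURS",
]


class NodeKind(str, Enum):
    """The twelve node kinds of the instance-map taxonomy."""

    INSTANCE = "Instance"
    MATERIAL = "Material"
    MEDIUM = "Medium"
    TRANSFORMATION_PROTOCOL = "TransformationProtocol"
    SAMPLE_PREPARATION_PROTOCOL = "SamplePreparationProtocol"
    MEASUREMENT_PROTOCOL = "MeasurementProtocol"
    DATA_PROCESSING_PROTOCOL = "DataProcessingProtocol"
    CURATED_PROPERTY = "CuratedProperty"
    COMPUTED_PROPERTY = "ComputedProperty"
    EXPERIMENTAL_PROPERTY = "ExperimentalProperty"
    RAW_DATA = "RawData"
    PROCESSED_DATA = "ProcessedData"


class NodeCategory(str, Enum):
    """The four categories partitioning the twelve kinds."""

    INSTANCE_FAMILY = "instance-family"
    PROTOCOL = "protocol"
    PROPERTY = "property"
    DATA = "data"


#: Default node colour per category.  Instances are drawn in blue, protocols
#: in purple, properties in orange and data in red; the exact hex values are
#: a rendering choice of this package.
CATEGORY_COLOURS: dict[NodeCategory, str] = {
    NodeCategory.INSTANCE_FAMILY: "#6baed6",
    NodeCategory.PROTOCOL: "#9e9ac8",
    NodeCategory.PROPERTY: "#fd8d3c",
    NodeCategory.DATA: "#e34a33",
}

#: The five-term vocabulary of the original NIKC curation tables.
LEGACY_TERMS: tuple[str, ...] = (
    "instance",
    "material",
    "medium",
    "property",
    "supplementary",
)

PROPERTY_KINDS: frozenset[NodeKind] = frozenset(
    {
        NodeKind.CURATED_PROPERTY,
        NodeKind.COMPUTED_PROPERTY,
        NodeKind.EXPERIMENTAL_PROPERTY,
    }
)


@dataclass(frozen=True)
class RequirementSlot:
    """One piece of supporting metadata a node kind should cover.

    A slot is *satisfied* when the node has a metadata field, or an attached
    resource link with a role, whose name appears in ``satisfied_by``.
    """

    slot_id: str
    label: str
    satisfied_by: frozenset[str]


@dataclass(frozen=True)
class KindSpec:
    kind: NodeKind
    category: NodeCategory
    description: str
    requirement_slots: tuple[RequirementSlot, ...] = field(default_factory=tuple)

    @property
    def colour(self) -> str:
        return CATEGORY_COLOURS[self.category]


Taxonomy = dict[NodeKind, KindSpec]


def _slot(slot_id: str, label: str, *satisfied_by: str) -> RequirementSlot:
    return RequirementSlot(slot_id, label, frozenset(satisfied_by))


_PROTOCOL_SATISFIERS = ("protocol", "sop", "eln_page", "protocol_document", "video")

_BUILTIN: Taxonomy = {
    spec.kind: spec
    for spec in (
        KindSpec(
            NodeKind.INSTANCE,
            NodeCategory.INSTANCE_FAMILY,
            "The test material (or other object of interest) in its chemical,"
            " biological and/or product environment at a specific moment in"
            " time; a physical or chemical change creates a new instance.",
            (
                _slot(
                    "component_listing",
                    "listing of all components (materials and media) defining"
                    " the current life cycle stage of the material/sample",
                    "components", "data_file", "eln_page",
                ),
                _slot(
                    "provenance_setup",
                    "bibliographic and provenance data defining the setup",
                    "provenance", "setup", "reference", "data_file",
                ),
            ),
        ),
        KindSpec(
            NodeKind.MATERIAL,
            NodeCategory.INSTANCE_FAMILY,
            "Compositional and structural information about the test object.",
            (
                _slot(
                    "full_characterisation",
                    "full characterisation of material including, e.g.,"
                    " chemical composition, size, shape/structure, and/or"
                    " NanoInChI",
                    "characterisation", "chemical_composition", "size",
                    "shape", "nanoinchi", "data_file",
                ),
            ),
        ),
        KindSpec(
            NodeKind.MEDIUM,
            NodeCategory.INSTANCE_FAMILY,
            "Description of the surroundings of the test object, e.g. a"
            " solvent, biological model or product matrix.",
            (
                _slot(
                    "recipe_or_identifier",
                    "recipe of medium and/or identifier of medium and its"
                    " constituents",
                    "recipe", "medium_identifier", "constituents",
                    "data_file", "sop",
                ),
            ),
        ),
        KindSpec(
            NodeKind.TRANSFORMATION_PROTOCOL,
            NodeCategory.PROTOCOL,
            "Experimental details of changes to the object or its"
            " surroundings that drive a change in physicochemical properties.",
            (
                _slot(
                    "protocol_reference",
                    "protocol document/video, SOP, and/or ELN workflow",
                    *_PROTOCOL_SATISFIERS,
                ),
            ),
        ),
        KindSpec(
            NodeKind.SAMPLE_PREPARATION_PROTOCOL,
            NodeCategory.PROTOCOL,
            "Experimental details of sample preparation, e.g. dispersion,"
            " mixing, or presentation to test organisms/environment.",
            (
                _slot(
                    "protocol_reference",
                    "protocol document/video, SOP, and/or ELN workflow",
                    *_PROTOCOL_SATISFIERS,
                ),
            ),
        ),
        KindSpec(
            NodeKind.MEASUREMENT_PROTOCOL,
            NodeCategory.PROTOCOL,
            "Experimental details of the measurement performed.",
            (
                _slot(
                    "instrument_metadata",
                    "instrument metadata, software metadata, instrument"
                    " settings/input parameters",
                    "instrument", "instrument_settings", "software",
                    "input_parameters", "data_file",
                ),
                _slot(
                    "protocol_reference",
                    "protocol document/video, SOP, and/or ELN workflow",
                    *_PROTOCOL_SATISFIERS,
                ),
            ),
        ),
        KindSpec(
            NodeKind.DATA_PROCESSING_PROTOCOL,
            NodeCategory.PROTOCOL,
            "Step-by-step description of the data processing.",
            (
                _slot(
                    "processing_description",
                    "data processing pipeline, software details, statistical"
                    " test details, equations utilised, and blanks/controls",
                    "pipeline", "software", "statistical_tests", "equations",
                    "blanks_controls", "notebook", *_PROTOCOL_SATISFIERS,
                ),
            ),
        ),
        KindSpec(
            NodeKind.CURATED_PROPERTY,
            NodeCategory.PROPERTY,
            "A property of the object extracted from a publication"
            " (secondary data).",
            (
                _slot(
                    "bibliography_or_value",
                    "bibliographic information and/or link to numeric"
                    " value/data",
                    "reference", "bibliography", "value", "data_file",
                    "publication",
                ),
            ),
        ),
        KindSpec(
            NodeKind.COMPUTED_PROPERTY,
            NodeCategory.PROPERTY,
            "A property calculated or predicted using a model or algorithm.",
            (
                _slot(
                    "model_and_software",
                    "model/algorithm name and software used to compute the"
                    " property, and/or link to numeric value/data",
                    "model", "algorithm", "software", "value", "data_file",
                    "source_code",
                ),
            ),
        ),
        KindSpec(
            NodeKind.EXPERIMENTAL_PROPERTY,
            NodeCategory.PROPERTY,
            "A property measured experimentally.",
            (
                _slot(
                    "assay_metadata",
                    "assay name, instrument metadata (if relevant), organism"
                    " metadata (if relevant), and/or link to numeric"
                    " value/data",
                    "assay", "instrument", "organism", "value", "data_file",
                ),
            ),
        ),
        KindSpec(
            NodeKind.RAW_DATA,
            NodeCategory.DATA,
            "Data retrieved directly from observation, measurement or"
            " computation.",
            (
                _slot(
                    "raw_dataset",
                    "first set of data produced by a specific experiment",
                    "dataset", "value", "raw_data", "data_file",
                ),
            ),
        ),
        KindSpec(
            NodeKind.PROCESSED_DATA,
            NodeCategory.DATA,
            "Data produced from raw data by e.g. background subtraction,"
            " normalisation or calculation.",
            (
                _slot(
                    "processed_dataset",
                    "second and any other downstream set of data generated"
                    " from raw data",
                    "dataset", "derivation", "processed_data", "data_file",
                ),
            ),
        ),
    )
}


def builtin_taxonomy() -> Taxonomy:
    """Return the built-in registry mapping each :class:`NodeKind` to its spec.

    The registry is deterministic across calls; a fresh dict is returned so
    callers may extend their copy without mutating the built-in one.
    """
    return dict(_BUILTIN)


def coerce_kind(kind: Union[NodeKind, str]) -> NodeKind:
    """Normalise a kind name to :class:`NodeKind`, raising on unknown kinds."""
    if isinstance(kind, NodeKind):
        return kind
    try:
        return NodeKind(kind)
    except ValueError:
        raise UnknownKindError(f"unknown node kind: {kind!r}") from None


def requirements_for(kind: Union[NodeKind, str]) -> list[RequirementSlot]:
    """Requirement slots (information to be covered) for ``kind``."""
    return list(_BUILTIN[coerce_kind(kind)].requirement_slots)


@dataclass(frozen=True)
class AttachmentDirective:
    """Directive produced by :func:`map_legacy` for 'supplementary' rows.

    A legacy *supplementary* is visual support material for a property (an
    image or diagram); it does not become a node but a resource link with the
    given role on the preceding property node.
    """

    role: str = "supplementary"


def map_legacy(
    term: str,
    property_default: NodeKind = NodeKind.CURATED_PROPERTY,
) -> Union[NodeKind, AttachmentDirective]:
    """Translate one NIKC five-category term into the current taxonomy.

    ``instance``, ``material`` and ``medium`` map to their same-named kinds;
    ``property`` maps to ``property_default`` (the original curation effort
    extracted all data from publications, hence the ``CuratedProperty``
    default); ``supplementary`` yields an :class:`AttachmentDirective`.
    """
    if property_default not in PROPERTY_KINDS:
        raise UnknownKindError(
            f"property_default must be a property kind, got {property_default!r}"
        )
    mapping: dict[str, Union[NodeKind, AttachmentDirective]] = {
        "instance": NodeKind.INSTANCE,
        "material": NodeKind.MATERIAL,
        "medium": NodeKind.MEDIUM,
        "property": property_default,
        "supplementary": AttachmentDirective(),
    }
    try:
        return mapping[term]
    except KeyError:
        raise UnknownLegacyTermError(f"unknown legacy term: {term!r}") from None


def taxonomy_reference() -> dict:
    """The taxonomy as a plain JSON-serialisable reference document.

    Intended for documentation and for authors of validation-profile config
    files who need the exact kind/category/slot identifiers.
    """
    return {
        "kinds": [
            {
                "kind": spec.kind.value,
                "category": spec.category.value,
                "colour": spec.colour,
                "description": spec.description,
                "requirement_slots": [
                    {
                        "slot_id": slot.slot_id,
                        "label": slot.label,
                        "satisfied_by": sorted(slot.satisfied_by),
                    }
                    for slot in spec.requirement_slots
                ],
            }
            for spec in _BUILTIN.values()
        ],
        "categories": [
            {"category": cat.value, "colour": col}
            for cat, col in CATEGORY_COLOURS.items()
        ],
        "legacy_terms": list(LEGACY_TERMS),
    }
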