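"""The instance-map graph document.

An :class:`InstanceMap` is a directed, often tree-like graph whose main
branches are consecutive instances of the studied object, with side branches
for materials, media, properties, protocols and data.  Edge direction
encodes flow and time: for instance→instance edges the source precedes the
target.

Construction goes through the functional ops (:func:`new_map`,
:func:`add_node`, :func:`add_edge`, ...), each of which returns an updated
copy and enforces referential integrity.  Maps built any other way (e.g.
parsed from a document with relaxed reference checking) may carry dangling
references; the validator reports those rather than crashing.
"""

from __future__ import annotations

import re
from datetime import date
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import (
    BadIdError,
    DanglingReferenceError,
    DuplicateEdgeError,
    DuplicateNodeError,
)
from .taxonomy import CATEGORY_COLOURS, NodeKind, Taxonomy, builtin_taxonomy

__all__ = [
    "ResourceLink",
    "NodeMeta",
    "Node",
    "Edge",
    "Region",
    "MapLink",
    "InstanceMap",
    "new_map",
    "add_node",
    "add_edge",
    "add_region",
    "attach_resource",
    "effective_colour",
    "ID_PATTERN",
]

ID_PATTERN = re.compile(r"^[A-Za-z0-9_.-]+$")


class _Model(BaseModel):
    model_config = ConfigDict(validate_assignment=True, extra="forbid")


class ResourceLink(_Model):
    """A link (URL or relative path) from a node to a supporting resource.

    ``role`` says what the resource is to the node (``protocol``, ``sop``,
    ``raw_data``, ``supplementary``, ``eln_page``, ...); roles participate in
    completeness checking.  Content is stored opaquely and never fetched.
    """

    target: str
    role: str = "data_file"
    media_hint: Optional[str] = None

    @field_validator("target")
    @classmethod
    def _target_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("resource link target must be non-empty")
        return v


class NodeMeta(_Model):
    """Descriptive metadata carried by a map or an individual node."""

    description: Optional[str] = None
    keywords: list[str] = Field(default_factory=list)
    version: Optional[str] = None
    created: Optional[str] = None
    licence: Optional[str] = None
    contributors: list[str] = Field(default_factory=list)
    references: list[str] = Field(default_factory=list)

    @field_validator("created")
    @classmethod
    def _created_iso(cls, v: Optional[str]) -> Optional[str]:
        if v is not None:
            date.fromisoformat(v)
        return v


class Node(_Model):
    id: str
    kind: NodeKind
    label: str = ""
    meta: NodeMeta = Field(default_factory=NodeMeta)
    fields: dict[str, str] = Field(default_factory=dict)
    links: list[ResourceLink] = Field(default_factory=list)
    colour_override: Optional[str] = None

    @field_validator("id")
    @classmethod
    def _id_wellformed(cls, v: str) -> str:
        if not ID_PATTERN.match(v):
            raise ValueError(f"malformed node id: {v!r}")
        return v


class Edge(_Model):
    """A directed edge; the arrow points forward in workflow order/time."""

    source: str
    target: str
    label: Optional[str] = None

    @property
    def key(self) -> tuple[str, str, Optional[str]]:
        return (self.source, self.target, self.label)


class Region(_Model):
    """A named, optionally coloured annotation over a set of nodes.

    Regions highlight phases or sections of a workflow (e.g. a synthesis
    phase vs. an exposure phase); they may overlap.
    """

    id: str
    label: str = ""
    member_ids: set[str] = Field(default_factory=set)
    colour: Optional[str] = None


class MapLink(_Model):
    """A cross-map link from a local node into a node of another map.

    Target resolution is deferred: maps travel separately, so an unresolved
    target is a warning during workspace resolution, never an error.
    """

    source_node: str
    target_map: str
    target_node: str
    relation: str = ""


class InstanceMap(_Model):
    """The directed-graph study description document."""

    id: str
    meta: NodeMeta = Field(default_factory=NodeMeta)
    nodes: dict[str, Node] = Field(default_factory=dict)
    edges: list[Edge] = Field(default_factory=list)
    regions: list[Region] = Field(default_factory=list)
    map_links: list[MapLink] = Field(default_factory=list)

    @field_validator("id")
    @classmethod
    def _id_wellformed(cls, v: str) -> str:
        if not ID_PATTERN.match(v):
            raise ValueError(f"malformed map id: {v!r}")
        return v

    @field_validator("nodes")
    @classmethod
    def _keys_match(cls, v: dict[str, Node]) -> dict[str, Node]:
        for key, node in v.items():
            if key != node.id:
                raise ValueError(f"nodes key {key!r} does not match node id {node.id!r}")
        return v

    def node_ids(self) -> set[str]:
        return set(self.nodes)

    def __eq__(self, other: object) -> bool:
        """Canonical equality: edge, region and map-link order is not
        semantically meaningful, so two maps differing only in list order
        compare equal (and round-tripping through the canonical document
        preserves equality)."""
        if not isinstance(other, InstanceMap):
            return NotImplemented
        return (
            self.id == other.id
            and self.meta == other.meta
            and self.nodes == other.nodes
            and sorted(self.edges, key=lambda e: (e.source, e.target, e.label or ""))
            == sorted(other.edges, key=lambda e: (e.source, e.target, e.label or ""))
            and sorted(self.regions, key=lambda r: r.id)
            == sorted(other.regions, key=lambda r: r.id)
            and sorted(self.map_links, key=lambda ml: (
                ml.source_node, ml.target_map, ml.target_node, ml.relation))
            == sorted(other.map_links, key=lambda ml: (
                ml.source_node, ml.target_map, ml.target_node, ml.relation))
        )

    __hash__ = None  # mutable container


def new_map(id: str, meta: Optional[NodeMeta] = None) -> InstanceMap:
    """Create an empty map with well-formed ``id``."""
    if not ID_PATTERN.match(id):
        raise BadIdError(f"malformed map id: {id!r}")
    return InstanceMap(id=id, meta=meta or NodeMeta())


def add_node(m: InstanceMap, node: Node) -> InstanceMap:
    """Return ``m`` with ``node`` added; duplicate ids are rejected."""
    if node.id in m.nodes:
        raise DuplicateNodeError(f"duplicate node id: {node.id!r}")
    out = m.model_copy(deep=True)
    out.nodes[node.id] = node.model_copy(deep=True)
    return out


def add_edge(m: InstanceMap, edge: Edge) -> InstanceMap:
    """Return ``m`` with ``edge`` added; both endpoints must exist."""
    for endpoint in (edge.source, edge.target):
        if endpoint not in m.nodes:
            raise DanglingReferenceError(f"edge endpoint not in map: {endpoint!r}")
    if edge.key in {e.key for e in m.edges}:
        raise DuplicateEdgeError(f"duplicate edge: {edge.key!r}")
    out = m.model_copy(deep=True)
    out.edges.append(edge.model_copy())
    return out


def add_region(m: InstanceMap, region: Region) -> InstanceMap:
    """Return ``m`` with ``region`` added; all members must exist."""
    missing = region.member_ids - set(m.nodes)
    if missing:
        raise DanglingReferenceError(f"region members not in map: {sorted(missing)}")
    out = m.model_copy(deep=True)
    out.regions.append(region.model_copy(deep=True))
    return out


def attach_resource(m: InstanceMap, node_id: str, link: ResourceLink) -> InstanceMap:
    """Return ``m`` with ``link`` attached to node ``node_id``."""
    if node_id not in m.nodes:
        raise DanglingReferenceError(f"node not in map: {node_id!r}")
    out = m.model_copy(deep=True)
    out.nodes[node_id].links.append(link.model_copy())
    return out


def add_map_link(m: InstanceMap, link: MapLink) -> InstanceMap:
    """Return ``m`` with a cross-map link added; the local source must exist."""
    if link.source_node not in m.nodes:
        raise DanglingReferenceError(f"node not in map: {link.source_node!r}")
    out = m.model_copy(deep=True)
    out.map_links.append(link.model_copy())
    return out


def effective_colour(node: Node, taxonomy: Optional[Taxonomy] = None) -> str:
    """The colour a renderer should use for ``node``.

    An explicit ``colour_override`` wins; otherwise the default colour of the
    kind's category.  Overrides are purely presentational — validation and
    completeness never look at them (workflows deliberately "misuse" colour,
    e.g. flagging undecided planning nodes in the data-category red).
    """
    if node.colour_override:
        return node.colour_override
    tax = taxonomy if taxonomy is not None else builtin_taxonomy()
    return CATEGORY_COLOURS[tax[node.kind].category]
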