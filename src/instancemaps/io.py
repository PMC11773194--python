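"""Serialisation and format conversion.

The canonical on-disk form is JSON with ``format_version`` ``"1.0"``:
nodes sorted by id, edges by (source, target, label), fixed key order and
UTF-8 throughout, so that serialising the same map twice is byte-identical
and documents diff cleanly under ordinary version control.  YAML is
accepted on read (it is a JSON superset and common for hand-written
configs); writing is JSON only, to avoid dialect drift.

Exports to DOT, Mermaid and GraphML carry each node's kind, label and
effective colour, so map overviews stay colour-coded by category outside
the package.  Legacy five-category curation tables (CSV) are imported via
the taxonomy's legacy-term mapping.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import yaml
from pydantic import ValidationError

from .errors import (
    FormatError,
    FormatVersionError,
    OrphanSupplementaryError,
    SchemaError,
    UnknownLegacyTermError,
)
from .model import (
    Edge,
    InstanceMap,
    MapLink,
    Node,
    NodeMeta,
    Region,
    ResourceLink,
    effective_colour,
)
from .taxonomy import (
    AttachmentDirective,
    NodeKind,
    Taxonomy,
    builtin_taxonomy,
    map_legacy,
)

__all__ = [
    "FORMAT_VERSION",
    "to_document",
    "from_document",
    "load_map",
    "save_map",
    "export",
    "import_legacy_table",
    "read_legacy_csv",
]

FORMAT_VERSION = "1.0"


# --------------------------------------------------------------------------
# canonical document


def _meta_dict(meta: NodeMeta) -> dict:
    out: dict = {}
    for key in ("description", "keywords", "version", "created", "licence",
                "contributors", "references"):
        value = getattr(meta, key)
        if value:
            out[key] = value
    return out


def _node_dict(node: Node) -> dict:
    out: dict = {"id": node.id, "kind": node.kind.value, "label": node.label}
    meta = _meta_dict(node.meta)
    if meta:
        out["meta"] = meta
    if node.fields:
        out["fields"] = {k: node.fields[k] for k in sorted(node.fields)}
    if node.links:
        out["links"] = [
            {k: v for k, v in (("target", ln.target), ("role", ln.role),
                               ("media_hint", ln.media_hint)) if v is not None}
            for ln in node.links
        ]
    if node.colour_override:
        out["colour_override"] = node.colour_override
    return out


def _edge_sort_key(e: Edge) -> tuple:
    return (e.source, e.target, e.label or "")


def to_document(m: InstanceMap) -> str:
    """Serialise to canonical JSON text (byte-stable for equal maps)."""
    doc = {
        "format_version": FORMAT_VERSION,
        "map": {"id": m.id, "meta": _meta_dict(m.meta)},
        "nodes": [_node_dict(m.nodes[nid]) for nid in sorted(m.nodes)],
        "edges": [
            {k: v for k, v in (("source", e.source), ("target", e.target),
                               ("label", e.label)) if v is not None}
            for e in sorted(m.edges, key=_edge_sort_key)
        ],
        "regions": [
            {k: v for k, v in (("id", r.id), ("label", r.label),
                               ("member_ids", sorted(r.member_ids)),
                               ("colour", r.colour)) if v is not None}
            for r in sorted(m.regions, key=lambda r: r.id)
        ],
        "map_links": [
            {"source_node": ml.source_node, "target_map": ml.target_map,
             "target_node": ml.target_node, "relation": ml.relation}
            for ml in sorted(m.map_links, key=lambda ml: (
                ml.source_node, ml.target_map, ml.target_node, ml.relation))
        ],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


def _pointer(prefix: str, err: ValidationError) -> SchemaError:
    first = err.errors()[0]
    loc = "/".join(str(p) for p in first["loc"])
    location = f"{prefix}/{loc}" if loc else prefix
    return SchemaError(first["msg"], location)


def from_document(text: str, check_refs: bool = True) -> InstanceMap:
    """Parse a canonical JSON (or YAML) document into an :class:`InstanceMap`.

    With ``check_refs`` (the default), referential breakage — an edge,
    region or map link naming an unknown node — is a :class:`SchemaError`
    whose location points at the offending list entry.  With
    ``check_refs=False`` the map loads anyway and the validator reports the
    breakage as rule R1, which is what batch checking pipelines want.
    """
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise SchemaError(f"input is neither valid JSON nor YAML: {exc}", "")
    if not isinstance(data, dict):
        raise SchemaError("document root must be an object", "")
    version = data.get("format_version")
    if version is None:
        raise FormatVersionError("document has no format_version")
    if version != FORMAT_VERSION:
        raise FormatVersionError(
            f"unsupported format_version {version!r} (expected {FORMAT_VERSION!r})")

    map_block = data.get("map")
    if not isinstance(map_block, dict) or "id" not in map_block:
        raise SchemaError("missing or malformed 'map' block with an 'id'", "/map")
    try:
        meta = NodeMeta.model_validate(map_block.get("meta") or {})
    except ValidationError as exc:
        raise _pointer("/map/meta", exc) from None

    nodes: dict[str, Node] = {}
    for i, raw in enumerate(data.get("nodes") or []):
        try:
            node = Node.model_validate(raw)
        except ValidationError as exc:
            raise _pointer(f"/nodes/{i}", exc) from None
        if node.id in nodes:
            raise SchemaError(f"duplicate node id {node.id!r}", f"/nodes/{i}/id")
        nodes[node.id] = node

    edges: list[Edge] = []
    for i, raw in enumerate(data.get("edges") or []):
        try:
            edge = Edge.model_validate(raw)
        except ValidationError as exc:
            raise _pointer(f"/edges/{i}", exc) from None
        if check_refs:
            for field_name, endpoint in (("source", edge.source), ("target", edge.target)):
                if endpoint not in nodes:
                    raise SchemaError(
                        f"edge references unknown node {endpoint!r}",
                        f"/edges/{i}/{field_name}")
        edges.append(edge)

    regions: list[Region] = []
    for i, raw in enumerate(data.get("regions") or []):
        try:
            region = Region.model_validate(raw)
        except ValidationError as exc:
            raise _pointer(f"/regions/{i}", exc) from None
        if check_refs:
            missing = region.member_ids - set(nodes)
            if missing:
                raise SchemaError(
                    f"region references unknown nodes {sorted(missing)}",
                    f"/regions/{i}/member_ids")
        regions.append(region)

    map_links: list[MapLink] = []
    for i, raw in enumerate(data.get("map_links") or []):
        try:
            ml = MapLink.model_validate(raw)
        except ValidationError as exc:
            raise _pointer(f"/map_links/{i}", exc) from None
        if check_refs and ml.source_node not in nodes:
            raise SchemaError(
                f"map link references unknown local node {ml.source_node!r}",
                f"/map_links/{i}/source_node")
        map_links.append(ml)

    try:
        return InstanceMap(id=map_block["id"], meta=meta, nodes=nodes,
                           edges=edges, regions=regions, map_links=map_links)
    except ValidationError as exc:
        raise _pointer("/map", exc) from None


def load_map(path: Union[str, Path], check_refs: bool = True) -> InstanceMap:
    return from_document(Path(path).read_text(encoding="utf-8"), check_refs=check_refs)


def save_map(m: InstanceMap, path: Union[str, Path]) -> None:
    Path(path).write_text(to_document(m), encoding="utf-8")


# --------------------------------------------------------------------------
# graph/diagram export


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _first_region_assignment(m: InstanceMap) -> dict[str, str]:
    """Node id → id of the first region containing it (DOT/Mermaid clusters
    cannot overlap, so overlapping regions keep only their first claim)."""
    assignment: dict[str, str] = {}
    for region in m.regions:
        for nid in sorted(region.member_ids):
            assignment.setdefault(nid, region.id)
    return assignment


def _to_dot(m: InstanceMap, tax: Taxonomy) -> str:
    lines = [f'digraph "{_dot_escape(m.id)}" {{', "  rankdir=TB;",
             "  node [style=filled];"]
    assignment = _first_region_assignment(m)

    def node_stmt(nid: str, indent: str) -> str:
        node = m.nodes[nid]
        label = _dot_escape(node.label or nid)
        colour = effective_colour(node, tax)
        return (f'{indent}"{_dot_escape(nid)}" [label="{label}", '
                f'kind="{node.kind.value}", fillcolor="{colour}"];')

    for region in sorted(m.regions, key=lambda r: r.id):
        lines.append(f'  subgraph "cluster_{_dot_escape(region.id)}" {{')
        lines.append(f'    label="{_dot_escape(region.label or region.id)}";')
        if region.colour:
            lines.append(f'    color="{_dot_escape(region.colour)}";')
        for nid in sorted(region.member_ids):
            if assignment.get(nid) == region.id and nid in m.nodes:
                lines.append(node_stmt(nid, "    "))
        lines.append("  }")
    for nid in sorted(m.nodes):
        if nid not in assignment:
            lines.append(node_stmt(nid, "  "))
    for e in sorted(m.edges, key=_edge_sort_key):
        attr = f' [label="{_dot_escape(e.label)}"]' if e.label else ""
        lines.append(f'  "{_dot_escape(e.source)}" -> "{_dot_escape(e.target)}"{attr};')
    lines.append("}")
    return "\n".join(lines) + "\n"


_MERMAID_SHAPES = {
    # shape per category: rectangle, hexagon, rounded, parallelogram
    "instance-family": ('["{}"]'),
    "protocol": ('{{{{"{}"}}}}'),
    "property": ('("{}")'),
    "data": ('[/"{}"/]'),
}


def _mermaid_ids(m: InstanceMap) -> dict[str, str]:
    """Deterministic Mermaid-safe identifier per node."""
    return {nid: f"n{i}" for i, nid in enumerate(sorted(m.nodes))}


def _to_mermaid(m: InstanceMap, tax: Taxonomy) -> str:
    ids = _mermaid_ids(m)
    assignment = _first_region_assignment(m)
    lines = ["flowchart TD"]

    def node_stmt(nid: str, indent: str) -> str:
        node = m.nodes[nid]
        shape = _MERMAID_SHAPES[tax[node.kind].category.value]
        label = (node.label or nid).replace('"', "'")
        return f"{indent}{ids[nid]}{shape.format(label)}"

    for region in sorted(m.regions, key=lambda r: r.id):
        label = (region.label or region.id).replace('"', "'")
        lines.append(f'  subgraph {region.id.replace(".", "_")} ["{label}"]')
        for nid in sorted(region.member_ids):
            if assignment.get(nid) == region.id and nid in m.nodes:
                lines.append(node_stmt(nid, "    "))
        lines.append("  end")
    for nid in sorted(m.nodes):
        if nid not in assignment:
            lines.append(node_stmt(nid, "  "))
    for e in sorted(m.edges, key=_edge_sort_key):
        if e.source not in ids or e.target not in ids:
            continue
        if e.label:
            lines.append(f'  {ids[e.source]} -- "{e.label}" --> {ids[e.target]}')
        else:
            lines.append(f"  {ids[e.source]} --> {ids[e.target]}")
    for nid in sorted(m.nodes):
        lines.append(f"  style {ids[nid]} fill:{effective_colour(m.nodes[nid], tax)}")
    return "\n".join(lines) + "\n"


def _to_graphml(m: InstanceMap, tax: Taxonomy) -> str:
    g = nx.MultiDiGraph()
    region_of: dict[str, list[str]] = {}
    for region in sorted(m.regions, key=lambda r: r.id):
        for nid in region.member_ids:
            region_of.setdefault(nid, []).append(region.id)
    for nid in sorted(m.nodes):
        node = m.nodes[nid]
        attrs = {
            "kind": node.kind.value,
            "category": tax[node.kind].category.value,
            "label": node.label,
            "colour": effective_colour(node, tax),
        }
        if nid in region_of:
            attrs["regions"] = ",".join(region_of[nid])
        g.add_node(nid, **attrs)
    for e in sorted(m.edges, key=_edge_sort_key):
        if e.source in m.nodes and e.target in m.nodes:
            g.add_edge(e.source, e.target, label=e.label or "")
    return "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"


def export(m: InstanceMap, format: str, taxonomy: Optional[Taxonomy] = None) -> str:
    """Render the map as ``dot``, ``mermaid`` or ``graphml`` text.

    Every node yields exactly one node statement carrying its kind, label
    and effective colour; regions become clusters/subgraphs where the
    format supports them (overlapping regions are flattened to the first
    claim; GraphML stores memberships as a node attribute instead).
    """
    tax = taxonomy if taxonomy is not None else builtin_taxonomy()
    renderers = {"dot": _to_dot, "mermaid": _to_mermaid, "graphml": _to_graphml}
    if format not in renderers:
        raise FormatError(f"unknown export format: {format!r}")
    return renderers[format](m, tax)


# --------------------------------------------------------------------------
# legacy NIKC-table import


def _slug(name: str, taken: set[str]) -> str:
    base = "".join(c if c.isalnum() else "_" for c in name.strip().lower()).strip("_")
    base = base or "node"
    slug, i = base, 1
    while slug in taken:
        i += 1
        slug = f"{base}_{i}"
    taken.add(slug)
    return slug


def import_legacy_table(
    rows: Iterable[Sequence[str]],
    property_default: NodeKind = NodeKind.CURATED_PROPERTY,
    map_id: str = "legacy-import",
) -> InstanceMap:
    """Build a map from a five-category NIKC-style curation table.

    Each row is ``(category, name, value, link)``.  Rows are expected in
    curation order: material/medium/property rows follow the instance they
    describe.  Consecutive instances are chained in time order; material
    and medium nodes point into their instance; properties hang off it.
    A ``supplementary`` row does not become a node — it attaches a resource
    link (role ``supplementary``) to the nearest preceding property node.
    """
    nodes: dict[str, Node] = {}
    edges: list[Edge] = []
    taken: set[str] = set()
    last_instance: Optional[str] = None
    last_property: Optional[str] = None

    for row_no, row in enumerate(rows, start=1):
        category, name, value, link = (list(row) + ["", "", "", ""])[:4]
        try:
            directive = map_legacy(category, property_default)
        except UnknownLegacyTermError:
            raise UnknownLegacyTermError(
                f"row {row_no}: unknown legacy category {category!r}") from None

        if isinstance(directive, AttachmentDirective):
            if last_property is None:
                raise OrphanSupplementaryError(
                    f"row {row_no}: supplementary with no preceding property")
            target = link or value or name or "supplementary"
            nodes[last_property].links.append(
                ResourceLink(target=target, role=directive.role))
            continue

        nid = _slug(name or category, taken)
        fields = {"value": value} if value else {}
        links = [ResourceLink(target=link)] if link else []
        nodes[nid] = Node(id=nid, kind=directive, label=name or nid,
                          fields=fields, links=links)

        if directive == NodeKind.INSTANCE:
            if last_instance is not None:
                edges.append(Edge(source=last_instance, target=nid))
            last_instance, last_property = nid, None
        elif directive in (NodeKind.MATERIAL, NodeKind.MEDIUM):
            if last_instance is not None:
                edges.append(Edge(source=nid, target=last_instance))
        else:  # a property kind
            if last_instance is not None:
                edges.append(Edge(source=last_instance, target=nid))
            last_property = nid

    return InstanceMap(id=map_id, nodes=nodes, edges=edges)


def read_legacy_csv(
    path: Union[str, Path],
    property_default: NodeKind = NodeKind.CURATED_PROPERTY,
    map_id: Optional[str] = None,
) -> InstanceMap:
    """Import an RFC 4180 CSV with header ``category,name,value,link``."""
    p = Path(path)
    with p.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        rows = [
            (r.get("category", ""), r.get("name", ""),
             r.get("value", ""), r.get("link", ""))
            for r in reader
        ]
    return import_legacy_table(rows, property_default,
                               map_id=map_id or p.stem.replace(" ", "-"))
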