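"""Map versioning, cross-map linking and composition.

Study maps evolve: a planning map is refined as the real workflow deviates
from it, and each revision should be explainable.  :func:`diff` produces a
deterministic changeset between two versions — node-level add/remove,
field-level modification, identity-level edge changes — renderable as
human-readable text or as a JSON changeset.

Maps also reference each other (e.g. a chronic-toxicity test whose exposure
concentration comes from the dose–response curve of an acute test described
in a separate map).  A :class:`Workspace` holds several maps;
:func:`resolve_links` checks which cross-map links can be resolved inside
it — an unresolved target is a warning, never an error, because maps travel
separately.  :func:`merge` composes maps into one, optionally rewriting
resolvable cross-map links into ordinary edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

from .errors import IdCollisionError
from .model import Edge, InstanceMap, MapLink, Node, NodeMeta, Region, ResourceLink

__all__ = [
    "FieldChange",
    "MapDiff",
    "Workspace",
    "LinkResolution",
    "diff",
    "apply_diff",
    "resolve_links",
    "merge",
]


FieldChange = tuple[str, Any, Any]  # (field path, old, new); None = absent

_EdgeKey = tuple[str, str, Optional[str]]
_MapLinkKey = tuple[str, str, str, str]


def _links_value(links: list[ResourceLink]) -> list[dict]:
    return [
        {k: v for k, v in (("target", ln.target), ("role", ln.role),
                           ("media_hint", ln.media_hint)) if v is not None}
        for ln in links
    ]


def _node_flat(node: Node) -> dict[str, Any]:
    flat: dict[str, Any] = {"kind": node.kind.value, "label": node.label}
    if node.colour_override is not None:
        flat["colour_override"] = node.colour_override
    for key in ("description", "keywords", "version", "created", "licence",
                "contributors", "references"):
        value = getattr(node.meta, key)
        if value:
            flat[f"meta.{key}"] = value
    for key in sorted(node.fields):
        flat[f"fields.{key}"] = node.fields[key]
    if node.links:
        flat["links"] = _links_value(node.links)
    return flat


def _meta_flat(meta: NodeMeta) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for key in ("description", "keywords", "version", "created", "licence",
                "contributors", "references"):
        value = getattr(meta, key)
        if value:
            out[key] = value
    return out


def _region_flat(region: Region) -> dict[str, Any]:
    flat: dict[str, Any] = {"label": region.label,
                            "member_ids": sorted(region.member_ids)}
    if region.colour is not None:
        flat["colour"] = region.colour
    return flat


def _flat_changes(old: dict[str, Any], new: dict[str, Any]) -> list[FieldChange]:
    changes = []
    for key in sorted(set(old) | set(new)):
        if old.get(key) != new.get(key):
            changes.append((key, old.get(key), new.get(key)))
    return changes


@dataclass(frozen=True)
class MapDiff:
    """Difference between two map versions (``a`` → ``b``).

    Nodes are matched by id; added nodes carry their full payload so the
    changeset is self-contained and applicable.  Edges and cross-map links
    have no mutable payload beyond their identity, so they only appear as
    added/removed.  ``annotation`` is free text for the *reason* behind the
    revision (why the plan deviated), carried with the changeset.
    """

    added: dict[str, Node] = field(default_factory=dict)
    removed_nodes: set[str] = field(default_factory=set)
    modified_nodes: dict[str, list[FieldChange]] = field(default_factory=dict)
    added_edges: set[_EdgeKey] = field(default_factory=set)
    removed_edges: set[_EdgeKey] = field(default_factory=set)
    added_regions: dict[str, Region] = field(default_factory=dict)
    removed_regions: set[str] = field(default_factory=set)
    modified_regions: dict[str, list[FieldChange]] = field(default_factory=dict)
    added_map_links: set[_MapLinkKey] = field(default_factory=set)
    removed_map_links: set[_MapLinkKey] = field(default_factory=set)
    meta_changes: list[FieldChange] = field(default_factory=list)
    annotation: str = ""

    @property
    def added_nodes(self) -> set[str]:
        return set(self.added)

    @property
    def empty(self) -> bool:
        return not (self.added or self.removed_nodes or self.modified_nodes
                    or self.added_edges or self.removed_edges
                    or self.added_regions or self.removed_regions
                    or self.modified_regions or self.added_map_links
                    or self.removed_map_links or self.meta_changes)

    def to_json(self) -> str:
        """The diff as a JSON changeset."""
        def edge_list(keys):
            return [{"source": s, "target": t, "label": l}
                    for s, t, l in sorted(keys, key=lambda k: (k[0], k[1], k[2] or ""))]

        def change_list(changes):
            return [{"field": f, "old": o, "new": n} for f, o, n in changes]

        doc = {
            "added_nodes": [_node_payload(self.added[nid])
                            for nid in sorted(self.added)],
            "removed_nodes": sorted(self.removed_nodes),
            "modified_nodes": {nid: change_list(self.modified_nodes[nid])
                               for nid in sorted(self.modified_nodes)},
            "added_edges": edge_list(self.added_edges),
            "removed_edges": edge_list(self.removed_edges),
            "added_regions": [
                {"id": rid, **_region_flat(self.added_regions[rid])}
                for rid in sorted(self.added_regions)],
            "removed_regions": sorted(self.removed_regions),
            "modified_regions": {rid: change_list(self.modified_regions[rid])
                                 for rid in sorted(self.modified_regions)},
            "added_map_links": [list(k) for k in sorted(self.added_map_links)],
            "removed_map_links": [list(k) for k in sorted(self.removed_map_links)],
            "meta_changes": change_list(self.meta_changes),
            "annotation": self.annotation,
        }
        return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"

    def to_text(self) -> str:
        """Human-readable rendering."""
        if self.empty:
            return "maps are identical\n"
        lines: list[str] = []
        if self.annotation:
            lines.append(f"# {self.annotation}")
        for nid in sorted(self.added):
            lines.append(f"+ node {nid} ({self.added[nid].kind.value})")
        for nid in sorted(self.removed_nodes):
            lines.append(f"- node {nid}")
        for nid in sorted(self.modified_nodes):
            for fieldname, old, new in self.modified_nodes[nid]:
                lines.append(f"~ node {nid}: {fieldname}: {old!r} -> {new!r}")
        for s, t, l in sorted(self.added_edges, key=lambda k: (k[0], k[1], k[2] or "")):
            lines.append(f"+ edge {s} -> {t}" + (f" [{l}]" if l else ""))
        for s, t, l in sorted(self.removed_edges, key=lambda k: (k[0], k[1], k[2] or "")):
            lines.append(f"- edge {s} -> {t}" + (f" [{l}]" if l else ""))
        for rid in sorted(self.added_regions):
            lines.append(f"+ region {rid}")
        for rid in sorted(self.removed_regions):
            lines.append(f"- region {rid}")
        for rid in sorted(self.modified_regions):
            for fieldname, old, new in self.modified_regions[rid]:
                lines.append(f"~ region {rid}: {fieldname}: {old!r} -> {new!r}")
        for key in sorted(self.added_map_links):
            lines.append(f"+ map-link {key[0]} -> {key[1]}:{key[2]}")
        for key in sorted(self.removed_map_links):
            lines.append(f"- map-link {key[0]} -> {key[1]}:{key[2]}")
        for fieldname, old, new in self.meta_changes:
            lines.append(f"~ map meta: {fieldname}: {old!r} -> {new!r}")
        return "\n".join(lines) + "\n"


def _node_payload(node: Node) -> dict:
    payload: dict = {"id": node.id, "kind": node.kind.value, "label": node.label}
    meta = _meta_flat(node.meta)
    if meta:
        payload["meta"] = meta
    if node.fields:
        payload["fields"] = dict(sorted(node.fields.items()))
    if node.links:
        payload["links"] = _links_value(node.links)
    if node.colour_override:
        payload["colour_override"] = node.colour_override
    return payload


def _edge_keys(m: InstanceMap) -> set[_EdgeKey]:
    return {e.key for e in m.edges}


def _map_link_keys(m: InstanceMap) -> set[_MapLinkKey]:
    return {(ml.source_node, ml.target_map, ml.target_node, ml.relation)
            for ml in m.map_links}


def diff(a: InstanceMap, b: InstanceMap, annotation: str = "") -> MapDiff:
    """Changeset turning version ``a`` into version ``b``.

    Deterministic: field changes are sorted by field name.  Antisymmetric:
    ``diff(a, b).added_nodes == diff(b, a).removed_nodes``.
    """
    a_ids, b_ids = set(a.nodes), set(b.nodes)
    modified: dict[str, list[FieldChange]] = {}
    for nid in sorted(a_ids & b_ids):
        changes = _flat_changes(_node_flat(a.nodes[nid]), _node_flat(b.nodes[nid]))
        if changes:
            modified[nid] = changes

    a_regions = {r.id: r for r in a.regions}
    b_regions = {r.id: r for r in b.regions}
    modified_regions: dict[str, list[FieldChange]] = {}
    for rid in sorted(set(a_regions) & set(b_regions)):
        changes = _flat_changes(_region_flat(a_regions[rid]),
                                _region_flat(b_regions[rid]))
        if changes:
            modified_regions[rid] = changes

    return MapDiff(
        added={nid: b.nodes[nid].model_copy(deep=True)
               for nid in sorted(b_ids - a_ids)},
        removed_nodes=a_ids - b_ids,
        modified_nodes=modified,
        added_edges=_edge_keys(b) - _edge_keys(a),
        removed_edges=_edge_keys(a) - _edge_keys(b),
        added_regions={rid: b_regions[rid].model_copy(deep=True)
                       for rid in sorted(set(b_regions) - set(a_regions))},
        removed_regions=set(a_regions) - set(b_regions),
        modified_regions=modified_regions,
        added_map_links=_map_link_keys(b) - _map_link_keys(a),
        removed_map_links=_map_link_keys(a) - _map_link_keys(b),
        meta_changes=_flat_changes(_meta_flat(a.meta), _meta_flat(b.meta)),
        annotation=annotation,
    )


def _apply_flat(node: Node, changes: list[FieldChange]) -> Node:
    data = node.model_dump()
    for path, _old, new in changes:
        if path == "links":
            data["links"] = new or []
        elif path.startswith("meta."):
            data["meta"][path[5:]] = new if new is not None else (
                [] if path[5:] in ("keywords", "contributors", "references") else None)
        elif path.startswith("fields."):
            key = path[7:]
            if new is None:
                data["fields"].pop(key, None)
            else:
                data["fields"][key] = new
        else:
            data[path] = new
    return Node.model_validate(data)


def apply_diff(a: InstanceMap, d: MapDiff) -> InstanceMap:
    """Apply a changeset produced by :func:`diff` to ``a``.

    ``apply_diff(a, diff(a, b))`` reconstructs ``b`` exactly (the map id is
    kept from ``a``; ids are version-stable by design).
    """
    nodes = {nid: n.model_copy(deep=True) for nid, n in a.nodes.items()
             if nid not in d.removed_nodes}
    for nid, changes in d.modified_nodes.items():
        nodes[nid] = _apply_flat(nodes[nid], changes)
    for nid, node in d.added.items():
        nodes[nid] = node.model_copy(deep=True)

    edge_keys = (_edge_keys(a) - d.removed_edges) | d.added_edges
    edges = [Edge(source=s, target=t, label=l)
             for s, t, l in sorted(edge_keys, key=lambda k: (k[0], k[1], k[2] or ""))]

    regions = {r.id: r.model_copy(deep=True) for r in a.regions
               if r.id not in d.removed_regions}
    for rid, changes in d.modified_regions.items():
        data = regions[rid].model_dump()
        for path, _old, new in changes:
            data[path] = new
        regions[rid] = Region.model_validate(data)
    for rid, region in d.added_regions.items():
        regions[rid] = region.model_copy(deep=True)

    ml_keys = (_map_link_keys(a) - d.removed_map_links) | d.added_map_links
    map_links = [MapLink(source_node=s, target_map=tm, target_node=tn, relation=rel)
                 for s, tm, tn, rel in sorted(ml_keys)]

    meta_data = a.meta.model_dump()
    for path, _old, new in d.meta_changes:
        meta_data[path] = new if new is not None else (
            [] if path in ("keywords", "contributors", "references") else None)

    return InstanceMap(
        id=a.id, meta=NodeMeta.model_validate(meta_data), nodes=nodes,
        edges=edges, regions=sorted(regions.values(), key=lambda r: r.id),
        map_links=map_links)


# --------------------------------------------------------------------------
# workspaces and composition


@dataclass
class Workspace:
    """A collection of maps that may reference each other."""

    maps: dict[str, InstanceMap] = field(default_factory=dict)

    def add(self, m: InstanceMap) -> None:
        if m.id in self.maps:
            raise IdCollisionError(f"duplicate map id in workspace: {m.id!r}")
        self.maps[m.id] = m


@dataclass(frozen=True)
class LinkResolution:
    source_map: str
    link: MapLink
    resolved: bool
    status: str  # "resolved" or a warning message


def resolve_links(ws: Workspace) -> list[LinkResolution]:
    """Resolve every cross-map link against the workspace.

    A link resolves iff its target map is present and contains the target
    node.  Unresolved links get a warning status; they are expected when
    maps are exchanged piecemeal.
    """
    out: list[LinkResolution] = []
    for map_id in sorted(ws.maps):
        for ml in ws.maps[map_id].map_links:
            target = ws.maps.get(ml.target_map)
            if target is None:
                out.append(LinkResolution(
                    map_id, ml, False,
                    f"warning: target map {ml.target_map!r} not in workspace"))
            elif ml.target_node not in target.nodes:
                out.append(LinkResolution(
                    map_id, ml, False,
                    f"warning: node {ml.target_node!r} not in map {ml.target_map!r}"))
            else:
                out.append(LinkResolution(map_id, ml, True, "resolved"))
    return out


def merge(maps: Sequence[InstanceMap], id_prefixing: bool = False) -> InstanceMap:
    """Union of several maps into one document.

    Without prefixing, node-id sets must be pairwise disjoint.  With
    prefixing, every node id becomes ``<map_id>.<node_id>`` and cross-map
    links between the merged maps are rewritten as ordinary edges labelled
    by the link relation; links pointing outside the merge set survive as
    cross-map links.
    """
    if not maps:
        raise ValueError("merge requires at least one map")
    if not id_prefixing:
        seen: set[str] = set()
        for m in maps:
            clash = seen & set(m.nodes)
            if clash:
                raise IdCollisionError(
                    f"node id collision without prefixing: {sorted(clash)}")
            seen |= set(m.nodes)

    merged_ids = {m.id for m in maps}

    def rename(map_id: str, nid: str) -> str:
        return f"{map_id}.{nid}" if id_prefixing else nid

    nodes: dict[str, Node] = {}
    edges: list[Edge] = []
    regions: list[Region] = []
    map_links: list[MapLink] = []
    for m in maps:
        for nid, node in m.nodes.items():
            new_id = rename(m.id, nid)
            nodes[new_id] = node.model_copy(deep=True, update={"id": new_id})
        for e in m.edges:
            edges.append(Edge(source=rename(m.id, e.source),
                              target=rename(m.id, e.target), label=e.label))
        for r in m.regions:
            regions.append(Region(
                id=rename(m.id, r.id), label=r.label, colour=r.colour,
                member_ids={rename(m.id, nid) for nid in r.member_ids}))
        for ml in m.map_links:
            src = rename(m.id, ml.source_node)
            if (id_prefixing and ml.target_map in merged_ids
                    and f"{ml.target_map}.{ml.target_node}" in
                    {rename(om.id, n) for om in maps for n in om.nodes
                     if om.id == ml.target_map}):
                edges.append(Edge(source=src,
                                  target=f"{ml.target_map}.{ml.target_node}",
                                  label=ml.relation or None))
            else:
                map_links.append(ml.model_copy(update={"source_node": src}))

    return InstanceMap(
        id="-".join(m.id for m in maps), meta=maps[0].meta.model_copy(deep=True),
        nodes=nodes, edges=edges, regions=regions, map_links=map_links)
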