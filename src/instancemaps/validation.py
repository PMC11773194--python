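"""Structural validation, backbone extraction and completeness scoring.

Validation is profile-driven.  The format deliberately does not hard-wire
connection rules — different communities arrange nodes differently, and a
measurement chain may legitimately sit before or after the property node it
determines, or replace it entirely.  Two built-in profiles are provided:

* **strict** — flags edges outside a curated adjacency whitelist and
  mis-ordered measurement chains as warnings;
* **lenient** — raises the same notices at info severity only.

Referential breakage (rule R1) and directed cycles (R2) are errors under
every profile, because instance order encodes time.  All other findings are
advisory; map authors decide what to act on, and community profiles can
re-grade any rule via severity overrides.

Completeness scoring checks each node against the requirement slots of its
kind (see :mod:`instancemaps.taxonomy`): used at the study-design stage, it
answers "which metadata is this study description still missing?" before
any data is collected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import yaml

from .errors import CyclicMapError, UnknownKindError
from .model import InstanceMap, Node
from .taxonomy import (
    PROPERTY_KINDS,
    NodeKind,
    Taxonomy,
    builtin_taxonomy,
)

__all__ = [
    "Severity",
    "Issue",
    "ValidationReport",
    "ValidationProfile",
    "CompletenessReport",
    "NodeCompleteness",
    "strict_profile",
    "lenient_profile",
    "load_profile",
    "is_acyclic",
    "extract_backbone",
    "validate",
    "completeness",
    "STRICT_ADJACENCY",
    "MEASUREMENT_STAGE_ORDER",
]

Severity = str  # one of "error" | "warning" | "info"
_SEVERITY_RANK = {"info": 0, "warning": 1, "error": 2}

#: Canonical ordering of the measurement workflow stages: sample
#: preparation → measurement → raw data → data processing → processed data.
MEASUREMENT_STAGE_ORDER: dict[NodeKind, int] = {
    NodeKind.SAMPLE_PREPARATION_PROTOCOL: 0,
    NodeKind.MEASUREMENT_PROTOCOL: 1,
    NodeKind.RAW_DATA: 2,
    NodeKind.DATA_PROCESSING_PROTOCOL: 3,
    NodeKind.PROCESSED_DATA: 4,
}


def _whitelist() -> dict[NodeKind, frozenset[NodeKind]]:
    pairs: set[tuple[NodeKind, NodeKind]] = set()

    def allow(sources, targets):
        for s in sources:
            for t in targets:
                pairs.add((s, t))

    inst = [NodeKind.INSTANCE]
    allow([NodeKind.MATERIAL], inst)
    allow([NodeKind.MEDIUM], inst)
    allow(inst, inst)
    allow(inst, [NodeKind.TRANSFORMATION_PROTOCOL])
    allow([NodeKind.TRANSFORMATION_PROTOCOL], inst)
    # measurement chain, entered from an instance
    allow(inst, [NodeKind.SAMPLE_PREPARATION_PROTOCOL])
    chain = [
        NodeKind.SAMPLE_PREPARATION_PROTOCOL,
        NodeKind.MEASUREMENT_PROTOCOL,
        NodeKind.RAW_DATA,
        NodeKind.DATA_PROCESSING_PROTOCOL,
        NodeKind.PROCESSED_DATA,
    ]
    for a, b in zip(chain, chain[1:]):
        pairs.add((a, b))
    # properties may hang off instance-family nodes or off data nodes, and a
    # measurement chain may follow a property (chain-before-property variant)
    allow([NodeKind.INSTANCE, NodeKind.MATERIAL, NodeKind.MEDIUM], PROPERTY_KINDS)
    allow([NodeKind.PROCESSED_DATA, NodeKind.RAW_DATA], PROPERTY_KINDS)
    allow(PROPERTY_KINDS, [NodeKind.SAMPLE_PREPARATION_PROTOCOL])

    out: dict[NodeKind, set[NodeKind]] = {}
    for s, t in pairs:
        out.setdefault(s, set()).add(t)
    return {s: frozenset(t) for s, t in out.items()}


#: Adjacency whitelist used by the built-in profiles.  It covers the node
#: arrangements observed in practice without declaring any of them wrong;
#: edges outside it are at most warnings.
STRICT_ADJACENCY: dict[NodeKind, frozenset[NodeKind]] = _whitelist()


@dataclass(frozen=True)
class Issue:
    rule_id: str
    severity: Severity
    ref: str  # node id, "source->target" edge ref, or "" for map-level
    message: str

    def __post_init__(self) -> None:
        if self.severity not in _SEVERITY_RANK:
            raise ValueError(f"unknown severity: {self.severity!r}")


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[Issue, ...]

    @property
    def passed(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def by_rule(self, rule_id: str) -> list[Issue]:
        return [i for i in self.issues if i.rule_id == rule_id]


@dataclass(frozen=True)
class ValidationProfile:
    """Connection rules plus per-rule severities.

    ``adjacency`` is the whitelist rule R3 checks against;
    ``rule_severities`` grades each rule; ``severity_overrides`` lets a
    community config re-grade individual rules (applied last).
    """

    name: str
    adjacency: dict[NodeKind, frozenset[NodeKind]]
    rule_severities: dict[str, Severity]
    severity_overrides: dict[str, Severity] = field(default_factory=dict)

    def severity(self, rule_id: str) -> Severity:
        if rule_id in self.severity_overrides:
            return self.severity_overrides[rule_id]
        return self.rule_severities[rule_id]

    def allows(self, source: NodeKind, target: NodeKind) -> bool:
        return target in self.adjacency.get(source, frozenset())


_BASE_SEVERITIES = {"R1": "error", "R2": "error", "R5": "info", "R6": "warning"}


def strict_profile(
    severity_overrides: Optional[dict[str, Severity]] = None,
) -> ValidationProfile:
    return ValidationProfile(
        name="strict",
        adjacency=dict(STRICT_ADJACENCY),
        rule_severities={**_BASE_SEVERITIES, "R3": "warning", "R4": "warning"},
        severity_overrides=dict(severity_overrides or {}),
    )


def lenient_profile(
    severity_overrides: Optional[dict[str, Severity]] = None,
) -> ValidationProfile:
    """Same notices as strict, graded down to info for R3/R4.

    Cycles and dangling references remain errors: instance order encodes
    time, and a reference to a missing node breaks the document.
    """
    return ValidationProfile(
        name="lenient",
        adjacency=dict(STRICT_ADJACENCY),
        rule_severities={**_BASE_SEVERITIES, "R3": "info", "R4": "info"},
        severity_overrides=dict(severity_overrides or {}),
    )


def load_profile(source: Union[str, Path, dict]) -> ValidationProfile:
    """Load a profile from a YAML/JSON file or an equivalent dict.

    Recognised keys: ``name``; ``base`` (``strict``/``lenient``, default
    strict) to inherit adjacency and severities; ``adjacency`` — mapping of
    source kind to list of allowed target kinds (replaces the base list for
    those sources); ``severity_overrides`` — mapping rule id to severity.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
    else:
        data = source
    if not isinstance(data, dict):
        raise ValueError("profile config must be a mapping")
    base_name = data.get("base", "strict")
    base = strict_profile() if base_name == "strict" else lenient_profile()
    adjacency = dict(base.adjacency)
    for src, targets in (data.get("adjacency") or {}).items():
        adjacency[NodeKind(src)] = frozenset(NodeKind(t) for t in targets)
    return ValidationProfile(
        name=data.get("name", base.name),
        adjacency=adjacency,
        rule_severities=dict(base.rule_severities),
        severity_overrides={
            str(k): str(v) for k, v in (data.get("severity_overrides") or {}).items()
        },
    )


def _graph(m: InstanceMap) -> nx.MultiDiGraph:
    """Graph over the map's *existing* nodes; dangling edges are skipped
    (they are rule R1's business, not the graph algorithms')."""
    g = nx.MultiDiGraph()
    g.add_nodes_from(m.nodes)
    for e in m.edges:
        if e.source in m.nodes and e.target in m.nodes:
            g.add_edge(e.source, e.target, label=e.label)
    return g


def is_acyclic(m: InstanceMap) -> tuple[bool, Optional[list[str]]]:
    """Whether the edge set contains no directed cycle.

    Returns ``(True, None)`` or ``(False, witness)`` where witness is the
    node-id sequence of one cycle.
    """
    g = _graph(m)
    if nx.is_directed_acyclic_graph(g):
        return True, None
    cycle = nx.find_cycle(g)
    return False, [edge[0] for edge in cycle]


def extract_backbone(m: InstanceMap) -> list[list[str]]:
    """Maximal instance chains — the main branch(es) of the map.

    The backbone is the subgraph induced by ``Instance`` nodes, where two
    instances are linked if connected directly or through a single
    ``TransformationProtocol`` node.  Chains are returned as ordered node-id
    lists, one per maximal path, sorted lexicographically for determinism.
    """
    ok, witness = is_acyclic(m)
    if not ok:
        raise CyclicMapError(f"map contains a cycle: {witness}")
    g = _graph(m)
    instances = {nid for nid, n in m.nodes.items() if n.kind == NodeKind.INSTANCE}
    ig = nx.DiGraph()
    ig.add_nodes_from(sorted(instances))
    for u, v in g.edges():
        if u in instances and v in instances:
            ig.add_edge(u, v)
        elif u in instances and m.nodes[v].kind == NodeKind.TRANSFORMATION_PROTOCOL:
            for w in g.successors(v):
                if w in instances:
                    ig.add_edge(u, w)

    chains: list[list[str]] = []
    roots = sorted(n for n in ig.nodes if ig.in_degree(n) == 0)

    def walk(path: list[str]) -> None:
        succs = sorted(ig.successors(path[-1]))
        if not succs:
            chains.append(path)
            return
        for s in succs:
            walk(path + [s])

    for r in roots:
        walk([r])
    return chains


def validate(m: InstanceMap, profile: Optional[ValidationProfile] = None) -> ValidationReport:
    """Apply the profile's structural rules; problems are issues, never
    exceptions.

    Rules: R1 dangling references; R2 directed cycles; R3 edge outside the
    adjacency whitelist; R4 measurement-chain stage inversion (e.g. raw data
    feeding back into its measurement protocol); R5 material/medium not
    associated with any instance; R6 empty map.
    """
    profile = profile or strict_profile()
    issues: list[Issue] = []

    def emit(rule: str, ref: str, message: str) -> None:
        issues.append(Issue(rule, profile.severity(rule), ref, message))

    # R1 — referential integrity
    for i, e in enumerate(m.edges):
        for endpoint in (e.source, e.target):
            if endpoint not in m.nodes:
                emit("R1", f"{e.source}->{e.target}",
                     f"edge {i} references missing node {endpoint!r}")
    for r in m.regions:
        for missing in sorted(r.member_ids - set(m.nodes)):
            emit("R1", r.id, f"region {r.id!r} references missing node {missing!r}")
    for ml in m.map_links:
        if ml.source_node not in m.nodes:
            emit("R1", ml.source_node,
                 f"map link references missing local node {ml.source_node!r}")

    # R2 — cycles (errors under every profile: edge direction encodes time)
    ok, witness = is_acyclic(m)
    if not ok:
        emit("R2", "->".join(witness or []), f"directed cycle: {witness}")

    # R3 / R4 — connection rules on resolvable edges
    for e in m.edges:
        if e.source not in m.nodes or e.target not in m.nodes:
            continue
        sk, tk = m.nodes[e.source].kind, m.nodes[e.target].kind
        if not profile.allows(sk, tk):
            emit("R3", f"{e.source}->{e.target}",
                 f"edge kind pair {sk.value}->{tk.value} outside adjacency rules")
        si, ti = MEASUREMENT_STAGE_ORDER.get(sk), MEASUREMENT_STAGE_ORDER.get(tk)
        if si is not None and ti is not None and si > ti:
            emit("R4", f"{e.source}->{e.target}",
                 f"{sk.value} precedes {tk.value}, inverting the sample "
                 "preparation -> measurement -> raw data -> data processing "
                 "-> processed data stage order")

    # R5 — material/medium not associated with any instance
    for nid, node in sorted(m.nodes.items()):
        if node.kind not in (NodeKind.MATERIAL, NodeKind.MEDIUM):
            continue
        attached = any(
            (e.source == nid and m.nodes.get(e.target, None) is not None
             and m.nodes[e.target].kind == NodeKind.INSTANCE)
            or (e.target == nid and m.nodes.get(e.source, None) is not None
                and m.nodes[e.source].kind == NodeKind.INSTANCE)
            for e in m.edges
        )
        if not attached:
            emit("R5", nid,
                 f"{node.kind.value} node {nid!r} is not associated with any instance")

    # R6 — empty map
    if not m.nodes:
        emit("R6", "", "map has no nodes")

    return ValidationReport(issues=tuple(issues))


@dataclass(frozen=True)
class NodeCompleteness:
    satisfied: tuple[str, ...]
    missing: tuple[str, ...]

    @property
    def score(self) -> float:
        total = len(self.satisfied) + len(self.missing)
        return len(self.satisfied) / total if total else 1.0


@dataclass(frozen=True)
class CompletenessReport:
    per_node: dict[str, NodeCompleteness]

    @property
    def map_score(self) -> float:
        if not self.per_node:
            return 1.0
        return sum(nc.score for nc in self.per_node.values()) / len(self.per_node)


def _node_completeness(node: Node, taxonomy: Taxonomy) -> NodeCompleteness:
    if node.kind not in taxonomy:
        raise UnknownKindError(f"unknown node kind: {node.kind!r}")
    provided = set(node.fields) | {link.role for link in node.links}
    satisfied, missing = [], []
    for slot in taxonomy[node.kind].requirement_slots:
        (satisfied if provided & slot.satisfied_by else missing).append(slot.slot_id)
    return NodeCompleteness(tuple(satisfied), tuple(missing))


def completeness(m: InstanceMap, taxonomy: Optional[Taxonomy] = None) -> CompletenessReport:
    """Score every node against its kind's requirement slots.

    A slot counts as satisfied when the node carries a metadata field, or a
    resource link with a role, named in the slot's ``satisfied_by`` set.
    Node score = satisfied/required; map score = mean over nodes (1.0 for an
    empty map, vacuously).
    """
    tax = taxonomy if taxonomy is not None else builtin_taxonomy()
    return CompletenessReport(
        per_node={nid: _node_completeness(n, tax) for nid, n in sorted(m.nodes.items())}
    )
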