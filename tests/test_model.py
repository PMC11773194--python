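"""Graph-document construction ops and their invariants."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from instancemaps.errors import (
    BadIdError,
    DanglingReferenceError,
    DuplicateEdgeError,
    DuplicateNodeError,
)
from instancemaps.model import (
    ID_PATTERN,
    Edge,
    Node,
    NodeMeta,
    Region,
    ResourceLink,
    add_edge,
    add_node,
    add_region,
    attach_resource,
    effective_colour,
    new_map,
)
from instancemaps.taxonomy import CATEGORY_COLOURS, NodeCategory, NodeKind
from instancemaps.validation import lenient_profile, strict_profile, validate


def _inst(nid):
    return Node(id=nid, kind=NodeKind.INSTANCE, label=nid)


def test_add_edge_on_empty_map_is_dangling():
    with pytest.raises(DanglingReferenceError):
        add_edge(new_map("m"), Edge(source="a", target="b"))


def test_duplicate_node_id_rejected():
    m = add_node(new_map("m"), _inst("a"))
    with pytest.raises(DuplicateNodeError):
        add_node(m, _inst("a"))


def test_duplicate_edge_rejected_but_relabel_allowed():
    m = add_node(add_node(new_map("m"), _inst("a")), _inst("b"))
    m = add_edge(m, Edge(source="a", target="b"))
    with pytest.raises(DuplicateEdgeError):
        add_edge(m, Edge(source="a", target="b"))
    m = add_edge(m, Edge(source="a", target="b", label="repeat"))
    assert len(m.edges) == 2


def test_malformed_ids_rejected():
    with pytest.raises(BadIdError):
        new_map("bad id with spaces")
    with pytest.raises(ValueError):
        Node(id="no/slashes", kind=NodeKind.INSTANCE)


def test_region_members_must_exist():
    m = add_node(new_map("m"), _inst("a"))
    with pytest.raises(DanglingReferenceError):
        add_region(m, Region(id="r", member_ids={"a", "ghost"}))


def test_attach_resource_appends_link():
    m = add_node(new_map("culture"), Node(id="medium", kind=NodeKind.MEDIUM))
    m2 = attach_resource(m, "medium", ResourceLink(target="sop.pdf", role="sop"))
    assert len(m2.nodes["medium"].links) == 1
    assert m.nodes["medium"].links == []  # ops are non-mutating
    with pytest.raises(DanglingReferenceError):
        attach_resource(m, "ghost", ResourceLink(target="x"))


def test_created_date_must_be_iso8601():
    assert NodeMeta(created="2024-01-02").created == "2024-01-02"
    with pytest.raises(ValueError):
        NodeMeta(created="02/01/24")


def test_effective_colour_default_and_override():
    raw = Node(id="d", kind=NodeKind.RAW_DATA)
    assert effective_colour(raw) == CATEGORY_COLOURS[NodeCategory.DATA]
    inst = Node(id="i", kind=NodeKind.INSTANCE, colour_override="#ff0000")
    assert effective_colour(inst) == "#ff0000"
    # total over all registered kinds
    for kind in NodeKind:
        assert effective_colour(Node(id="n", kind=kind)).startswith("#")


def test_colour_override_never_affects_validation():
    plain = add_node(new_map("m"), _inst("a"))
    painted = add_node(new_map("m"),
                       Node(id="a", kind=NodeKind.INSTANCE, label="a",
                            colour_override="#ff0000"))
    for profile in (strict_profile(), lenient_profile()):
        assert [ (i.rule_id, i.severity) for i in validate(plain, profile).issues] \
            == [ (i.rule_id, i.severity) for i in validate(painted, profile).issues]


def _check_invariants(m):
    assert set(m.nodes) == {n.id for n in m.nodes.values()}
    for nid in m.nodes:
        assert ID_PATTERN.match(nid)
    keys = [e.key for e in m.edges]
    assert len(keys) == len(set(keys))
    for e in m.edges:
        assert e.source in m.nodes and e.target in m.nodes
    for r in m.regions:
        assert r.member_ids <= set(m.nodes)


@settings(derandomize=True, max_examples=30)
@given(seed=st.integers(0, 2**31 - 1))
def test_random_construction_sequences_preserve_invariants(seed):
    """No sequence of construction ops can produce an inconsistent map."""
    rng = random.Random(seed)
    m = new_map("m")
    for step in range(rng.randint(1, 25)):
        op = rng.choice(["node", "edge", "region", "link"])
        try:
            if op == "node":
                kind = rng.choice(list(NodeKind))
                m = add_node(m, Node(id=f"n{rng.randint(0, 15)}", kind=kind))
            elif op == "edge" and m.nodes:
                ids = sorted(m.nodes)
                m = add_edge(m, Edge(source=rng.choice(ids),
                                     target=rng.choice(ids),
                                     label=rng.choice([None, "x"])))
            elif op == "region" and m.nodes:
                ids = sorted(m.nodes)
                members = {rng.choice(ids) for _ in range(rng.randint(1, 3))}
                m = add_region(m, Region(id=f"r{step}", member_ids=members))
            elif op == "link" and m.nodes:
                m = attach_resource(m, rng.choice(sorted(m.nodes)),
                                    ResourceLink(target=f"res{step}"))
        except (DuplicateNodeError, DuplicateEdgeError, DanglingReferenceError):
            pass  # rejected ops must leave the map untouched
        _check_invariants(m)
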