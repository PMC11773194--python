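"""Diffing, workspace link resolution and map merging."""

import json
import random

import pytest

from instancemaps.compose import (
    Workspace,
    apply_diff,
    diff,
    merge,
    resolve_links,
)
from instancemaps.errors import IdCollisionError
from instancemaps.fixtures import build, random_map
from instancemaps.model import Edge, MapLink, Node, Region, ResourceLink
from instancemaps.taxonomy import NodeKind


def test_diff_of_identical_maps_is_empty(fixture_map):
    d = diff(fixture_map, fixture_map)
    assert d.empty
    assert d.to_text() == "maps are identical\n"


def test_added_node_only():
    a = build("oecd202")
    b = a.model_copy(deep=True)
    b.nodes["extra"] = Node(id="extra", kind=NodeKind.CURATED_PROPERTY)
    d = diff(a, b)
    assert d.added_nodes == {"extra"}
    assert not (d.removed_nodes or d.modified_nodes or d.added_edges
                or d.removed_edges)


def test_label_change_is_single_field_entry():
    a = build("oecd202")
    b = a.model_copy(deep=True)
    b.nodes["inst_stock"].label = "Stock dispersion v2"
    d = diff(a, b)
    assert d.modified_nodes == {
        "inst_stock": [("label", "Stock dispersion", "Stock dispersion v2")]}


def test_diff_antisymmetry():
    a, b = random_map(5, 6, 0.7), random_map(9, 4, 0.3)
    b = b.model_copy(deep=True, update={"id": a.id})
    fwd, bwd = diff(a, b), diff(b, a)
    assert fwd.added_nodes == bwd.removed_nodes
    assert fwd.removed_nodes == bwd.added_nodes
    assert fwd.added_edges == bwd.removed_edges


def _mutate(m, seed):
    """A random plausible revision of a map."""
    rng = random.Random(seed)
    out = m.model_copy(deep=True)
    ids = sorted(out.nodes)
    if ids and rng.random() < 0.7:
        out.nodes[rng.choice(ids)].label = f"revised {seed}"
    if ids and rng.random() < 0.5:
        victim = rng.choice(ids)
        del out.nodes[victim]
        out.edges = [e for e in out.edges
                     if victim not in (e.source, e.target)]
        for r in out.regions:
            r.member_ids.discard(victim)
        out.map_links = [ml for ml in out.map_links if ml.source_node != victim]
    out.nodes[f"added_{seed}"] = Node(
        id=f"added_{seed}", kind=NodeKind.PROCESSED_DATA,
        fields={"dataset": "rev"},
        links=[ResourceLink(target="new.csv", role="processed_data")])
    if out.nodes and rng.random() < 0.5:
        out.edges.append(Edge(source=sorted(out.nodes)[0],
                              target=f"added_{seed}", label="revision"))
    if rng.random() < 0.4:
        out.regions.append(Region(id=f"reg_{seed}",
                                  member_ids={f"added_{seed}"}))
    if rng.random() < 0.4:
        out.meta.version = str(seed)
    return out


def test_patch_property_reconstructs_revision():
    """apply(diff(a, b), a) == b over fixtures and random revisions."""
    bases = [build(n) for n in ("oecd202", "oecd211", "immunotox")]
    bases += [random_map(s, 5, 0.6) for s in range(10)]
    for seed, a in enumerate(bases):
        b = _mutate(a, seed)
        assert apply_diff(a, diff(a, b)) == b


def test_diff_json_changeset_is_valid_json():
    a = build("oecd202")
    b = _mutate(a, 1)
    doc = json.loads(diff(a, b, annotation="plan deviated").to_json())
    assert doc["annotation"] == "plan deviated"
    assert any(n["id"] == "added_1" for n in doc["added_nodes"])


def test_acute_to_chronic_link_resolves_in_shared_workspace():
    ws = Workspace()
    ws.add(build("oecd202"))
    ws.add(build("oecd211"))
    [res] = resolve_links(ws)
    assert res.resolved and res.link.target_node == "pd_dose_response"


def test_link_unresolved_when_target_map_absent():
    ws = Workspace()
    ws.add(build("oecd211"))
    [res] = resolve_links(ws)
    assert not res.resolved and "warning" in res.status


def test_no_map_links_no_resolutions():
    ws = Workspace()
    ws.add(build("sulfidation"))
    assert resolve_links(ws) == []


def test_merge_single_map_is_identity():
    m = build("mesocosm")
    assert merge([m]) == m


def test_merge_disjoint_maps_conserves_counts():
    a, b = build("sulfidation"), build("oecd202")
    merged = merge([a, b], id_prefixing=True)
    assert len(merged.nodes) == len(a.nodes) + len(b.nodes)
    assert len(merged.edges) == len(a.edges) + len(b.edges)


def test_merge_collision_without_prefixing():
    a, b = build("oecd202"), build("oecd211")  # share mat_test_item etc.
    with pytest.raises(IdCollisionError):
        merge([a, b], id_prefixing=False)


def test_merge_rewrites_cross_map_link_as_edge():
    merged = merge([build("oecd202"), build("oecd211")], id_prefixing=True)
    assert merged.map_links == []
    assert any(e.source == "oecd211.inst_exposure_conc"
               and e.target == "oecd202.pd_dose_response" for e in merged.edges)
    ws = Workspace()
    ws.add(merged)
    assert resolve_links(ws) == []


def test_merge_keeps_links_pointing_outside_merge_set():
    merged = merge([build("oecd211"), build("daphnia_culture")],
                   id_prefixing=True)
    assert len(merged.map_links) == 1
    assert merged.map_links[0].target_map == "oecd202"


def test_merge_associative_on_disjoint_maps():
    # prefix once to make the three node-id sets pairwise disjoint
    ms = [merge([random_map(s, 3, 0.4)], id_prefixing=True) for s in (1, 2, 3)]
    left = merge([merge(ms[:2]), ms[2]])
    right = merge([ms[0], merge(ms[1:])])
    assert left.nodes == right.nodes
    assert sorted(e.key for e in left.edges) == sorted(e.key for e in right.edges)
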