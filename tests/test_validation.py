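"""Structural validation, backbone extraction and completeness scoring."""

import random
from collections import defaultdict

import pytest

from instancemaps.errors import CyclicMapError, UnknownKindError
from instancemaps.fixtures import build, random_map
from instancemaps.model import (
    Edge,
    InstanceMap,
    Node,
    ResourceLink,
    add_edge,
    add_node,
    attach_resource,
    new_map,
)
from instancemaps.taxonomy import NodeKind, builtin_taxonomy
from instancemaps.validation import (
    completeness,
    extract_backbone,
    is_acyclic,
    lenient_profile,
    load_profile,
    strict_profile,
    validate,
)

K = NodeKind
_SEV_RANK = {"info": 0, "warning": 1, "error": 2}


def _digraph_map(n_nodes, edge_pairs):
    """Build a map with arbitrary edges, bypassing the construction ops."""
    nodes = {f"n{i}": Node(id=f"n{i}", kind=K.INSTANCE) for i in range(n_nodes)}
    edges = [Edge(source=f"n{a}", target=f"n{b}") for a, b in edge_pairs]
    return InstanceMap(id="g", nodes=nodes, edges=edges)


def _has_cycle_bruteforce(n_nodes, edge_pairs):
    """Independent oracle: exhaustive DFS over all simple paths."""
    adj = defaultdict(list)
    for a, b in edge_pairs:
        adj[a].append(b)

    def reaches(start, current, visited):
        for nxt in adj[current]:
            if nxt == start:
                return True
            if nxt not in visited and reaches(start, nxt, visited | {nxt}):
                return True
        return False

    return any(reaches(v, v, {v}) for v in range(n_nodes))


def test_is_acyclic_trivial_cases():
    chain = _digraph_map(3, [(0, 1), (1, 2)])
    assert is_acyclic(chain) == (True, None)
    loop = _digraph_map(2, [(0, 1), (1, 0)])
    ok, witness = is_acyclic(loop)
    assert not ok
    assert set(witness) == {"n0", "n1"}


def test_is_acyclic_matches_bruteforce_oracle():
    """200 seeded random digraphs with <= 8 nodes against exhaustive DFS."""
    rng = random.Random(20240101)
    for _ in range(200):
        n = rng.randint(1, 8)
        possible = [(a, b) for a in range(n) for b in range(n) if a != b]
        edges = rng.sample(possible, k=rng.randint(0, len(possible)))
        expect_acyclic = not _has_cycle_bruteforce(n, edges)
        got, witness = is_acyclic(_digraph_map(n, edges))
        assert got == expect_acyclic
        if not got:
            assert witness


def test_backbone_empty_without_instances():
    m = add_node(new_map("m"), Node(id="d", kind=K.RAW_DATA))
    assert extract_backbone(m) == []


def test_backbone_rejects_cyclic_map():
    with pytest.raises(CyclicMapError):
        extract_backbone(_digraph_map(2, [(0, 1), (1, 0)]))


def test_backbone_of_sulfidation_starts_with_synthesis_chain():
    chains = extract_backbone(build("sulfidation"))
    assert all(chain[:3] == ["inst_1", "inst_2", "inst_3"] for chain in chains)
    # transformation protocols bridge into the sulfidised instances
    tails = {chain[3] for chain in chains}
    assert tails == {"inst_sulfidised_low", "inst_sulfidised_mid",
                     "inst_sulfidised_high"}


def test_backbone_equals_topological_order_on_random_paths():
    """An instance path with property side-branches has exactly one chain:
    the instances in construction (= topological) order."""
    rng = random.Random(7)
    for _ in range(20):
        n = rng.randint(1, 6)
        m = new_map("m")
        order = [f"i{j}" for j in range(n)]
        for j, nid in enumerate(order):
            m = add_node(m, Node(id=nid, kind=K.INSTANCE))
            if j:
                m = add_edge(m, Edge(source=order[j - 1], target=nid))
            if rng.random() < 0.5:
                m = add_node(m, Node(id=f"p{j}", kind=K.EXPERIMENTAL_PROPERTY))
                m = add_edge(m, Edge(source=nid, target=f"p{j}"))
        assert extract_backbone(m) == [order]


def test_dangling_edge_is_r1_error():
    m = add_node(new_map("m"), Node(id="a", kind=K.INSTANCE))
    m.edges.append(Edge(source="a", target="ghost"))
    report = validate(m, strict_profile())
    assert not report.passed
    assert any(i.rule_id == "R1" and i.severity == "error" for i in report.issues)


def test_cycle_is_error_even_under_lenient():
    report = validate(_digraph_map(2, [(0, 1), (1, 0)]), lenient_profile())
    assert not report.passed
    assert report.by_rule("R2")


def test_fixtures_have_zero_errors_under_strict(fixture_map):
    assert validate(fixture_map, strict_profile()).passed


def test_reversed_measurement_chain_is_r4():
    m = new_map("m")
    m = add_node(m, Node(id="rd", kind=K.RAW_DATA))
    m = add_node(m, Node(id="mp", kind=K.MEASUREMENT_PROTOCOL))
    m = add_edge(m, Edge(source="rd", target="mp"))
    strict = validate(m, strict_profile())
    r4 = strict.by_rule("R4")
    assert r4 and r4[0].severity == "warning"
    assert "raw data" in r4[0].message
    lenient_r4 = validate(m, lenient_profile()).by_rule("R4")
    assert lenient_r4 and lenient_r4[0].severity == "info"


def test_unattached_material_is_info_only():
    m = add_node(new_map("m"), Node(id="mat", kind=K.MATERIAL))
    report = validate(m, strict_profile())
    assert report.passed
    assert any(i.rule_id == "R5" and i.severity == "info" for i in report.issues)


def test_empty_map_is_warning():
    report = validate(new_map("m"), lenient_profile())
    assert report.passed
    assert report.by_rule("R6")


def test_validate_is_idempotent(fixture_map):
    assert validate(fixture_map) == validate(fixture_map)


def test_lenient_issues_subset_of_strict():
    """Strictness monotonicity over fixtures and random maps: the lenient
    profile raises the same findings at no higher severity."""
    maps = [build(n) for n in ("sulfidation", "macrame_planning")]
    maps += [random_map(s, 6, 0.8) for s in range(10)]
    # plus a map with off-whitelist and inverted-chain edges
    m = new_map("odd")
    m = add_node(m, Node(id="pd", kind=K.PROCESSED_DATA))
    m = add_node(m, Node(id="spp", kind=K.SAMPLE_PREPARATION_PROTOCOL))
    m = add_edge(m, Edge(source="pd", target="spp"))
    maps.append(m)
    for mp in maps:
        strict = {(i.rule_id, i.ref): i.severity for i in validate(mp, strict_profile()).issues}
        lenient = {(i.rule_id, i.ref): i.severity for i in validate(mp, lenient_profile()).issues}
        assert set(lenient) == set(strict)
        for key, sev in lenient.items():
            assert _SEV_RANK[sev] <= _SEV_RANK[strict[key]]


def test_profile_loadable_from_yaml(tmp_path):
    cfg = tmp_path / "profile.yaml"
    cfg.write_text(
        "name: community\n"
        "base: strict\n"
        "adjacency:\n"
        "  RawData: [MeasurementProtocol]\n"
        "severity_overrides:\n"
        "  R4: error\n",
        encoding="utf-8",
    )
    prof = load_profile(cfg)
    assert prof.name == "community"
    assert prof.allows(K.RAW_DATA, K.MEASUREMENT_PROTOCOL)
    m = new_map("m")
    m = add_node(m, Node(id="rd", kind=K.RAW_DATA))
    m = add_node(m, Node(id="mp", kind=K.MEASUREMENT_PROTOCOL))
    m = add_edge(m, Edge(source="rd", target="mp"))
    report = validate(m, prof)
    assert not report.passed  # R4 upgraded to error by the override
    assert not report.by_rule("R3")  # pair whitelisted by the config


def test_completeness_full_and_missing():
    m = new_map("m")
    m = add_node(m, Node(id="med", kind=K.MEDIUM,
                         fields={"recipe": "ISO medium"}))
    m = add_node(m, Node(id="mat", kind=K.MATERIAL))  # nothing provided
    report = completeness(m)
    assert report.per_node["med"].score == 1.0
    mat = report.per_node["mat"]
    assert mat.score == 0.0 and "full_characterisation" in mat.missing
    assert 0.0 <= report.map_score <= 1.0


def test_completeness_unknown_kind():
    m = add_node(new_map("m"), Node(id="a", kind=K.INSTANCE))
    with pytest.raises(UnknownKindError):
        completeness(m, taxonomy={})


def test_adding_satisfying_link_never_decreases_scores(fixture_map):
    tax = builtin_taxonomy()
    base = completeness(fixture_map)
    m = fixture_map
    for nid in sorted(m.nodes):
        missing = base.per_node[nid].missing
        if not missing:
            continue
        slot = next(s for s in tax[m.nodes[nid].kind].requirement_slots
                    if s.slot_id == missing[0])
        m = attach_resource(m, nid, ResourceLink(
            target="extra.json", role=sorted(slot.satisfied_by)[0]))
    after = completeness(m)
    for nid in m.nodes:
        assert after.per_node[nid].score >= base.per_node[nid].score
    assert after.map_score >= base.map_score


def test_completeness_invariant_under_relabel_and_edge_reorder():
    m = build("oecd202")
    relabelled = m.model_copy(deep=True)
    for node in relabelled.nodes.values():
        node.label = node.label + " (renamed)"
    relabelled.edges.reverse()
    assert completeness(m).map_score == completeness(relabelled).map_score
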