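"""Worked-example builders and the random-map generator."""

import csv

import pytest

from instancemaps.errors import UnknownFixtureError
from instancemaps.fixtures import (
    FIXTURE_NAMES,
    build,
    culture_log_path,
    random_map,
)
from instancemaps.io import from_document, to_document
from instancemaps.taxonomy import NodeKind
from instancemaps.validation import is_acyclic, lenient_profile, validate

K = NodeKind


def test_unknown_fixture_name():
    with pytest.raises(UnknownFixtureError):
        build("fusion_reactor")


def test_builders_are_deterministic(fixture_map):
    assert to_document(build(fixture_map.id)) == to_document(fixture_map)


def test_all_fixtures_pass_lenient_with_zero_errors(fixture_map):
    report = validate(fixture_map, lenient_profile())
    assert report.passed
    assert not any(i.severity == "error" for i in report.issues)


def test_sulfidation_structure():
    m = build("sulfidation")
    synthesis = next(r for r in m.regions if r.id == "phase_synthesis")
    synth_instances = [nid for nid in synthesis.member_ids
                       if m.nodes[nid].kind == K.INSTANCE]
    assert len(synth_instances) == 3  # synthesis occurs in the first 3 instances
    tps = [n for n in m.nodes.values() if n.kind == K.TRANSFORMATION_PROTOCOL]
    assert len(tps) == 3  # one sulfidation protocol per PVP-AgNP concentration
    variants = {n.fields["variant"] for n in m.nodes.values()
                if n.kind == K.MATERIAL and "variant" in n.fields}
    assert len(variants) == len(tps) + 1  # sulfidised variants plus pristine
    assert "pristine" in variants


def test_daphnia_culture_metadata_and_log_attachment():
    m = build("daphnia_culture")
    medium = next(n for n in m.nodes.values() if n.kind == K.MEDIUM)
    assert medium.fields["medium_volume"] == "900 mL"
    assert medium.fields["vessel"] == "1 L"
    culture = m.nodes["inst_culture"]
    assert culture.fields["adults"] == "10-15"
    assert culture.fields["temperature"] == "20 °C"
    assert culture.fields["photoperiod"] == "16:8"
    raw = m.nodes["rd_log"]
    assert raw.kind == K.RAW_DATA
    [link] = raw.links
    assert link.role == "raw_data" and link.target.endswith(".csv")


def test_culture_log_csv_is_wellformed():
    path = culture_log_path()
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    assert len(rows) == 16  # 16 tracked culture days
    assert rows[0]["food_ml"] == "0.75" and rows[0]["medium_change"] == "x"
    assert {r["count_jar1"] for r in rows} == {"12"}


def test_oecd202_ends_in_dose_response_node():
    m = build("oecd202")
    sinks = [nid for nid in m.nodes
             if not any(e.source == nid for e in m.edges)]
    assert "pd_dose_response" in sinks
    assert m.nodes["pd_dose_response"].kind == K.PROCESSED_DATA


def test_oecd211_links_into_acute_map():
    m = build("oecd211")
    [ml] = m.map_links
    assert (ml.target_map, ml.target_node) == ("oecd202", "pd_dose_response")
    assert ml.source_node in m.nodes


def test_immunotox_regions_a_to_e():
    m = build("immunotox")
    labels = sorted(r.label for r in m.regions)
    assert labels == ["A", "B", "C", "D", "E"]
    for r in m.regions:
        assert r.member_ids and r.member_ids <= set(m.nodes)


def test_macrame_planning_has_shipping_and_red_overrides():
    m = build("macrame_planning")
    shipping = [n for n in m.nodes.values()
                if n.kind == K.TRANSFORMATION_PROTOCOL and "Shipping" in n.label]
    assert len(shipping) == 2
    red = [n for n in m.nodes.values() if n.colour_override]
    assert red and all(n.colour_override == "#e34a33" for n in red)
    assert all(n.kind not in (K.RAW_DATA, K.PROCESSED_DATA) for n in red)


def test_fixture_roundtrip_through_io(fixture_map):
    assert from_document(to_document(fixture_map)) == fixture_map


def test_random_map_without_instances():
    m = random_map(1, 0, 0.9)
    assert not any(n.kind == K.INSTANCE for n in m.nodes.values())


def test_random_map_determinism():
    assert to_document(random_map(42, 5, 0.5)) == to_document(random_map(42, 5, 0.5))


def test_random_maps_always_acyclic_and_lenient_clean():
    for seed in range(100):
        m = random_map(seed, n_instances=1 + seed % 8, branch_prob=0.5)
        assert is_acyclic(m) == (True, None)
        assert validate(m, lenient_profile()).passed
        backbone = [n.id for n in m.nodes.values() if n.kind == K.INSTANCE]
        assert len(backbone) == 1 + seed % 8


def test_fixture_name_registry():
    assert set(FIXTURE_NAMES) == {
        "sulfidation", "mesocosm", "daphnia_culture", "oecd202", "oecd211",
        "immunotox", "macrame_planning"}
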