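"""Worked-example maps and random-map generation.

Seven deterministic builders reproduce the structure of published
instance-map use cases spanning the typical nanosafety workflow:

* ``sulfidation`` — synthesis of PVP-coated silver nanoparticles (three
  consecutive instances), their physicochemical characterisation, and a
  sulfidation phase with one transformation protocol per PVP-AgNP
  concentration, yielding three sulfidised material variants plus the
  pristine one (four tracked nanoparticle variants in total).
* ``mesocosm`` — a soil mesocosm exposure: dispersion and soil spiking,
  organism addition, sampling, porewater separation, tissue-metal and
  biomass raw data, and a transcriptomics extension.  The published map is
  far larger; this fixture is a faithful skeleton of the nodes the study
  description enumerates.
* ``daphnia_culture`` — continuous *Daphnia magna* culture maintenance:
  high-hardness medium (900 mL in 1 L vessels), 10–15 adults per jar,
  20 °C, 16:8 h photoperiod, daily *Chlorella vulgaris* ration, and the
  offspring-tracking log shipped as a CSV resource on the raw-data node.
* ``oecd202`` — the OECD 202 *Daphnia* sp. acute immobilisation test,
  ending in the acute dose–response processed-data node.
* ``oecd211`` — the OECD 211 *Daphnia magna* reproduction test, whose
  exposure concentration is derived from the acute dose–response curve —
  expressed as a cross-map link into ``oecd202``.
* ``immunotox`` — immunotoxicity assessment of surface-functionalised
  silica nanomaterials, divided into annotation regions A–E (synthesis
  baseline, immunological profiling, protein binding, in silico corona
  prediction, epitope integrity).
* ``macrame_planning`` — planning map of a multi-partner project use case
  (antibiotics-loaded polymeric nanomaterials): production, shipping
  transformation protocols towards testing partners, and planning nodes
  deliberately overridden to the data-category red to flag open
  discussion points.

Fixtures encode only what the source descriptions state; rosters that are
not enumerated are skeletal.  :func:`random_map` generates seeded random
maps (instance backbone plus probabilistic side branches) for property
tests.
"""

from __future__ import annotations

import random
from importlib import resources
from pathlib import Path

from .errors import UnknownFixtureError
from .model import (
    Edge,
    InstanceMap,
    MapLink,
    Node,
    NodeMeta,
    Region,
    ResourceLink,
)
from .taxonomy import NodeKind

__all__ = ["FIXTURE_NAMES", "build", "random_map", "culture_log_path"]

K = NodeKind


def _node(nid: str, kind: NodeKind, label: str, **kwargs) -> Node:
    return Node(id=nid, kind=kind, label=label, **kwargs)


def _assemble(map_id, description, nodes, edges, regions=(), map_links=()):
    return InstanceMap(
        id=map_id,
        meta=NodeMeta(description=description),
        nodes={n.id: n for n in nodes},
        edges=[Edge(source=s, target=t) for s, t in edges],
        regions=list(regions),
        map_links=list(map_links),
    )


def culture_log_path() -> Path:
    """Filesystem path of the packaged daphnia culture-log CSV."""
    return Path(resources.files("instancemaps").joinpath("data/daphnia_culture_log.csv"))


def _sulfidation() -> InstanceMap:
    sulf_concs = [("low", "2 g/L"), ("mid", "5 g/L"), ("high", "10 g/L")]
    nodes = [
        _node("mat_agno3", K.MATERIAL, "Silver nitrate",
              fields={"chemical_composition": "AgNO3"}),
        _node("med_eg", K.MEDIUM, "Ethylene glycol",
              fields={"medium_identifier": "ethylene glycol"}),
        _node("mat_pvp", K.MATERIAL, "Polyvinylpyrrolidone (10k PVP)",
              fields={"chemical_composition": "PVP 10k"}),
        _node("inst_1", K.INSTANCE, "AgNO3 dissolved in ethylene glycol",
              fields={"components": "AgNO3; ethylene glycol"}),
        _node("inst_2", K.INSTANCE, "Reduction in presence of 10k PVP",
              fields={"components": "AgNO3; ethylene glycol; PVP"}),
        _node("inst_3", K.INSTANCE, "Purified PVP-AgNP suspension",
              fields={"components": "PVP-AgNP; water"}),
        _node("mat_pvp_agnp", K.MATERIAL, "PVP-AgNP",
              fields={"characterisation": "shape, size, crystalline phase",
                      "variant": "pristine"}),
        _node("prop_shape", K.EXPERIMENTAL_PROPERTY, "Particle shape",
              fields={"assay": "TEM"}),
        _node("prop_size", K.EXPERIMENTAL_PROPERTY, "Particle size",
              fields={"assay": "TEM/DLS"}),
        _node("prop_phase", K.EXPERIMENTAL_PROPERTY, "Crystalline phase",
              fields={"assay": "XRD"}),
    ]
    edges = [
        ("mat_agno3", "inst_1"), ("med_eg", "inst_1"),
        ("inst_1", "inst_2"), ("mat_pvp", "inst_2"),
        ("inst_2", "inst_3"), ("mat_pvp_agnp", "inst_3"),
        ("mat_pvp_agnp", "prop_shape"), ("mat_pvp_agnp", "prop_size"),
        ("mat_pvp_agnp", "prop_phase"),
    ]
    sulf_members = set()
    for tag, conc in sulf_concs:
        tp, inst, mat = f"tp_sulfidation_{tag}", f"inst_sulfidised_{tag}", f"mat_agnp_s_{tag}"
        nodes += [
            _node(tp, K.TRANSFORMATION_PROTOCOL,
                  f"Sulfidation at {conc} PVP-AgNP",
                  fields={"protocol": "sulfidation", "pvp_agnp_concentration": conc}),
            _node(inst, K.INSTANCE, f"Sulfidised AgNP suspension ({tag} S/Ag)"),
            _node(mat, K.MATERIAL, f"Sulfidised AgNP ({tag} S/Ag ratio)",
                  fields={"variant": f"sulfidised-{tag}",
                          "characterisation": "S/Ag ratio"}),
        ]
        edges += [("inst_3", tp), (tp, inst), (mat, inst)]
        sulf_members |= {tp, inst, mat}
    regions = [
        Region(id="phase_synthesis", label="Phase 1: PVP-AgNP synthesis",
               member_ids={"inst_1", "inst_2", "inst_3"}),
        Region(id="phase_sulfidation", label="Phase 2: sulfidation",
               member_ids=sulf_members),
    ]
    return _assemble(
        "sulfidation",
        "Synthesis of PVP-coated silver nanoparticles, their characterisation"
        " and sulfidation to increasing S/Ag ratios; four nanoparticle"
        " variants are tracked downstream.",
        nodes, edges, regions)


def _mesocosm() -> InstanceMap:
    nodes = [
        _node("mat_nm", K.MATERIAL, "Pristine nanomaterial",
              fields={"characterisation": "supplier, batch number, CAS"}),
        _node("med_soil", K.MEDIUM, "Test soil",
              fields={"medium_identifier": "standard soil"}),
        _node("inst_dispersion", K.INSTANCE,
              "Set up - nanomaterial dispersion"),
        _node("inst_spiked_soil", K.INSTANCE, "Nanomaterial-spiked soil"),
        _node("inst_organisms", K.INSTANCE, "Organisms added to mesocosm"),
        _node("inst_sampling", K.INSTANCE, "Sample collection timepoint"),
        _node("cprop_soil_ph", K.CURATED_PROPERTY, "Soil pH (pre-experiment)",
              fields={"reference": "supplier datasheet"}),
        _node("cprop_culture", K.CURATED_PROPERTY,
              "Species and culture maintenance information",
              fields={"reference": "culture records"}),
        # porewater metal chain
        _node("spp_porewater", K.SAMPLE_PREPARATION_PROTOCOL,
              "Soil porewater separation", fields={"sop": "porewater SOP"}),
        _node("mp_metals", K.MEASUREMENT_PROTOCOL,
              "Porewater metal concentration measurement",
              fields={"instrument": "ICP-MS"}),
        _node("rd_porewater_metals", K.RAW_DATA, "Porewater metal concentrations",
              fields={"dataset": "porewater metals"}),
        _node("dpp_bioacc", K.DATA_PROCESSING_PROTOCOL,
              "Bioaccumulation rate calculation",
              fields={"pipeline": "rate fitting"}),
        _node("pd_bioacc", K.PROCESSED_DATA, "Metal bioaccumulation rates",
              fields={"dataset": "bioaccumulation rates"}),
        # tissue / biomass chain
        _node("spp_tissue", K.SAMPLE_PREPARATION_PROTOCOL,
              "Tissue sample collection", fields={"sop": "tissue SOP"}),
        _node("mp_biomass", K.MEASUREMENT_PROTOCOL,
              "Organism biomass measurement", fields={"instrument": "balance"}),
        _node("rd_biomass", K.RAW_DATA, "Organism biomass data",
              fields={"dataset": "biomass"}),
        _node("rd_tissue_metals", K.RAW_DATA, "Tissue metal concentrations",
              fields={"dataset": "tissue metals"}),
        # transcriptomics extension
        _node("spp_rna", K.SAMPLE_PREPARATION_PROTOCOL, "RNA extraction",
              fields={"sop": "RNA extraction SOP"}),
        _node("mp_rtpcr", K.MEASUREMENT_PROTOCOL,
              "Transcriptomic analysis by real-time PCR",
              fields={"instrument": "qPCR cycler"}),
        _node("rd_transcriptomics", K.RAW_DATA, "Transcriptomics data",
              fields={"dataset": "qPCR Ct values"}),
    ]
    edges = [
        ("mat_nm", "inst_dispersion"),
        ("inst_dispersion", "inst_spiked_soil"),
        ("med_soil", "inst_spiked_soil"),
        ("inst_spiked_soil", "inst_organisms"),
        ("inst_organisms", "inst_sampling"),
        ("med_soil", "cprop_soil_ph"),
        ("inst_organisms", "cprop_culture"),
        ("inst_sampling", "spp_porewater"),
        ("spp_porewater", "mp_metals"),
        ("mp_metals", "rd_porewater_metals"),
        ("rd_porewater_metals", "dpp_bioacc"),
        ("dpp_bioacc", "pd_bioacc"),
        ("inst_sampling", "spp_tissue"),
        ("spp_tissue", "mp_biomass"),
        ("mp_biomass", "rd_biomass"),
        ("mp_biomass", "rd_tissue_metals"),
        ("inst_sampling", "spp_rna"),
        ("spp_rna", "mp_rtpcr"),
        ("mp_rtpcr", "rd_transcriptomics"),
    ]
    return _assemble(
        "mesocosm",
        "Soil mesocosm exposure of a nanomaterial: spiking, organism"
        " addition, sampling, porewater and tissue analyses, and a"
        " transcriptomics extension. Partial skeleton: the published map's"
        " full node roster is larger; only the enumerated nodes are encoded.",
        nodes, edges)


def _daphnia_culture() -> InstanceMap:
    nodes = [
        _node("med_hh", K.MEDIUM, "High hardness medium",
              fields={"medium_identifier": "high hardness medium",
                      "medium_volume": "900 mL",
                      "vessel": "1 L",
                      "aeration": "minimum 8 h before use"}),
        _node("mat_chlorella", K.MATERIAL, "Chlorella vulgaris algal feed",
              fields={"characterisation": "algal ration",
                      "ration_days_0_7": "7.5 mg C",
                      "ration_days_7_plus": "11.25 mg C",
                      "friday_ration": "double"}),
        _node("tp_feeding", K.TRANSFORMATION_PROTOCOL, "Daily algal feeding",
              fields={"protocol": "daily feeding schedule"}),
        _node("inst_culture", K.INSTANCE, "Running D. magna culture",
              fields={"components": "D. magna adults; high hardness medium",
                      "adults": "10-15",
                      "temperature": "20 °C",
                      "photoperiod": "16:8",
                      "medium_refresh": "three times per week"}),
        _node("inst_third_brood", K.INSTANCE,
              "Third-brood neonates for ecotoxicity testing",
              fields={"components": "third-brood D. magna neonates"}),
        _node("prop_do", K.EXPERIMENTAL_PROPERTY, "Dissolved oxygen",
              fields={"assay": "DO probe, every 2-3 days"}),
        _node("prop_ph", K.EXPERIMENTAL_PROPERTY, "Medium pH",
              fields={"assay": "pH meter"}),
        _node("spp_count", K.SAMPLE_PREPARATION_PROTOCOL,
              "Offspring collection per culture jar",
              fields={"sop": "brood counting SOP"}),
        _node("mp_count", K.MEASUREMENT_PROTOCOL, "Offspring counting",
              fields={"instrument": "manual count"}),
        _node("rd_log", K.RAW_DATA, "Culture performance log",
              fields={"dataset": "offspring per brood, food, medium changes"},
              links=[ResourceLink(target="daphnia_culture_log.csv",
                                  role="raw_data", media_hint="text/csv")]),
    ]
    edges = [
        ("med_hh", "inst_culture"),
        ("mat_chlorella", "inst_culture"),
        ("inst_culture", "tp_feeding"),
        ("tp_feeding", "inst_third_brood"),
        ("inst_culture", "inst_third_brood"),
        ("med_hh", "prop_do"),
        ("med_hh", "prop_ph"),
        ("inst_culture", "spp_count"),
        ("spp_count", "mp_count"),
        ("mp_count", "rd_log"),
    ]
    return _assemble(
        "daphnia_culture",
        "Maintenance of continuous Daphnia magna cultures: 1 L beakers with"
        " 900 mL high hardness medium, 10-15 adults, 20 °C under a 16:8"
        " light/dark cycle, daily Chlorella vulgaris ration, offspring"
        " tracking as culture QA/QC.",
        nodes, edges)


def _oecd202() -> InstanceMap:
    nodes = [
        _node("mat_test_item", K.MATERIAL, "Test nanomaterial",
              fields={"characterisation": "stock characterisation"}),
        _node("med_test", K.MEDIUM, "Test medium",
              fields={"recipe": "lab SOP medium (guideline leaves choice open)"}),
        _node("inst_stock", K.INSTANCE, "Stock dispersion",
              fields={"components": "test item; test medium"}),
        _node("inst_dilutions", K.INSTANCE, "Test concentration series",
              fields={"components": "stock dispersion; test medium"}),
        _node("inst_exposure", K.INSTANCE, "Neonates exposed for 48 h",
              fields={"components": "neonates; concentration series"}),
        _node("spp_setup", K.SAMPLE_PREPARATION_PROTOCOL,
              "Distribution of neonates to test vessels",
              fields={"sop": "lab acute test SOP"}),
        _node("mp_immobilisation", K.MEASUREMENT_PROTOCOL,
              "Immobilisation scoring at 24 h and 48 h",
              fields={"instrument": "visual inspection"}),
        _node("rd_counts", K.RAW_DATA, "Immobilisation counts",
              fields={"dataset": "immobilised per vessel"},
              links=[ResourceLink(target="acute_data_capture_template.xlsx",
                                  role="data_file",
                                  media_hint="spreadsheet")]),
        _node("dpp_fit", K.DATA_PROCESSING_PROTOCOL, "Dose-response fitting",
              fields={"pipeline": "concentration-response regression"}),
        _node("pd_dose_response", K.PROCESSED_DATA,
              "Acute dose-response curve (EC50)",
              fields={"dataset": "dose-response curve"}),
    ]
    edges = [
        ("mat_test_item", "inst_stock"),
        ("med_test", "inst_dilutions"),
        ("inst_stock", "inst_dilutions"),
        ("inst_dilutions", "inst_exposure"),
        ("inst_exposure", "spp_setup"),
        ("spp_setup", "mp_immobilisation"),
        ("mp_immobilisation", "rd_counts"),
        ("rd_counts", "dpp_fit"),
        ("dpp_fit", "pd_dose_response"),
    ]
    return _assemble(
        "oecd202",
        "OECD 202 Daphnia sp. acute immobilisation test, from stock"
        " dispersion to the acute dose-response curve.",
        nodes, edges)


def _oecd211() -> InstanceMap:
    nodes = [
        _node("mat_test_item", K.MATERIAL, "Test nanomaterial",
              fields={"characterisation": "stock characterisation"}),
        _node("med_test", K.MEDIUM, "Test medium",
              fields={"recipe": "lab SOP medium"}),
        _node("inst_exposure_conc", K.INSTANCE,
              "Exposure concentration (EC10/EC30 from acute test)",
              fields={"components": "test item at sub-acute concentration"}),
        _node("inst_chronic", K.INSTANCE, "21 d reproduction exposure",
              fields={"components": "adult daphnids; exposure concentration"}),
        _node("spp_renewal", K.SAMPLE_PREPARATION_PROTOCOL,
              "Semi-static medium renewal and feeding",
              fields={"sop": "chronic test SOP"}),
        _node("mp_reproduction", K.MEASUREMENT_PROTOCOL,
              "Offspring counting per parent animal",
              fields={"instrument": "manual count"}),
        _node("rd_offspring", K.RAW_DATA, "Offspring counts",
              fields={"dataset": "living offspring per parent"}),
        _node("dpp_stats", K.DATA_PROCESSING_PROTOCOL,
              "Reproduction statistics",
              fields={"pipeline": "ECx estimation"}),
        _node("pd_ec10", K.PROCESSED_DATA, "Chronic EC10 (reproduction)",
              fields={"dataset": "EC10"}),
    ]
    edges = [
        ("mat_test_item", "inst_exposure_conc"),
        ("med_test", "inst_chronic"),
        ("inst_exposure_conc", "inst_chronic"),
        ("inst_chronic", "spp_renewal"),
        ("spp_renewal", "mp_reproduction"),
        ("mp_reproduction", "rd_offspring"),
        ("rd_offspring", "dpp_stats"),
        ("dpp_stats", "pd_ec10"),
    ]
    map_links = [MapLink(
        source_node="inst_exposure_conc", target_map="oecd202",
        target_node="pd_dose_response",
        relation="exposure concentration is derived from the acute"
                 " dose-response curve")]
    return _assemble(
        "oecd211",
        "OECD 211 Daphnia magna reproduction test; the exposure"
        " concentration links back to the acute dose-response curve of the"
        " OECD 202 map.",
        nodes, edges, map_links=map_links)


def _immunotox() -> InstanceMap:
    nodes = [
        # section A: synthesis, functionalisation, characterisation baseline
        _node("inst_synthesis", K.INSTANCE, "SiO2 NM synthesis (Stoeber/emulsion)",
              fields={"components": "SiO2 precursors"}),
        _node("inst_functionalised", K.INSTANCE,
              "Surface-functionalised SiO2 NM (amino/carboxyl)",
              fields={"components": "SiO2 NM; surface groups"}),
        _node("mat_sio2", K.MATERIAL, "SiO2 nanomaterial (50-100 nm)",
              fields={"characterisation": "size, surface modification"}),
        _node("spp_char", K.SAMPLE_PREPARATION_PROTOCOL, "Dispersion for characterisation",
              fields={"sop": "dispersion SOP"}),
        _node("mp_dls", K.MEASUREMENT_PROTOCOL, "Physicochemical characterisation (TEM/NTA/DLS)",
              fields={"instrument": "TEM, NTA, DLS"}),
        _node("rd_char", K.RAW_DATA, "Characterisation raw data",
              fields={"dataset": "size distributions"}),
        # section B: immunological profiling with APC models
        _node("inst_apc", K.INSTANCE, "Monocyte-derived dendritic cells (APC model)",
              fields={"components": "MoDCs from human whole blood"}),
        _node("inst_apc_exposed", K.INSTANCE, "APCs incubated with SiO2 NMs",
              fields={"components": "MoDCs; SiO2 NMs"}),
        _node("mp_flow", K.MEASUREMENT_PROTOCOL, "Flow cytometry and ELISA",
              fields={"instrument": "flow cytometer"}),
        _node("rd_activation", K.RAW_DATA, "Immunologic activation profile",
              fields={"dataset": "surface markers, cytokines"}),
        # section C: protein binding capacity
        _node("inst_conjugates", K.INSTANCE, "NM-protein conjugates",
              fields={"components": "SiO2 NMs; proteins"}),
        _node("mp_gel", K.MEASUREMENT_PROTOCOL, "Gel electrophoresis quantification",
              fields={"instrument": "gel electrophoresis"}),
        _node("rd_binding", K.RAW_DATA, "Protein binding data",
              fields={"dataset": "bound/unbound protein"}),
        # section D: in silico corona prediction vs in vitro determination
        _node("dpp_corona", K.DATA_PROCESSING_PROTOCOL,
              "In silico protein corona prediction",
              fields={"software": "corona prediction tools"}),
        _node("cp_corona", K.COMPUTED_PROPERTY, "Predicted corona composition",
              fields={"model": "corona prediction"}),
        # section E: epitope integrity / structural alterations
        _node("mp_structure", K.MEASUREMENT_PROTOCOL,
              "Structural alteration analysis of bound proteins",
              fields={"instrument": "spectroscopy"}),
        _node("rd_epitope", K.RAW_DATA, "Epitope integrity data",
              fields={"dataset": "structural alterations"}),
    ]
    edges = [
        ("inst_synthesis", "inst_functionalised"),
        ("mat_sio2", "inst_functionalised"),
        ("inst_functionalised", "spp_char"),
        ("spp_char", "mp_dls"),
        ("mp_dls", "rd_char"),
        ("inst_apc", "inst_apc_exposed"),
        ("inst_functionalised", "inst_apc_exposed"),
        ("inst_apc_exposed", "mp_flow"),
        ("mp_flow", "rd_activation"),
        ("inst_functionalised", "inst_conjugates"),
        ("inst_conjugates", "mp_gel"),
        ("mp_gel", "rd_binding"),
        ("rd_binding", "dpp_corona"),
        ("dpp_corona", "cp_corona"),
        ("inst_conjugates", "mp_structure"),
        ("mp_structure", "rd_epitope"),
    ]
    regions = [
        Region(id="section_a", label="A",
               member_ids={"inst_synthesis", "inst_functionalised", "mat_sio2",
                           "spp_char", "mp_dls", "rd_char"}),
        Region(id="section_b", label="B",
               member_ids={"inst_apc", "inst_apc_exposed", "mp_flow",
                           "rd_activation"}),
        Region(id="section_c", label="C",
               member_ids={"inst_conjugates", "mp_gel", "rd_binding"}),
        Region(id="section_d", label="D",
               member_ids={"dpp_corona", "cp_corona"}),
        Region(id="section_e", label="E",
               member_ids={"mp_structure", "rd_epitope"}),
    ]
    return _assemble(
        "immunotox",
        "Immunotoxicity workflow for surface-functionalised SiO2"
        " nanomaterials with antigen-presenting-cell models, divided into"
        " sections A-E (synthesis baseline, immunological profiling, protein"
        " binding, in silico corona prediction, epitope integrity).",
        nodes, edges, regions)


def _macrame_planning() -> InstanceMap:
    red = "#e34a33"  # data-category red, misused on purpose to flag open points
    nodes = [
        _node("inst_production", K.INSTANCE,
              "Antibiotics-loaded polymeric NM production",
              fields={"components": "polymeric NM; antibiotic load"}),
        _node("inst_imaging_controls", K.INSTANCE, "Imaging control batch",
              fields={"components": "labelled control NM"}),
        _node("tp_ship_tox", K.TRANSFORMATION_PROTOCOL,
              "Shipping to human-toxicity partner",
              fields={"protocol": "shipping and chain of custody"}),
        _node("tp_ship_ecotox", K.TRANSFORMATION_PROTOCOL,
              "Shipping to ecotoxicity partner",
              fields={"protocol": "shipping and chain of custody"}),
        _node("inst_at_tox", K.INSTANCE, "Material at human-tox partner",
              fields={"components": "shipped NM batch"}),
        _node("inst_at_ecotox", K.INSTANCE, "Material at ecotox partner",
              fields={"components": "shipped NM batch"}),
        _node("inst_aerosol", K.INSTANCE,
              "Aerosol exposure of in vitro lung model (to be discussed)",
              fields={"components": "aerosolised NM; lung model"},
              colour_override=red),
        _node("mp_aerosol_quant", K.MEASUREMENT_PROTOCOL,
              "Aerosol quantification (feasibility open)",
              fields={"instrument": "to be decided"},
              colour_override=red),
        _node("spp_eol", K.SAMPLE_PREPARATION_PROTOCOL,
              "End-of-life sample preparation (soot/char)",
              fields={"sop": "degradation scenarios"}),
        _node("mp_ecotox", K.MEASUREMENT_PROTOCOL, "Ecotoxicity testing",
              fields={"instrument": "OECD guideline battery"}),
        _node("rd_ecotox", K.RAW_DATA, "Ecotoxicity raw data",
              fields={"dataset": "endpoint measurements"}),
    ]
    edges = [
        ("inst_production", "inst_imaging_controls"),
        ("inst_production", "tp_ship_tox"),
        ("inst_production", "tp_ship_ecotox"),
        ("tp_ship_tox", "inst_at_tox"),
        ("tp_ship_ecotox", "inst_at_ecotox"),
        ("inst_at_tox", "inst_aerosol"),
        ("inst_aerosol", "mp_aerosol_quant"),
        ("inst_at_ecotox", "spp_eol"),
        ("spp_eol", "mp_ecotox"),
        ("mp_ecotox", "rd_ecotox"),
    ]
    return _assemble(
        "macrame_planning",
        "Planning map for a multi-partner use case on antibiotics-loaded"
        " polymeric nanomaterials: production, shipping to testing partners,"
        " and red-overridden planning nodes marking steps still under"
        " discussion.",
        nodes, edges)


_BUILDERS = {
    "sulfidation": _sulfidation,
    "mesocosm": _mesocosm,
    "daphnia_culture": _daphnia_culture,
    "oecd202": _oecd202,
    "oecd211": _oecd211,
    "immunotox": _immunotox,
    "macrame_planning": _macrame_planning,
}

FIXTURE_NAMES: tuple[str, ...] = tuple(_BUILDERS)


def build(name: str) -> InstanceMap:
    """Build the named worked-example map (deterministic across calls)."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture: {name!r} (choose from {', '.join(FIXTURE_NAMES)})"
        ) from None
    return builder()


def random_map(seed: int, n_instances: int = 5, branch_prob: float = 0.5) -> InstanceMap:
    """Seeded random map: an instance backbone with probabilistic branches.

    The backbone is a chain of ``n_instances`` instance nodes in time
    order; each instance draws side branches (material+medium, a property,
    or a full measurement chain) with probability ``branch_prob``.  All
    edges point forward, so the result is acyclic by construction and
    passes lenient validation with zero errors.  Identical seeds yield
    identical maps.
    """
    if n_instances < 0:
        raise ValueError("n_instances must be >= 0")
    if not 0 <= branch_prob <= 1:
        raise ValueError("branch_prob must be in [0, 1]")
    rng = random.Random(seed)
    nodes: list[Node] = []
    edges: list[tuple[str, str]] = []
    prev: str | None = None
    for i in range(n_instances):
        nid = f"inst_{i:03d}"
        nodes.append(_node(nid, K.INSTANCE, f"Instance {i}",
                           fields={"components": f"sample state {i}"}))
        if prev is not None:
            edges.append((prev, nid))
        prev = nid
        if rng.random() >= branch_prob:
            continue
        branch = rng.choice(["instance-family", "property", "measurement"])
        if branch == "instance-family":
            mat, med = f"mat_{i:03d}", f"med_{i:03d}"
            nodes.append(_node(mat, K.MATERIAL, f"Material {i}",
                               fields={"characterisation": "basic"}))
            nodes.append(_node(med, K.MEDIUM, f"Medium {i}",
                               fields={"recipe": "standard"}))
            edges += [(mat, nid), (med, nid)]
        elif branch == "property":
            kind = rng.choice([K.CURATED_PROPERTY, K.COMPUTED_PROPERTY,
                               K.EXPERIMENTAL_PROPERTY])
            pid = f"prop_{i:03d}"
            node = _node(pid, kind, f"Property {i}")
            if rng.random() < 0.5:
                node.links.append(ResourceLink(target=f"prop_{i}.json",
                                               role="data_file"))
            nodes.append(node)
            edges.append((nid, pid))
        else:
            chain_ids = [f"spp_{i:03d}", f"mp_{i:03d}", f"rd_{i:03d}"]
            chain_kinds = [K.SAMPLE_PREPARATION_PROTOCOL,
                           K.MEASUREMENT_PROTOCOL, K.RAW_DATA]
            if rng.random() < 0.5:
                chain_ids += [f"dpp_{i:03d}", f"pd_{i:03d}"]
                chain_kinds += [K.DATA_PROCESSING_PROTOCOL, K.PROCESSED_DATA]
            prev_c = nid
            for cid, ckind in zip(chain_ids, chain_kinds):
                nodes.append(_node(cid, ckind, f"{ckind.value} {i}"))
                edges.append((prev_c, cid))
                prev_c = cid
    m = _assemble(f"random-{seed}", f"Random map (seed {seed})", nodes, edges)
    instance_ids = [n.id for n in nodes if n.kind == K.INSTANCE]
    if instance_ids and rng.random() < branch_prob:
        k = max(1, len(instance_ids) // 2)
        m.regions.append(Region(id="region_backbone", label="backbone sample",
                                member_ids=set(instance_ids[:k])))
    return m
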