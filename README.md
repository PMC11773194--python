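# instancemaps

A Python implementation of the **instance map**: a directed-graph format for
describing experimental workflows, developed in nanosafety research and
useful wherever a study's provenance, protocols and data flows need to be
documented — ideally at the study-design stage, before any data exists.

## The model

An *instance* is the object under study (a nanomaterial, an organism
culture, a product sample) in its medium at a specific moment in time; any
physical or chemical change creates a new instance.  An instance map is a
directed, often tree-like graph whose main branches are consecutive
instances, with side branches describing each instance:

* **instance-family** nodes — `Instance`, `Material`, `Medium`;
* **protocol** nodes — `TransformationProtocol`, `SamplePreparationProtocol`,
  `MeasurementProtocol`, `DataProcessingProtocol`;
* **property** nodes — `CuratedProperty`, `ComputedProperty`,
  `ExperimentalProperty`;
* **data** nodes — `RawData`, `ProcessedData`.

Twelve kinds, four colour-coded categories.  Edges point forward in
workflow order, so instance chains encode time and measurement chains
follow the stage order *sample preparation → measurement → raw data → data
processing → processed data*.  Nodes link out to the resources that carry
the actual content (protocols, SOPs, ELN pages, data files); each kind has
*requirement slots* describing the metadata it should cover, and the
completeness engine scores a map against them:

```
score(node) = |satisfied slots| / |required slots|,   map score = mean over nodes
```

The package provides the data model, canonical JSON serialisation (YAML
read), profile-driven structural validation, completeness scoring, map
diffing/merging and cross-map link resolution, export to DOT / Mermaid /
GraphML, import of legacy five-category (NIKC-style) curation tables,
seven worked-example maps, and an `instancemaps` command-line tool.

## Worked example

```python
import instancemaps as im

m = im.build("sulfidation")          # PVP-AgNP synthesis + sulfidation map
print(im.extract_backbone(m)[0])     # the main instance chain
report = im.validate(m, im.strict_profile())
comp = im.completeness(m)
print(report.passed, len(report.issues), round(comp.map_score, 2))
```

prints

```
['inst_1', 'inst_2', 'inst_3', 'inst_sulfidised_high']
True 0 0.76
```

— the synthesis backbone runs through three instances into a sulfidised
variant, the map has no structural findings under the strict profile, and
roughly three quarters of the per-kind metadata slots are already covered
(the characterisation property nodes carry no linked numeric data yet,
which is exactly what a completeness check at the design stage should
reveal).

The same from the shell:

```sh
instancemaps example sulfidation -o sulf.json
instancemaps validate sulf.json            # exit 0 = clean, 1 = errors, 2 = bad input
instancemaps report sulf.json              # node counts per kind/category
instancemaps render sulf.json --format mermaid -o sulf.mmd
instancemaps diff old.json new.json --json # changeset between versions
instancemaps convert legacy.csv -o map.json
```

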