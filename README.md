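# ocrvkit

Ontology-guided semantic data integration for multi-level cancer-survival
analysis, at desk scale and fully synthetic.

Cancer-survival studies increasingly need predictors from more than one
source system: individual-level factors from a state cancer registry,
community behavior from a weighted telephone survey, and tract- or
county-level context (social vulnerability, education and poverty,
rurality, county health rankings). Pooling these into one analytic matrix
is usually done with ad-hoc SQL, which buries the variable definitions and
regrouping decisions in code. `ocrvkit` implements the alternative:
**ontology-based data access (OBDA)**. A small application ontology — the
Ontology for Cancer Research Variables (OCRV) — fixes the shared
vocabulary and encodes the data-analysis knowledge (category regroupings,
survey definitions, value constraints); declarative *mapping axioms*
realize relational rows as a virtual RDF graph; and semantic queries over
that graph, with subclass reasoning, produce the pooled dataset.

Because real registry data are restricted, the package ships a seeded
synthetic generator for all five source systems with *planted ground
truth* (known county rates, known inconsistent records), so every stage is
testable end to end.

## What is inside

| Module | Role |
| --- | --- |
| `ocrvkit.ontology` | The OCRV model: 30 registry classes, 23 properties, subclass axioms, `allValuesFrom` restrictions; closure/depth queries; Turtle export |
| `ocrvkit.obda` | Mapping axioms (`mappingId` / `source` SQL / `target` triple template), virtual-graph materialization, BGP query answering with subclass expansion, closed-world restriction checking |
| `ocrvkit.sources` | Seeded synthetic registry / survey / SVI / census / RUCA / county-health tables with a `TruthBundle` |
| `ocrvkit.queries` | The four query types (direct, transform, geographic linkage, reasoned), the ICD-O-3 cancer-type classifier, marital and RUCA regrouping |
| `ocrvkit.measures` | Survey-weighted county rates and the sex-specific heavy-drinker rule |
| `ocrvkit.qc` | Ontology-driven consistency checks (computed vs recorded age at diagnosis, date/code formats, ranges) |
| `ocrvkit.pipeline` | The 6-step integration run producing the pooled matrix (one row per diagnosis record) |

Two definitional rules carry most of the semantic weight:

* **Current smoker** (survey definition): a respondent who (1) now smokes
  every day or some days *and* (2) has smoked at least 100 cigarettes in
  their entire life. Condition (1) lives in the subclass structure
  (`BRFSS current every day smoker` and `BRFSS current someday smoker`
  under `BRFSS current smoker`); condition (2) is an `owl:allValuesFrom`
  restriction on `has smoking status`, enforced closed-world at query
  time.
* **Weighted county rate**: for county *c*,
  `rate(c) = Σ final_weight(qualifying respondents in c) / Σ final_weight(eligible respondents in c)`,
  with `final_weight = design_weight × raking_adjustment`.

## Worked example

```bash
ocrvkit generate --seed 3 --out demo --n-patients 200 \
    --brfss-per-county 50 --tracts-per-county 2
ocrvkit materialize --source demo --out ocrv.ttl
ocrvkit pool --source demo --out pooled.csv
```

prints

```
wrote 205 registry records to demo
ontology: 30 classes, 23 properties, max depth 5
virtual graph: 13315 triples
pooled matrix: 205 rows x 6 columns; 5 QC findings
```

The 200 patients yield 205 diagnosis records (a few patients carry a
second primary), and the pooled matrix keeps one row per record. The
ontology census — 30 created classes, 23 added properties, maximum class
depth 5 — is recomputed from the in-memory model, and the 5 QC findings
are the records whose recorded age at diagnosis disagrees with the age
computed from birth year and diagnosis date (the generator plants a known
2% of these). The matrix itself:

```
Patient ID,Biological Sex,Marital Status,Year of Diagnosis,SVI Socioeconomic Status,Survival
1,female,married,2004,0.25641,6.0
2,female,married,2004,0.435897,19.0
...
```

Marital status arrives regrouped (the raw categories widowed, divorced,
separated, unmarried and never-married all resolve to `single` through the
subclass axioms), year of diagnosis is extracted from the raw `yyyymmdd`
date, the SVI socioeconomic rank is joined through the patient's census
tract, and Survival is the survival time in months.

The same run is available as a library call:

```python
import ocrvkit as k
result = k.build_pooled_dataset(k.RunConfig(generate=k.SourceConfig(), seed=3))
result.matrix          # the pooled DataFrame
result.county_rates    # weighted smoking / heavy-drinking rates per county
result.qc_findings     # consistency findings
```

The three integration scenarios (adding a contextual predictor, swapping
the rurality scheme, regrouping RUCA codes differently) are pure
configuration changes — see `examples/*.yaml`.

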