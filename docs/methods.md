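# Methods

## The integration model

`ocrvkit` implements ontology-based data access (OBDA) over relational
sources. Three layers:

1. **Ontology (OCRV).** A structural model — classes, object/data
   properties, subclass axioms, universal (`owl:allValuesFrom`)
   restrictions — holding the analysis knowledge: which raw categories
   regroup to which analysis groups, how the survey defines a current
   smoker, which properties are functional. The entity registry comprises
   30 classes and 23 properties (22 object + 1 data, the survey final
   weight) in the `ocrv` namespace; a handful of terms from reference
   ontologies (NCI Thesaurus, a time-event ontology) are stubbed locally
   with canonical-style IRIs rather than imported wholesale. Support
   classes needed for regrouping and the n-ary diagnosis pattern (the five
   raw marital categories under `single`, `married`, `diagnosis relation`,
   `diagnosed tumor type`, `date of diagnosis`) and a few helper
   properties (`has value`, `has rurality status`, `has survival months`,
   `has birth year`, `has recorded age at diagnosis`) exist in the model
   but are flagged outside the entity registry, so the census
   (`entity_counts`) reports the registry exactly.
2. **Mapping axioms.** Each axiom is a (`mappingId`, `source` SQL query,
   `target` triple template) triple; placeholders `{column}` are filled
   per result row, literals carry datatype tags, and rows with NULL in a
   referenced column emit nothing. The union over all axioms is the
   *virtual graph*. Shared entities (patients, tracts, counties) are
   minted from their source keys — `ocrv:patient/<id>`,
   `ocrv:tract/<geoid>` — so cross-table references join by IRI identity.
3. **Query answering.** Conjunctive basic graph patterns with optional
   FILTER comparisons and named value transforms (`year`, `localname`).
   A pattern `?x rdf:type C` is expanded over the reflexive-transitive
   subclass closure of `C`. Results are deduplicated and canonically
   sorted, so answering is deterministic.

A deliberate engineering choice: rather than rewriting semantic queries
into SQL on the fly, the graph is **materialized in memory** and queried
there. At the scales this package targets (tens of thousands of patients,
a few hundred thousand survey rows, roughly 1.5 M triples at the default
study conditions) this is simple and fast, and the test suite pins every
shipped query to an independently written relational query over the same
sources, which is the correctness contract a rewriting engine would
otherwise provide.

### Reasoning semantics

Only two inference services are provided, because they are the only two
the integration uses:

* **Subclass expansion** — sound and complete transitive closure over the
  asserted subclass edges (the hierarchy is validated acyclic).
* **Closed-world restriction checking** — under open-world OWL semantics
  an `allValuesFrom` restriction never *classifies* individuals; here it
  is enforced operationally: every asserted value of the restricted
  property on a member of the restricted class must be asserted in the
  filler class, otherwise a violation is reported. An individual with no
  value passes vacuously. The reasoned smoker query therefore returns
  exactly the respondents satisfying the two-condition survey rule:
  membership in a current-smoker subclass (from the smoking-frequency
  item) minus restriction violators (from the 100-cigarette item). A
  respondent typed into a smoker subclass whose 100-cigarette answer is
  missing carries a status value outside the filler and is excluded — the
  conservative reading of the rule.

Full OWL-DL tableau reasoning, SPARQL 1.1, OPTIONAL/UNION/aggregation are
out of scope; aggregation lives in the measures module.

### Depth convention

The ontology census reports a maximum class depth of 5. Depth counts the
nodes on the longest parent chain within the shipped hierarchy (a root
class has depth 1); the deepest chains run
`property or attribute > personal attribute > smoking status > BRFSS
current smoker > BRFSS current every day smoker` and the marital chain
ending in the raw categories under `single`. Since the full upper
ontologies are not imported, depth is measured from the most general stub
each tree hangs from.

## Derived measures

For county *c* and qualifier *q*:

```
rate_q(c) = Σ final_weight over respondents in c satisfying q
            ─────────────────────────────────────────────────
            Σ final_weight over eligible respondents in c
```

with `final_weight = design_weight × raking_adjustment`, exactly.
Qualifiers: the two-condition current-smoker rule, and the sex-specific
heavy-drinker rule (strictly more than 14 drinks/week for males, 7 for
females). **Eligibility convention:** respondents missing an item the
qualifier needs are excluded from numerator *and* denominator (a
denominator-inclusive variant is available). Respondents outside the
catchment counties never enter any denominator. The rate is scale
invariant in the weights and bounded in [0, 1]; no design-based variance
estimation is attempted.

## Consistency checks

Age at diagnosis is recomputed as `year(diagnosis_date) − birth_year`
(the registry carries birth year only, so the year-difference convention
is the only one available; the synthetic generator uses the same
convention, and a ±1-year tolerance knob exists for real data where
birthday boundaries matter — default 0). Further checks: unparseable
`yyyymmdd` dates, birth year after diagnosis year, computed age under 18
(a warning — the study population is adults), ICD-O-3 codes failing
`C\d\d(.\d)?`, county unhealthy-days outside [0, 30]. Findings are pure
data (never mutations); dropping error records is an explicit pipeline
policy (`drop_on_error`).

## The synthetic generator

The generator emulates the *structure* of the five source systems, not
their marginal distributions. Defaults are the study conditions:

| Parameter | Default | Note |
| --- | --- | --- |
| counties | the 20 named catchment counties | synthetic FIPS `12` + index |
| tracts per county | 4 | GEOID = county FIPS + 6 digits |
| registry size | 50,151 patients | breast/lung/colorectal mix 18,644 / 21,552 / 9,955 |
| diagnosis window | 1996–2010 | dates `yyyymmdd` |
| second-diagnosis rate | 0.05 | second primary drawn later than the first, so both are adult |
| age-inconsistency rate | 0.02 | recorded age offset by ±1–5 years, logged to the truth bundle |
| survey size | 5,000 respondents/county | |
| planted smoking rates | linspace(0.05, 0.40) over counties | heavy drinking: linspace(0.05, 0.25) |
| missing-item rate | 0.02 | smoking items only |
| weights | design ~ U(0.8, 1.2), raking ~ U(0.95, 1.05) | final = product, exact |

Smoker status is drawn Bernoulli at the planted county rate among
non-missing respondents, independently of the weights, so the weighted
rate estimator is consistent for the planted rate with essentially
binomial error (the weight distribution is deliberately narrow; its
design effect is ≈1.02). Non-smokers include former smokers
(`not at all`/`yes`) and light experimenters (`some days`/`no`) so the
restriction-violation path is exercised by default data. SVI theme ranks
are min–max percentile ranks in [0, 1] of the theme factor sums across
all tracts (ties get averaged ranks; higher = more vulnerable; the 15
factors split 4/4/2/5 over the four themes). Patient-level attributes
(sex, race, marital status, residency, birth year) are constant across a
patient's records; per-record attributes (site, date, stage, procedure,
survival) vary.

Everything is a pure function of `(config, seed)` — identical inputs give
byte-identical CSV output — and every planted quantity is recorded in the
`TruthBundle`.

What passing tests on this generator do **not** show: realistic
covariate–survival relationships (no survival model is fit), realistic
geographic clustering, survey non-response structure, or real coding
noise beyond the planted inconsistencies. The "Survival" column is
survival months; no claim is made about units in any external layout it
mimics.

## Pipeline

`build_pooled_dataset` runs: connect sources → materialize the graph →
list diagnosis records (the patient identifier is the first column) →
execute each selected factor's query and left-join it onto the record
spine (cardinality is asserted unchanged; missing contextual values stay
empty, never imputed) → attach derived county rates through the residency
county → run consistency checks under the configured policy → write CSV
with a stable row order (patient id, then diagnosis date). The matrix has
one row per *diagnosis record*; regrouped values are the default output
(raw categories remain available through the catalog). The three
integration scenarios — added contextual predictor, county-level
urban–rural scheme instead of RUCA (user-supplied code table; no external
classification data ships), alternative RUCA grouping — are expressible
purely as configuration (`examples/*.yaml`).

## Numerical and testing choices

* Literals are typed (`string`/`integer`/`decimal`/`date`); numeric
  comparisons in tests use 1e-9 absolute tolerance; generated floats are
  rounded (weights and ranks to 6 decimals) so CSV round-trips are exact.
* Categorical per-record attributes (sex, stage, ...) are carried as plain
  literals in object position, matching the flat query outputs the
  integration needs, rather than reified value individuals.
* Rate-recovery tests compare each county's weighted rate with its
  planted value within 3 binomial standard errors computed at the
  *eligible* respondent count; the suite runs at fixed seeds.
* Test and acceptance problem sizes: unit fixtures use 60–400 patients
  over the full 20-county catchment with 2 tracts/county; the rate
  recovery runs at the full survey scale (5,000 × 20); the acceptance
  script additionally runs the complete default pipeline (50,151 patients,
  ≈1.5 M triples, ≈1 minute).

## Known limitations

* The engine answers conjunctive queries only; no negation, optional
  patterns or aggregation inside the query language.
* Closed-world restriction checking is a design decision, not standard
  OWL entailment; systems expecting open-world semantics will disagree on
  individuals with missing property values.
* The census of "created" entities depends on a registry flag; the
  support classes for regrouping and the n-ary diagnosis pattern are
  deliberately outside it (the printed counts exclude them), which is a
  bookkeeping convention, not an ontological claim.
* One published property label appears twice in the source registry; the
  second occurrence is shipped as the distinct `has tumor stage group` so
  identifiers stay unique while the 23-property count is preserved.
* Geographic codes are synthetic; do not join them against real FIPS
  resources.
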