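# pgxscribe

An offline pharmacogenomic (PGx) interpretation engine for people who already
*have* genotype calls — clinical laboratory staff, healthcare providers, and
PGx researchers — and need them translated into evidence-based prescribing
guidance. Given per-gene star-allele diplotypes (e.g. `CYP2D6 *1/*2`), HLA
risk-allele presence calls (e.g. `HLA-B *57:01 positive`) and named-variant
genotypes (VKORC1 −1639G>A), plus the patient's current and considered
medication lists, pgxscribe:

1. **translates** each diplotype to an inferred phenotype by exact lookup in
   gene-specific diplotype→phenotype tables (unmapped diplotypes report
   *indeterminate*; untyped genes report *unknown*);
2. **adjusts for phenoconversion**: concomitant drugs are classified per
   CYP450 gene (CYP2B6, CYP2C9, CYP2C19, CYP2D6, CYP3A5) as substrates,
   weak/moderate/strong inhibitors, or inducers. A strong inhibitor converts
   any inferred phenotype to poor metabolizer; a moderate inhibitor moves it
   one step down the gene's activity scale; an inducer moves it one step up;
   inhibitor+inducer conflicts, weak inhibitors alone, and phenotypes already
   at the floor/ceiling leave it unchanged. Inhibitor strength follows the
   fold increase in a substrate's plasma AUC (weak 1.25–2×, moderate >2×,
   strong >5×) or percent decrease in clearance (weak 20–49%, moderate
   50–80%, strong >80%);
3. **resolves recommendations** for all 97 supported gene-drug pairs (11
   genes) through the source-preference hierarchy **CPIC > DPWG > FDA**,
   using the phenoconverted phenotype whenever one applied; and
4. **renders a clinical report** (JSON, Markdown, or HTML) with the genetic
   results, the per-gene interaction listing, the full filterable
   future-medication table, a separate medications-being-considered table,
   and the knowledge-base version/update date stamped in the header.

The tool does **not** call star alleles from raw sequencing or array data,
and the bundled knowledge base carries `placeholder`-flagged synthetic
recommendation prose (the licensed guideline text corpus is not
redistributed): registry membership, diplotype maps, and the interaction
catalog are real curated content; the recommendation *wording* is not
clinical guidance.

## Worked example

```python
import json
import pgxscribe as px

kb = px.fixture_kb()                       # bundled KB: 97 pairs, 11 genes
patient = px.parse_patient_input(json.dumps({
    "genotypes": [
        {"gene": "CYP2D6", "value": "*2/*1"},
        {"gene": "CYP2C19", "value": "*1/*2"},
    ],
    "current": ["paroxetine"],             # strong CYP2D6 inhibitor
    "considered": ["codeine"],
}))
model = px.generate_report(kb, patient, generated_on="2021-03-01")
for row in model.genetic_results:
    if row.gene in ("CYP2D6", "CYP2C19"):
        print(row.gene, row.diplotype, "->", row.inferred_phenotype,
              "| converted:", row.converted_phenotype or "-", f"({row.conversion_basis})")
codeine = next(r for r in model.considered_medications if r.drug == "codeine")
print("codeine resolved against:", dict(codeine.phenotypes), "source:", codeine.source)
```

prints

```
CYP2C19 *1/*2 -> intermediate metabolizer | converted: - (no_trigger)
CYP2D6 *1/*2 -> normal metabolizer | converted: poor metabolizer (strong_inhibitor)
codeine resolved against: {'CYP2D6': 'poor metabolizer'} source: CPIC
```

i.e. the `*2/*1` entry is normalized to the canonical `*1/*2`, inferred as a
normal metabolizer, phenoconverted to a poor metabolizer because paroxetine
is on board, and the codeine recommendation is resolved against the
*converted* phenotype from the highest-preference source (CPIC).

The same pipeline from a shell:

```sh
pgxscribe report --patient patient.json --format markdown --out report.md
pgxscribe kb stats            # -> pairs=97 genes=11 drugs=86 phenoconversion_genes=5
pgxscribe kb init-fixture --out my_kb/   # editable TSV bundle
pgxscribe kb validate --kb my_kb/
```

## Layout

- `src/pgxscribe/kb.py` — knowledge-base schema, TSV bundle loader/writer,
  validator, inhibitor-strength classifier, statistics
- `src/pgxscribe/fixture.py` — the bundled knowledge base
- `src/pgxscribe/genotype.py` — patient input parsing; diplotype and
  drug-name normalization
- `src/pgxscribe/phenotype.py` — diplotype→phenotype translation, activity
  ranks, sentinel semantics
- `src/pgxscribe/phenoconversion.py` — interaction profiles and phenotype
  adjustment rules
- `src/pgxscribe/recommend.py` — hierarchy resolution, filters,
  considered-medication extraction
- `src/pgxscribe/report.py`, `src/pgxscribe/pipeline.py`,
  `src/pgxscribe/cli.py` — report model/rendering, end-to-end glue, CLI
- `docs/methods.md` — models, rules, parameters and design decisions
- `docs/input_formats.md` — patient file schemas and the KB bundle layout
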