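# Input and bundle formats

## Patient record — JSON (primary)

```json
{
  "genotypes": [
    {"gene": "CYP2D6", "value": "*2/*1", "note": "array panel v2"},
    {"gene": "HLA-B", "value": "57:01 pos"},
    {"gene": "VKORC1", "value": "G/A"}
  ],
  "current_medications": ["paroxetine", "omeprazole"],
  "considered_medications": ["codeine"],
  "metadata": {"specimen": "S-001"}
}
```

Rules:

- `genotypes`: at most one entry per gene; `gene` must be a KB gene symbol;
  `value` is non-empty; `note` is optional free text that appears next to the
  gene row in the report's genetic-results section.
- `current_medications` / `considered_medications` (short aliases `current` /
  `considered` accepted, not both spellings at once): optional lists of drug
  names; both sections may be empty or absent.
- Unknown top-level keys and unknown genotype keys are schema errors.
- Nothing parsed from a patient file is ever written anywhere; the only file
  the CLI produces is the one named by `--out`.

## Patient record — TSV dialect

Three to four `[section]` blocks, tab-separated rows, `#` comments ignored:

```
[genotypes]
CYP2D6	*2/*1	array panel v2
HLA-B	57:01 pos
[current_medications]
paroxetine
[considered_medications]
codeine
[metadata]
specimen	S-001
```

The CLI sniffs format from content (JSON starts with `{`) with extension
fallback; `--input-format json|tsv` overrides.

## Genotype value dialects

| input mode | accepted forms | canonical key |
| --- | --- | --- |
| star diplotype | two `/`-separated alleles, each `*<number>` with optional suffix letter (`*3A`) and optional copy number (`x2`, `xN`); any order | numerically sorted, e.g. `*1/*2`, `*1/*1x2` |
| HLA presence | allele with optional `HLA-B`/`B` prefix and optional `*`; status `pos`, `positive`, `+`, `present`, `detected`, `carrier` / `neg`, `negative`, `-`, `absent`, `not detected`, `non-carrier` | `*57:01 positive` / `*57:01 negative` |
| variant genotype | two `/`-separated nucleotides, any case/order | sorted pair, e.g. `A/G` |

Drug names are case-insensitive and whitespace-folded; a small synonym table
maps standard spellings onto the registry's curated ones (e.g. `carvedilol` →
`cavedilol`, `ondansetron` → `odansetron`, `rifampicin` → `rifampin`).
Unrecognized drugs are kept and reported as unrecognized.

## Knowledge-base bundle layout

A directory of UTF-8, tab-delimited files with header rows, plus a manifest:

| file | columns |
| --- | --- |
| `manifest.json` | `version`, `last_updated` (ISO-8601 date, shown in every report header) |
| `genes.tsv` | `symbol`, `input_mode`, `phenotype_scale` (pipe-joined, low→high activity), `categorical_terms` (pipe-joined), `phenoconversion_eligible` |
| `pairs.tsv` | `gene`, `drug`, `qualifier` (HLA risk allele, empty otherwise) |
| `diplotypes.tsv` | `gene`, `diplotype` (canonical key), `phenotype` |
| `interactions.tsv` | `gene`, `drug`, `role`, `strength`, `evidence_auc_fold`, `evidence_clearance_pct` |
| `recommendations.tsv` | `drug`, `drug_class`, `phenotype_key` (`GENE=term` pipe-joined), `text`, `strength`, `source`, `pathway_url`, `actionable`, `placeholder` |

`pgxscribe kb init-fixture --out DIR` writes the bundled KB in this layout;
`pgxscribe kb validate --kb DIR` loads and validates any bundle, reporting
each violation as *record: field: rule*.
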