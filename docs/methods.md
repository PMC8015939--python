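# Methods

## The interpretation model

pgxscribe is a deterministic rules engine, not a statistical model. Its chain
has four stages, each a pure function of the patient record and a versioned
knowledge base (KB):

**Genotype → phenotype.** Phenotypes are assigned by exact lookup in
gene-specific diplotype→phenotype tables. There is no interpolation and no
activity-score arithmetic: a CYP2D6 diplotype either has a table row or it
does not. Two sentinel outcomes are kept distinct from phenotype terms and
are represented as enum values rather than strings: *indeterminate* (a
diplotype was supplied but is not in the table — e.g. a copy-number allele
the curators have not mapped) and *unknown* (no genotype supplied for the
gene). Sentinels can never be ranked, phenoconverted, or matched by a
recommendation record, which removes a whole class of silent-coercion bugs.

**Phenoconversion.** For the five eligible CYP450 genes (CYP2B6, CYP2C9,
CYP2C19, CYP2D6, CYP3A5) each current medication is classified per gene as
substrate, weak/moderate/strong inhibitor, or inducer from the KB's
interaction catalog. The adjustment policy is deliberately blunt, reflecting
the limited evidence base for anything finer:

| trigger present | effect on inferred phenotype |
| --- | --- |
| strong inhibitor | → poor metabolizer, regardless of starting point |
| moderate inhibitor | → one step down the gene's activity scale |
| inducer | → one step up the gene's activity scale |
| (moderate or strong inhibitor) **and** inducer | no change (conflicting evidence) |
| weak inhibitor only, or substrates only | no change (but still displayed) |

Poor metabolizers are never pushed below the scale and the top phenotype is
never pushed above it; these outcomes are reported with explicit
`floor_no_change` / `ceiling_no_change` bases so the report can say *why*
nothing moved. Recommendations downstream always use the converted phenotype
when one applied.

**Inhibitor strength** is derived from pharmacokinetic evidence: fold
increase of a probe substrate's plasma AUC — weak [1.25, 2], moderate (2, 5],
strong (5, ∞) — or percent decrease in its clearance — weak [20, 50),
moderate [50, 80], strong (80, 100]. When both measurements exist the
stronger category governs; values below both floors are an error rather than
a silent "weak". The printed source bands are ambiguous exactly at 2-fold,
5-fold, the 49→50% boundary and 80%: this implementation closes the weak AUC
band at 2 (so "moderate: >2-fold" is strict), keeps 5.0 moderate (strong is
strictly >5), closes the 49–50 gap by defining weak as [20, 50), and keeps
80% moderate (strong strictly >80). KB curators who disagree can store an
explicit strength without evidence fields; when evidence fields *are*
present, validation requires the stored strength to equal the classifier's
output.

**Recommendation resolution.** For every drug in the supported gene-drug
pair registry, candidate records whose phenotype context matches the
patient's effective phenotypes are gathered. Selection order: records keyed
on more genes win (a composite warfarin CYP2C9+VKORC1 record beats either
single-gene fallback when both genes are callable), then the source
hierarchy CPIC > DPWG > FDA, then a deterministic tie-break on the sorted
gene set (relevant when, say, a tricyclic antidepressant is matched by a
CYP2D6 record and a CYP2C19 record of the same source). Two candidates with
the *same* gene set and the same source are a KB defect and raise. Drugs
whose genes are unknown/indeterminate, or whose phenotype combination has no
record, still appear in the output with strength `none` and an explanation —
the resolved list always covers the registry drug set exactly, so a report
can never silently drop a supported drug.

## The bundled knowledge base

The fixture KB is built programmatically (`fixture.py`) and serializes to a
human-diffable TSV bundle (`pgxscribe kb init-fixture`); `save → load` is
round-trip tested. Its registry is the full supported-pair table: 97 pairs
over 11 genes (CYP2B6 1, CYP2C19 17, CYP2C9 11, CYP2D6 49, CYP3A5 1, HLA-A 1,
HLA-B 5, NUDT15 3, SLCO1B1 4, TPMT 3, VKORC1 2; 86 distinct drug names, of
which 11 appear under two genes). Registry spellings are kept verbatim from
the curated source ("cavedilol", "odansetron"); the drug-name normalizer maps
the standard spellings onto them so user input in either form resolves.

Activity scales are the consensus standardized metabolizer terms; the source
material does not enumerate them per gene, so this package fixes them as:
CYP2B6 and CYP2C19 poor → intermediate → normal → rapid → ultrarapid; CYP2C9
and CYP3A5 poor → intermediate → normal; CYP2D6 poor → intermediate →
normal → ultrarapid (current CYP2D6 nomenclature has no "rapid" tier, so an
inducer steps a CYP2D6 normal metabolizer directly to ultrarapid — "one step"
means one step *among the terms the gene defines*). Non-CYP genes are
categorical and unranked: HLA presence per risk allele (`*57:01 positive`…),
TPMT/NUDT15 metabolizer categories, SLCO1B1 transporter function, VKORC1
warfarin-sensitivity categories keyed on the −1639G>A genotype.

The interaction catalog is Flockhart-style: per-gene substrate/inhibitor/
inducer roles, with inhibitor strengths backed by AUC-fold or clearance
evidence wherever recorded (validated against the classifier exhaustively).
Inducers carry no strength category — the upstream catalog does not grade
them. Catalog drugs need not be registry drugs (rifampin, ketoconazole…),
since current medications are free entry.

Recommendation records exist for every registry pair × every phenotype term
that pair can take (plus composite records for warfarin on CYP2C9+VKORC1 and
the three thiopurines on TPMT+NUDT15, and duplicate DPWG/FDA codeine records
that exercise hierarchy resolution). All prose is synthetic placeholder text
flagged `placeholder: true`; reports append a `[placeholder]` label and the
default disclaimer says what that flag means. `actionable` is a curated
boolean; the fixture marks any non-baseline phenotype (anything other than
normal metabolizer / normal function / normal sensitivity / risk-allele
negative) as actionable.

## What the fixture emulates, and what it does not

The bundle reproduces the *structure* of a production KB — registry,
scales, maps, catalog, per-phenotype records with sources and strengths —
at realistic shape and size, so every pipeline path (composite vs fallback
records, hierarchy conflicts, gap entries, phenoconversion triggers of every
strength) is exercised by shipped data. It does **not** carry real guideline
text, real per-drug strength assignments, exhaustive diplotype tables
(copy-number and rare alleles mostly resolve to *indeterminate*), or the
full Flockhart catalog breadth. Passing tests therefore demonstrate engine
correctness over a faithful KB schema, not the clinical accuracy of any
specific recommendation sentence.

## Numerical and degenerate-input choices

- Diplotype keys are canonicalized before lookup: star alleles sorted
  numerically then by suffix letter then copy number (`*2/*1` → `*1/*2`,
  `*1x2/*1` → `*1/*1x2`); HLA entry dialects collapse to
  `*<allele> positive|negative`; variant genotypes to a sorted nucleotide
  pair. Normalization is idempotent and allele-order symmetric
  (property-tested).
- Copy-number star alleles are accepted syntactically and mapped only if the
  table has a row; otherwise the call is *indeterminate* downstream.
- Multiple inhibitors: the strongest category present governs; weak
  inhibitor + inducer is treated as induction (weak inhibitors never trigger
  adjustment, so they cannot create a conflict).
- A moderate inhibitor acting on an intermediate metabolizer of a 3-term
  gene lands on poor metabolizer with basis `moderate_inhibitor`;
  `floor_no_change` is reserved for calls already *at* the floor.
- Unknown drugs in the medication lists are carried through and surfaced as
  unrecognized, never dropped or rejected.
- Reports are fully deterministic: rows sorted by gene or drug, JSON
  rendered with sorted keys, and the generation date injectable so repeated
  runs are byte-identical (golden-tested).

## Problem sizes

The test suite and the acceptance script run the complete truth-table
enumeration (5 genes × scale+sentinel terms × 16 trigger combinations = 480
cells), 1,000 randomized hierarchy candidate sets, and full-registry
end-to-end reports (86 drug rows spanning 97 pairs); all are exact,
CPU-trivial computations chosen to cover the rule space exhaustively rather
than sample it.

## Known limitations

- No star-allele calling, phasing, or VCF input; genotype quality is the
  caller's responsibility.
- Inducers are ungraded and inhibition is not substrate-specific; TPMT and
  SLCO1B1 inhibitors are out of scope.
- One genotype entry per gene: a patient's HLA-B status is a single
  risk-allele call, so drugs keyed on a different HLA-B allele resolve to an
  explained gap rather than a recommendation.
- DPYD, G6PD, UGT1A1 and CACNA1S/RYR1 content is not included.
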