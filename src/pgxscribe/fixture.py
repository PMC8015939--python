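"""Shipped fixture knowledge base.

Builds, deterministically and in memory, the demonstration bundle the package
ships with: the full registry of 97 supported gene-drug pairs across 11 genes,
activity scales for the five phenoconversion-eligible CYP450 genes, small but
realistic diplotype-to-phenotype lookup tables, a Flockhart-style CYP450
interaction catalog, and one or more recommendation records per registry pair.

Recommendation prose here is synthetic placeholder text (flagged
``placeholder=True`` and labelled as such in rendered reports): the licensed
guideline corpus is not distributed with the package. Everything else —
registry membership, interaction roles and strengths, diplotype maps — is
curated content the engine operates on directly.
"""

from __future__ import annotations

from .kb import (
    GeneDefinition,
    InputMode,
    InteractionRecord,
    KnowledgeBase,
    RecommendationRecord,
    RecStrength,
    Role,
    Source,
    Strength,
    make_phenotype_key,
)

FIXTURE_VERSION = "fixture-1.0"
FIXTURE_LAST_UPDATED = "2021-02-01"

_SCALE_5 = ("poor metabolizer", "intermediate metabolizer", "normal metabolizer", "rapid metabolizer", "ultrarapid metabolizer")
_SCALE_3 = ("poor metabolizer", "intermediate metabolizer", "normal metabolizer")
# CYP2D6 nomenclature has no "rapid" tier: normal steps directly to ultrarapid.
_SCALE_2D6 = ("poor metabolizer", "intermediate metabolizer", "normal metabolizer", "ultrarapid metabolizer")

_GENES = (
    GeneDefinition("CYP2B6", InputMode.STAR_DIPLOTYPE, _SCALE_5, (), True),
    GeneDefinition("CYP2C19", InputMode.STAR_DIPLOTYPE, _SCALE_5, (), True),
    GeneDefinition("CYP2C9", InputMode.STAR_DIPLOTYPE, _SCALE_3, (), True),
    GeneDefinition("CYP2D6", InputMode.STAR_DIPLOTYPE, _SCALE_2D6, (), True),
    GeneDefinition("CYP3A5", InputMode.STAR_DIPLOTYPE, _SCALE_3, (), True),
    GeneDefinition(
        "HLA-A", InputMode.HLA_PRESENCE, (), ("*31:01 positive", "*31:01 negative"), False
    ),
    GeneDefinition(
        "HLA-B",
        InputMode.HLA_PRESENCE,
        (),
        (
            "*15:02 positive",
            "*15:02 negative",
            "*57:01 positive",
            "*57:01 negative",
            "*58:01 positive",
            "*58:01 negative",
        ),
        False,
    ),
    GeneDefinition("NUDT15", InputMode.STAR_DIPLOTYPE, (), _SCALE_3, False),
    GeneDefinition(
        "SLCO1B1",
        InputMode.STAR_DIPLOTYPE,
        (),
        ("poor function", "decreased function", "normal function"),
        False,
    ),
    GeneDefinition("TPMT", InputMode.STAR_DIPLOTYPE, (), _SCALE_3, False),
    GeneDefinition(
        "VKORC1",
        InputMode.VARIANT_GENOTYPE,
        (),
        (
            "normal warfarin sensitivity",
            "increased warfarin sensitivity",
            "highly increased warfarin sensitivity",
        ),
        False,
    ),
)

# Supported gene-drug pair registry (97 pairs, 11 genes). HLA entries carry the
# risk-allele qualifier whose carriage status drives the recommendation.
_REGISTRY: dict[str, tuple[str, ...]] = {
    "CYP2B6": ("efavirenz",),
    "CYP2C19": (
        "amitriptyline", "citalopram", "clobazam", "clomipramine", "clopidogrel",
        "doxepin", "escitalopram", "esomeprazole", "imipramine", "lansoprazole",
        "omeprazole", "pantoprazole", "prasugrel", "sertraline", "ticagrelor",
        "trimipramine", "voriconazole",
    ),
    "CYP2C9": (
        "aspirin", "celecoxib", "flurbiprofen", "ibuprofen", "lornoxicam",
        "meloxicam", "naproxen", "phenytoin", "piroxicam", "tenoxicam", "warfarin",
    ),
    "CYP2D6": (
        "amiodarone", "amitriptyline", "amphetamine", "aripiprazole", "atenolol",
        "atomoxetine", "bisoprolol", "brexpiprazole", "cavedilol", "clomipramine",
        "clonidine", "clozapine", "codeine", "desipramine", "doxepin", "duloxetine",
        "eliglustat", "flecainide", "fluoxetine", "fluphenazine", "fluvoxamine",
        "haloperidol", "hydrocodone", "iloperidone", "imipramine", "methylphenidate",
        "metoprolol", "mirtazapine", "moclobemide", "nebivolol", "nortriptyline",
        "odansetron", "olanzapine", "oxycodone", "paroxetine", "perphenazine",
        "pimozide", "propafenone", "propranolol", "quetiapine", "risperidone",
        "tamoxifen", "tetrabenazine", "tramadol", "tropisetron", "trimipramine",
        "venlafaxine", "vortioxetine", "zuclopenthixol",
    ),
    "CYP3A5": ("tacrolimus",),
    "HLA-A": ("carbamazepine",),
    "HLA-B": ("abacavir", "allopurinol", "carbamazepine", "oxcarbazepine", "phenytoin"),
    "NUDT15": ("azathioprine", "mercaptopurine", "thioguanine"),
    "SLCO1B1": ("atorvastatin", "fluvastatin", "rosuvastatin", "simvastatin"),
    "TPMT": ("azathioprine", "mercaptopurine", "thioguanine"),
    "VKORC1": ("acenocoumarol", "warfarin"),
}

_HLA_QUALIFIERS = {
    ("HLA-A", "carbamazepine"): "*31:01",
    ("HLA-B", "abacavir"): "*57:01",
    ("HLA-B", "allopurinol"): "*58:01",
    ("HLA-B", "carbamazepine"): "*15:02",
    ("HLA-B", "oxcarbazepine"): "*15:02",
    ("HLA-B", "phenytoin"): "*15:02",
}

_DIPLOTYPE_MAPS: dict[str, dict[str, str]] = {
    "CYP2B6": {
        "*1/*1": "normal metabolizer",
        "*1/*4": "rapid metabolizer",
        "*1/*6": "intermediate metabolizer",
        "*4/*4": "ultrarapid metabolizer",
        "*6/*6": "poor metabolizer",
    },
    "CYP2C19": {
        "*1/*1": "normal metabolizer",
        "*1/*2": "intermediate metabolizer",
        "*1/*17": "rapid metabolizer",
        "*2/*2": "poor metabolizer",
        "*2/*17": "intermediate metabolizer",
        "*17/*17": "ultrarapid metabolizer",
    },
    "CYP2C9": {
        "*1/*1": "normal metabolizer",
        "*1/*2": "intermediate metabolizer",
        "*1/*3": "intermediate metabolizer",
        "*2/*2": "intermediate metabolizer",
        "*2/*3": "poor metabolizer",
        "*3/*3": "poor metabolizer",
    },
    "CYP2D6": {
        "*1/*1": "normal metabolizer",
        "*1/*2": "normal metabolizer",
        "*2/*2": "normal metabolizer",
        "*1/*4": "intermediate metabolizer",
        "*4/*4": "poor metabolizer",
        "*1/*1x2": "ultrarapid metabolizer",
    },
    "CYP3A5": {
        "*1/*1": "normal metabolizer",
        "*1/*3": "intermediate metabolizer",
        "*3/*3": "poor metabolizer",
    },
    "HLA-A": {
        "*31:01 positive": "*31:01 positive",
        "*31:01 negative": "*31:01 negative",
    },
    "HLA-B": {
        "*15:02 positive": "*15:02 positive",
        "*15:02 negative": "*15:02 negative",
        "*57:01 positive": "*57:01 positive",
        "*57:01 negative": "*57:01 negative",
        "*58:01 positive": "*58:01 positive",
        "*58:01 negative": "*58:01 negative",
    },
    "NUDT15": {
        "*1/*1": "normal metabolizer",
        "*1/*3": "intermediate metabolizer",
        "*3/*3": "poor metabolizer",
    },
    "SLCO1B1": {
        "*1/*1": "normal function",
        "*1/*5": "decreased function",
        "*5/*5": "poor function",
    },
    "TPMT": {
        "*1/*1": "normal metabolizer",
        "*1/*3A": "intermediate metabolizer",
        "*3A/*3A": "poor metabolizer",
    },
    "VKORC1": {
        "G/G": "normal warfarin sensitivity",
        "A/G": "increased warfarin sensitivity",
        "A/A": "highly increased warfarin sensitivity",
    },
}

# Flockhart-style CYP450 interaction catalog. Inhibitor rows record the probe
# evidence (AUC fold increase or % clearance decrease) that determines their
# weak/moderate/strong category; inducers are uncategorized by design.
_SUBSTRATES: dict[str, tuple[str, ...]] = {
    "CYP2B6": ("efavirenz", "bupropion", "methadone"),
    "CYP2C19": ("citalopram", "escitalopram", "sertraline", "clopidogrel", "omeprazole", "voriconazole", "amitriptyline"),
    "CYP2C9": ("warfarin", "phenytoin", "celecoxib", "ibuprofen"),
    "CYP2D6": ("codeine", "tramadol", "metoprolol", "amitriptyline", "nortriptyline", "risperidone", "atomoxetine", "oxycodone", "tamoxifen", "venlafaxine"),
    "CYP3A5": ("tacrolimus",),
}
# (gene, drug, auc_fold, clearance_pct, strength)
_INHIBITORS: tuple[tuple[str, str, float | None, float | None, Strength], ...] = (
    ("CYP2B6", "ticlopidine", 5.2, None, Strength.STRONG),
    ("CYP2B6", "clopidogrel", None, 52.0, Strength.MODERATE),
    ("CYP2C19", "fluvoxamine", 6.0, None, Strength.STRONG),
    ("CYP2C19", "fluconazole", 2.1, None, Strength.MODERATE),
    ("CYP2C19", "omeprazole", 2.2, None, Strength.MODERATE),
    ("CYP2C19", "cimetidine", 1.4, None, Strength.WEAK),
    ("CYP2C9", "amiodarone", None, 55.0, Strength.MODERATE),
    ("CYP2C9", "fluconazole", 2.8, None, Strength.MODERATE),
    ("CYP2C9", "sulfamethoxazole", 1.4, None, Strength.WEAK),
    ("CYP2D6", "paroxetine", 6.4, None, Strength.STRONG),
    ("CYP2D6", "fluoxetine", 6.0, None, Strength.STRONG),
    ("CYP2D6", "quinidine", None, 85.0, Strength.STRONG),
    ("CYP2D6", "duloxetine", 2.6, None, Strength.MODERATE),
    ("CYP2D6", "cimetidine", 1.5, None, Strength.WEAK),
    ("CYP2D6", "sertraline", 1.6, None, Strength.WEAK),
    ("CYP3A5", "ketoconazole", 15.0, None, Strength.STRONG),
    ("CYP3A5", "clarithromycin", 7.0, None, Strength.STRONG),
    ("CYP3A5", "erythromycin", 4.0, None, Strength.MODERATE),
    ("CYP3A5", "diltiazem", None, 60.0, Strength.MODERATE),
    ("CYP3A5", "fluvoxamine", 1.5, None, Strength.WEAK),
)
_INDUCERS: dict[str, tuple[str, ...]] = {
    "CYP2B6": ("rifampin", "carbamazepine", "efavirenz"),
    "CYP2C19": ("rifampin",),
    "CYP2C9": ("rifampin", "carbamazepine"),
    "CYP2D6": (),
    "CYP3A5": ("rifampin", "carbamazepine", "phenytoin", "st john's wort"),
}

_DRUG_CLASSES: dict[str, str] = {
    **dict.fromkeys(("citalopram", "escitalopram", "sertraline", "paroxetine", "fluoxetine", "fluvoxamine", "vortioxetine"), "SSRI"),
    **dict.fromkeys(("amitriptyline", "clomipramine", "desipramine", "doxepin", "imipramine", "nortriptyline", "trimipramine"), "TCA"),
    **dict.fromkeys(("venlafaxine", "duloxetine"), "SNRI"),
    **dict.fromkeys(
        ("aripiprazole", "brexpiprazole", "clozapine", "fluphenazine", "haloperidol", "iloperidone",
         "olanzapine", "perphenazine", "pimozide", "quetiapine", "risperidone", "zuclopenthixol"),
        "antipsychotic",
    ),
    **dict.fromkeys(("codeine", "tramadol", "hydrocodone", "oxycodone"), "opioid"),
    **dict.fromkeys(("atenolol", "bisoprolol", "cavedilol", "metoprolol", "nebivolol", "propranolol"), "beta-blocker"),
    **dict.fromkeys(("atorvastatin", "fluvastatin", "rosuvastatin", "simvastatin"), "statin"),
    **dict.fromkeys(("esomeprazole", "lansoprazole", "omeprazole", "pantoprazole"), "PPI"),
    **dict.fromkeys(("clopidogrel", "prasugrel", "ticagrelor", "aspirin"), "antiplatelet"),
    **dict.fromkeys(("warfarin", "acenocoumarol"), "anticoagulant"),
    **dict.fromkeys(("carbamazepine", "oxcarbazepine", "phenytoin", "clobazam"), "antiepileptic"),
    **dict.fromkeys(
        ("celecoxib", "flurbiprofen", "ibuprofen", "lornoxicam", "meloxicam", "naproxen", "piroxicam", "tenoxicam"),
        "NSAID",
    ),
    **dict.fromkeys(("azathioprine", "mercaptopurine", "thioguanine"), "thiopurine"),
    **dict.fromkeys(("abacavir", "efavirenz"), "antiretroviral"),
    **dict.fromkeys(("amphetamine", "methylphenidate"), "stimulant"),
    "tacrolimus": "immunosuppressant",
    "voriconazole": "antifungal",
    "allopurinol": "antigout",
}

#: Terms that describe the reference (no-deviation) result for a gene.
_BASELINE_TERMS = frozenset(
    {
        "normal metabolizer",
        "normal function",
        "normal warfarin sensitivity",
        "*31:01 negative",
        "*15:02 negative",
        "*57:01 negative",
        "*58:01 negative",
    }
)


def drug_class(drug: str) -> str:
    return _DRUG_CLASSES.get(drug, "other")


def _terms_for_pair(gene_def: GeneDefinition, gene: str, drug: str) -> tuple[str, ...]:
    if gene_def.input_mode is InputMode.HLA_PRESENCE:
        allele = _HLA_QUALIFIERS[(gene, drug)]
        return (f"{allele} positive", f"{allele} negative")
    return gene_def.valid_terms


def _placeholder(drug: str, key: dict[str, str], source: Source) -> str:
    ctx = "; ".join(f"{g} {t}" for g, t in sorted(key.items()))
    return (
        f"Placeholder fixture guidance ({source.value}): {drug} with {ctx}. "
        "Synthetic demonstration text — consult the cited source guideline for clinical wording."
    )


def _record(drug: str, key: dict[str, str], source: Source) -> RecommendationRecord:
    actionable = any(t not in _BASELINE_TERMS for t in key.values())
    return RecommendationRecord(
        drug=drug,
        drug_class=drug_class(drug),
        phenotype_key=make_phenotype_key(key),
        text=_placeholder(drug, key, source),
        strength=RecStrength.STRONG if actionable else RecStrength.OPTIONAL,
        source=source,
        pathway_url=f"https://example.org/pathway/{drug.replace(' ', '-')}",
        actionable=actionable,
        placeholder=True,
    )


def _build_recommendations(genes: dict[str, GeneDefinition]) -> tuple[RecommendationRecord, ...]:
    records: list[RecommendationRecord] = []
    for gene, drugs in _REGISTRY.items():
        gd = genes[gene]
        for drug in drugs:
            for term in _terms_for_pair(gd, gene, drug):
                records.append(_record(drug, {gene: term}, Source.CPIC))
    # Extra lower-preference sources for codeine so hierarchy resolution is
    # exercised by the fixture itself (CPIC must win over these).
    for term in _SCALE_2D6:
        records.append(_record("codeine", {"CYP2D6": term}, Source.DPWG))
        records.append(_record("codeine", {"CYP2D6": term}, Source.FDA))
    # Composite multi-gene records: preferred over single-gene fallbacks when
    # every constituent gene has a callable phenotype.
    for c9 in _SCALE_3:
        for vk in genes["VKORC1"].categorical_terms:
            records.append(_record("warfarin", {"CYP2C9": c9, "VKORC1": vk}, Source.CPIC))
    for tp in _SCALE_3:
        for nu in _SCALE_3:
            for thiopurine in ("azathioprine", "mercaptopurine", "thioguanine"):
                records.append(_record(thiopurine, {"TPMT": tp, "NUDT15": nu}, Source.CPIC))
    return tuple(records)


def fixture_kb() -> KnowledgeBase:
    """Construct the shipped fixture knowledge base (validated by tests)."""
    genes = {gd.symbol: gd for gd in _GENES}
    interactions: list[InteractionRecord] = []
    for gene, drugs in _SUBSTRATES.items():
        interactions.extend(InteractionRecord(gene, d, Role.SUBSTRATE) for d in drugs)
    for gene, drug, auc, clr, strength in _INHIBITORS:
        interactions.append(
            InteractionRecord(
                gene, drug, Role.INHIBITOR, strength,
                evidence_auc_fold=auc, evidence_clearance_pct=clr,
            )
        )
    for gene, drugs in _INDUCERS.items():
        interactions.extend(InteractionRecord(gene, d, Role.INDUCER) for d in drugs)

    return KnowledgeBase(
        version=FIXTURE_VERSION,
        last_updated=FIXTURE_LAST_UPDATED,
        genes=genes,
        pair_registry=frozenset(
            (gene, drug) for gene, drugs in _REGISTRY.items() for drug in drugs
        ),
        hla_qualifiers=dict(_HLA_QUALIFIERS),
        diplotype_maps={
            (gene, key): term
            for gene, table in _DIPLOTYPE_MAPS.items()
            for key, term in table.items()
        },
        interactions=tuple(interactions),
        recommendations=_build_recommendations(genes),
    )
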