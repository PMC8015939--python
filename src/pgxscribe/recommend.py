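"""Recommendation resolution, filtering, and considered-medication extraction.

For each drug in the supported gene-drug pair registry, candidate guideline
records whose phenotype context matches the patient's effective phenotypes
(phenoconverted when a conversion applied, else inferred) are gathered and a
single record is chosen for display. When several sources cover the same
context, the source-preference hierarchy CPIC > DPWG > FDA decides; records
keyed on more genes (composite records, e.g. warfarin on CYP2C9 + VKORC1
jointly) are preferred over single-gene fallbacks. Drugs whose genes are
unknown/indeterminate or whose phenotype context matches no record still get
an entry — with strength "none" and an explanation — so the output always
covers the whole registry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .kb import KnowledgeBase, RecommendationRecord, RecStrength, Source, SOURCE_RANK
from .phenoconversion import ConvertedPhenotypeCall
from .phenotype import Sentinel


class AmbiguityError(ValueError):
    """Two candidate records share the top-ranked source — a KB defect."""


class FilterError(ValueError):
    """A filter value matches nothing the recommendation list contains."""


@dataclass(frozen=True)
class ResolvedRecommendation:
    """The single recommendation displayed for one registry drug."""

    drug: str
    drug_class: str
    genes: tuple[str, ...]  # all registry genes for this drug, sorted
    phenotypes_used: tuple[tuple[str, str], ...]  # (gene, effective term/sentinel)
    text: str
    strength: RecStrength
    source: Optional[Source]  # absent for gap entries (strength none)
    pathway_url: str = ""
    actionable: bool = False
    placeholder: bool = False

    @property
    def phenotype_map(self) -> dict[str, str]:
        return dict(self.phenotypes_used)


@dataclass(frozen=True)
class FilterSpec:
    """Conjunctive report filters; an empty spec selects everything."""

    drugs: Optional[frozenset[str]] = None
    drug_classes: Optional[frozenset[str]] = None
    genes: Optional[frozenset[str]] = None
    recommendation_type: Optional[str] = None  # 'actionable' | 'non_actionable'


def resolve_hierarchy(candidates: Sequence[RecommendationRecord]) -> RecommendationRecord:
    """Pick the candidate from the highest-preference source (CPIC > DPWG > FDA).

    All candidates must address the same drug and phenotype context; two
    candidates sharing the top source indicate a knowledge-base defect.
    """
    if not candidates:
        raise ValueError("resolve_hierarchy requires at least one candidate")
    ranked = sorted(candidates, key=lambda r: SOURCE_RANK[r.source])
    if len(ranked) > 1 and ranked[0].source is ranked[1].source:
        raise AmbiguityError(
            f"two {ranked[0].source.value} records for {ranked[0].drug} "
            f"in context {dict(ranked[0].phenotype_key)}"
        )
    return ranked[0]


def _effective_phenotypes(
    calls: Sequence[ConvertedPhenotypeCall],
) -> tuple[dict[str, str], dict[str, str]]:
    """Split calls into matchable terms and sentinel labels, per gene."""
    effective: dict[str, str] = {}
    sentinels: dict[str, str] = {}
    seen: set[str] = set()
    for call in calls:
        if call.gene in seen:
            raise ValueError(f"more than one phenotype call for gene {call.gene}")
        seen.add(call.gene)
        term = call.effective
        if isinstance(term, Sentinel):
            sentinels[call.gene] = term.value
        else:
            effective[call.gene] = term
    return effective, sentinels


def collect_recommendations(
    kb: KnowledgeBase, calls: Sequence[ConvertedPhenotypeCall]
) -> list[ResolvedRecommendation]:
    """Resolve one displayed recommendation per registry drug.

    The output drug set always equals the registry drug set: drugs that cannot
    be matched (sentinel phenotypes, unmatched context) are represented with
    strength "none" and explanatory text rather than omitted.
    """
    effective, sentinels = _effective_phenotypes(calls)
    by_drug: dict[str, list[RecommendationRecord]] = {}
    for rec in kb.recommendations:
        by_drug.setdefault(rec.drug, []).append(rec)

    out: list[ResolvedRecommendation] = []
    for drug in kb.registry_drugs():
        drug_genes = kb.registry_genes_for_drug(drug)
        used = tuple(
            (g, effective.get(g) or sentinels.get(g, Sentinel.UNKNOWN.value)) for g in drug_genes
        )
        matching = [
            rec
            for rec in by_drug.get(drug, [])
            if all(effective.get(g) == term for g, term in rec.phenotype_key)
        ]
        if matching:
            # Prefer records keyed on more genes, then higher-preference source,
            # then a deterministic gene-set order for cross-gene ties.
            best = min(
                matching,
                key=lambda r: (-len(r.phenotype_key), SOURCE_RANK[r.source], r.phenotype_key),
            )
            out.append(
                ResolvedRecommendation(
                    drug=drug,
                    drug_class=best.drug_class,
                    genes=tuple(drug_genes),
                    phenotypes_used=used,
                    text=best.text,
                    strength=best.strength,
                    source=best.source,
                    pathway_url=best.pathway_url,
                    actionable=best.actionable,
                    placeholder=best.placeholder,
                )
            )
        else:
            missing = [g for g in drug_genes if g not in effective]
            if missing:
                labels = ", ".join(
                    f"{g} {sentinels.get(g, Sentinel.UNKNOWN.value)}" for g in missing
                )
                reason = f"No recommendation: phenotype {labels}."
            else:
                ctx = ", ".join(f"{g} {effective[g]}" for g in drug_genes)
                reason = f"No recommendation on record for {ctx}."
            known = by_drug.get(drug)
            out.append(
                ResolvedRecommendation(
                    drug=drug,
                    drug_class=known[0].drug_class if known else "other",
                    genes=tuple(drug_genes),
                    phenotypes_used=used,
                    text=reason,
                    strength=RecStrength.NONE,
                    source=None,
                )
            )
    return out


_REC_TYPES = {"actionable", "non_actionable"}


def filter_recommendations(
    recs: Sequence[ResolvedRecommendation], spec: FilterSpec
) -> list[ResolvedRecommendation]:
    """Conjunctive filtering by drug, drug class, gene and recommendation type.

    Unknown filter values raise :class:`FilterError` listing the valid values
    present in the input; input order is preserved.
    """
    def check(values: Optional[frozenset[str]], universe: set[str], what: str) -> None:
        if values is None:
            return
        unknown = set(values) - universe
        if unknown:
            raise FilterError(
                f"unknown {what} filter value(s) {sorted(unknown)}; valid: {sorted(universe)}"
            )

    check(spec.drugs, {r.drug for r in recs}, "drug")
    check(spec.drug_classes, {r.drug_class for r in recs}, "drug class")
    check(spec.genes, {g for r in recs for g in r.genes}, "gene")
    if spec.recommendation_type is not None and spec.recommendation_type not in _REC_TYPES:
        raise FilterError(
            f"unknown recommendation type {spec.recommendation_type!r}; valid: {sorted(_REC_TYPES)}"
        )

    out = []
    for rec in recs:
        if spec.drugs is not None and rec.drug not in spec.drugs:
            continue
        if spec.drug_classes is not None and rec.drug_class not in spec.drug_classes:
            continue
        if spec.genes is not None and not (set(rec.genes) & spec.genes):
            continue
        if spec.recommendation_type == "actionable" and not rec.actionable:
            continue
        if spec.recommendation_type == "non_actionable" and rec.actionable:
            continue
        out.append(rec)
    return out


@dataclass(frozen=True)
class ConsideredSplit:
    """Recommendations for considered medications, extracted (copied) from the
    full list; drugs outside the registry are reported as unsupported."""

    considered: tuple[ResolvedRecommendation, ...]
    unsupported: tuple[str, ...]


def split_considered(
    recs: Sequence[ResolvedRecommendation], considered: Sequence[str]
) -> ConsideredSplit:
    by_drug = {r.drug: r for r in recs}
    subset = []
    unsupported = []
    for drug in considered:
        if drug in by_drug:
            subset.append(by_drug[drug])
        else:
            unsupported.append(drug)
    return ConsideredSplit(tuple(subset), tuple(unsupported))
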