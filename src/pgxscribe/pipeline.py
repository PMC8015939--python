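"""End-to-end interpretation pipeline: patient record + knowledge base -> report.

Glue layer used by the CLI and by callers who want the whole chain in one
call: normalize genotypes and medication names, translate diplotypes, apply
phenoconversion, resolve recommendations, and assemble the report model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .genotype import (
    DiplotypeParseError,
    PatientRecord,
    normalize_diplotype,
    normalize_drug_name,
)
from .kb import KnowledgeBase
from .phenoconversion import ConvertedPhenotypeCall, InteractionProfile, convert_all
from .phenotype import PhenotypeCall, translate_diplotype
from .recommend import (
    ConsideredSplit,
    FilterSpec,
    ResolvedRecommendation,
    collect_recommendations,
    filter_recommendations,
    split_considered,
)
from .report import DEFAULT_DISCLAIMER, ReportModel, build_report


@dataclass
class InterpretationResult:
    calls: list[ConvertedPhenotypeCall]
    profiles: dict[str, InteractionProfile]
    resolutions: list[ResolvedRecommendation]
    considered: ConsideredSplit
    current_medications: list[str]
    unrecognized_current: list[str]


def interpret(kb: KnowledgeBase, patient: PatientRecord) -> InterpretationResult:
    """Run translation, phenoconversion and recommendation resolution.

    Every KB gene gets a phenotype call — genes without supplied genotype data
    are called ``unknown`` so they appear in the genetic-results section and
    their dependent drugs resolve to explanatory gap entries.
    """
    entered = {e.gene: e for e in patient.genotypes}
    unknown_genes = set(entered) - set(kb.genes)
    if unknown_genes:
        raise DiplotypeParseError(f"genotype entries for unknown gene(s): {sorted(unknown_genes)}")

    calls: list[PhenotypeCall] = []
    for symbol in sorted(kb.genes):
        entry = entered.get(symbol)
        if entry is None:
            calls.append(translate_diplotype(kb, symbol, None))
        else:
            key = normalize_diplotype(kb.gene(symbol), entry.raw_value)
            calls.append(translate_diplotype(kb, symbol, key, note=entry.note))

    current, unrecognized = [], []
    for raw in patient.current_medications:
        norm = normalize_drug_name(kb, raw)
        current.append(norm.name)
        if not norm.recognized:
            unrecognized.append(norm.name)

    converted, profiles = convert_all(kb, calls, current)
    resolutions = collect_recommendations(kb, converted)

    considered_names = [normalize_drug_name(kb, raw).name for raw in patient.considered_medications]
    considered = split_considered(resolutions, considered_names)

    return InterpretationResult(
        calls=converted,
        profiles=profiles,
        resolutions=resolutions,
        considered=considered,
        current_medications=current,
        unrecognized_current=unrecognized,
    )


def generate_report(
    kb: KnowledgeBase,
    patient: PatientRecord,
    *,
    filter_spec: Optional[FilterSpec] = None,
    generated_on: Optional[str] = None,
    disclaimer: str = DEFAULT_DISCLAIMER,
) -> ReportModel:
    """Full pipeline to a ReportModel; ``filter_spec`` narrows future medications."""
    result = interpret(kb, patient)
    resolutions: Sequence[ResolvedRecommendation] = result.resolutions
    model = build_report(
        patient,
        kb,
        result.calls,
        result.profiles,
        resolutions,
        result.considered,
        unrecognized_current=result.unrecognized_current,
        generated_on=generated_on,
        disclaimer=disclaimer,
    )
    if filter_spec is not None:
        from .report import _rec_row  # filtered view over the already-built table

        filtered = filter_recommendations(result.resolutions, filter_spec)
        model.future_medications = [_rec_row(r) for r in filtered]
    return model
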