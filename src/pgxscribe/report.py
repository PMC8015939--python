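"""Clinical report assembly and rendering (JSON, Markdown, HTML).

The report mirrors the layout of the web tool it replaces: a header carrying
the generation date, knowledge-base version and the date of the most recent
database update (top-right of every report); a genetic-results section (one
row per gene: genotype as entered, canonical diplotype, inferred phenotype,
phenoconverted phenotype with its basis, free-text note); a current-medication
interaction section listing all concomitant substrates, inhibitors (every
strength, including the weak ones that never trigger adjustment) and inducers
per CYP450 gene; the full future-medication recommendation table (one row per
supported drug); a separate medications-being-considered table; and a fixed —
but configurable — disclaimer. Rendering is pure: no patient data is persisted
anywhere by this module.
"""

from __future__ import annotations

import datetime
import html as _html
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

from .genotype import PatientRecord
from .kb import KnowledgeBase, RecStrength
from .phenoconversion import ConvertedPhenotypeCall, InteractionProfile
from .recommend import ConsideredSplit, ResolvedRecommendation

DEFAULT_DISCLAIMER = (
    "This report is intended for interpretation by a licensed physician or other "
    "licensed healthcare professional, who retains ultimate responsibility for all "
    "therapeutic decisions in light of the individual characteristics of the patient "
    "and the drugs prescribed. The generating software accepts no responsibility for "
    "modification or redistribution of this report and is not liable for actions taken "
    "on the basis of its contents, or for any inaccuracies, errors, or omissions. "
    "Recommendations flagged [placeholder] carry synthetic demonstration text, not "
    "clinical guidance."
)


class ReportAssemblyError(ValueError):
    """The inputs handed to build_report are mutually inconsistent."""


@dataclass
class GeneticResultRow:
    gene: str
    genotype_entered: str
    diplotype: str
    inferred_phenotype: str
    converted_phenotype: str  # empty unless a conversion applied
    conversion_basis: str
    interacting_drugs: tuple[str, ...]
    note: str


@dataclass
class InteractionRow:
    gene: str
    substrates: tuple[str, ...]
    weak_inhibitors: tuple[str, ...]
    moderate_inhibitors: tuple[str, ...]
    strong_inhibitors: tuple[str, ...]
    inducers: tuple[str, ...]


@dataclass
class RecommendationRow:
    drug: str
    drug_class: str
    genes: tuple[str, ...]
    phenotypes: tuple[tuple[str, str], ...]
    recommendation: str
    strength: str
    source: str
    pathway_url: str
    actionable: bool
    placeholder: bool


@dataclass
class ReportModel:
    generated_on: str
    kb_version: str
    kb_last_updated: str
    metadata: dict[str, str]
    genetic_results: list[GeneticResultRow]
    current_medications: list[str]
    current_medication_table: list[InteractionRow]
    unrecognized_current: list[str]
    future_medications: list[RecommendationRow]
    considered_medications: list[RecommendationRow]
    unsupported_considered: list[str]
    disclaimer: str


def _rec_row(rec: ResolvedRecommendation) -> RecommendationRow:
    return RecommendationRow(
        drug=rec.drug,
        drug_class=rec.drug_class,
        genes=rec.genes,
        phenotypes=rec.phenotypes_used,
        recommendation=rec.text,
        strength=rec.strength.value,
        source=rec.source.value if rec.source else "",
        pathway_url=rec.pathway_url,
        actionable=rec.actionable,
        placeholder=rec.placeholder,
    )


def build_report(
    patient: PatientRecord,
    kb: KnowledgeBase,
    calls: Sequence[ConvertedPhenotypeCall],
    profiles: dict[str, InteractionProfile],
    resolutions: Sequence[ResolvedRecommendation],
    considered: ConsideredSplit,
    *,
    unrecognized_current: Sequence[str] = (),
    generated_on: Optional[str] = None,
    disclaimer: str = DEFAULT_DISCLAIMER,
) -> ReportModel:
    """Assemble the report model deterministically from pipeline outputs.

    ``generated_on`` is injectable so identical inputs yield byte-identical
    renderings; it defaults to today's date.
    """
    registry_drugs = set(kb.registry_drugs())
    if {r.drug for r in resolutions} != registry_drugs:
        raise ReportAssemblyError("resolutions do not cover the KB registry drug set")
    call_genes = {c.gene for c in calls}
    if not call_genes <= set(kb.genes):
        raise ReportAssemblyError(f"calls reference genes unknown to this KB: {sorted(call_genes - set(kb.genes))}")

    entered = {e.gene: e for e in patient.genotypes}
    rows = []
    for call in sorted(calls, key=lambda c: c.gene):
        entry = entered.get(call.gene)
        rows.append(
            GeneticResultRow(
                gene=call.gene,
                genotype_entered=entry.raw_value if entry else "",
                diplotype=call.base.diplotype or "",
                inferred_phenotype=call.base.display_inferred,
                converted_phenotype=call.converted or "",
                conversion_basis=call.basis.value,
                interacting_drugs=call.triggering_drugs,
                note=call.base.note or "",
            )
        )

    interaction_rows = [
        InteractionRow(
            gene=gene,
            substrates=profiles[gene].substrates,
            weak_inhibitors=profiles[gene].weak_inhibitors,
            moderate_inhibitors=profiles[gene].moderate_inhibitors,
            strong_inhibitors=profiles[gene].strong_inhibitors,
            inducers=profiles[gene].inducers,
        )
        for gene in sorted(profiles)
    ]

    return ReportModel(
        generated_on=generated_on or datetime.date.today().isoformat(),
        kb_version=kb.version,
        kb_last_updated=kb.last_updated,
        metadata=dict(sorted(patient.metadata.items())),
        genetic_results=rows,
        current_medications=list(patient.current_medications),
        current_medication_table=interaction_rows,
        unrecognized_current=sorted(unrecognized_current),
        future_medications=[_rec_row(r) for r in resolutions],
        considered_medications=[_rec_row(r) for r in considered.considered],
        unsupported_considered=list(considered.unsupported),
        disclaimer=disclaimer,
    )


def render_report(model: ReportModel, fmt: str = "json") -> str:
    """Render a report model to 'json', 'markdown', or 'html'."""
    if fmt == "json":
        return json.dumps(asdict(model), indent=2, sort_keys=True) + "\n"
    if fmt == "markdown":
        return _render_markdown(model)
    if fmt == "html":
        return _render_html(model)
    raise ValueError(f"unknown report format {fmt!r}; choose json, markdown, or html")


def _join(items: Sequence[str]) -> str:
    return ", ".join(items) if items else "—"


def _md_table(headers: list[str], rows: list[list[str]]) -> list[str]:
    out = ["| " + " | ".join(headers) + " |", "| " + " | ".join("---" for _ in headers) + " |"]
    for row in rows:
        out.append("| " + " | ".join(cell.replace("|", "\\|") for cell in row) + " |")
    return out


def _phenotype_cell(row: RecommendationRow) -> str:
    return "; ".join(f"{g}: {t}" for g, t in row.phenotypes)


def _rec_table_rows(rows: Sequence[RecommendationRow]) -> list[list[str]]:
    out = []
    for r in rows:
        text = r.recommendation + (" [placeholder]" if r.placeholder else "")
        out.append(
            [
                r.drug,
                r.drug_class,
                ", ".join(r.genes),
                _phenotype_cell(r),
                text,
                r.strength,
                r.source or "—",
                "yes" if r.actionable else "no",
            ]
        )
    return out


_REC_HEADERS = ["Drug", "Class", "Gene(s)", "Phenotype(s)", "Recommendation", "Strength", "Source", "Actionable"]


def _render_markdown(model: ReportModel) -> str:
    lines = [
        "# Pharmacogenomic Report",
        "",
        f"Generated on: {model.generated_on}  ",
        f"Knowledge base: {model.kb_version} (last updated {model.kb_last_updated})",
        "",
    ]
    if model.metadata:
        lines += ["## Labels", ""]
        lines += [f"- {k}: {v}" for k, v in model.metadata.items()]
        lines.append("")

    lines += ["## Genetic Results", ""]
    lines += _md_table(
        ["Gene", "Genotype", "Diplotype", "Inferred phenotype", "Converted phenotype", "Basis", "Note"],
        [
            [
                r.gene,
                r.genotype_entered or "—",
                r.diplotype or "—",
                r.inferred_phenotype,
                r.converted_phenotype or "—",
                r.conversion_basis,
                r.note or "",
            ]
            for r in model.genetic_results
        ],
    )
    lines.append("")

    lines += ["## Current Medications", ""]
    lines.append(f"Entered: {_join(model.current_medications)}")
    lines.append("")
    lines += _md_table(
        ["Gene", "Substrates", "Weak inhibitors", "Moderate inhibitors", "Strong inhibitors", "Inducers"],
        [
            [
                r.gene,
                _join(r.substrates),
                _join(r.weak_inhibitors),
                _join(r.moderate_inhibitors),
                _join(r.strong_inhibitors),
                _join(r.inducers),
            ]
            for r in model.current_medication_table
        ],
    )
    if model.unrecognized_current:
        lines.append("")
        lines.append(f"Unrecognized: {_join(model.unrecognized_current)}")
    lines.append("")

    lines += ["## Future Medications", ""]
    lines += _md_table(_REC_HEADERS, _rec_table_rows(model.future_medications))
    lines.append("")

    lines += ["## Medications Being Considered", ""]
    if model.considered_medications:
        lines += _md_table(_REC_HEADERS, _rec_table_rows(model.considered_medications))
    else:
        lines.append("None specified.")
    if model.unsupported_considered:
        lines.append("")
        lines.append(f"Not supported by the knowledge base: {_join(model.unsupported_considered)}")
    lines.append("")

    lines += ["## Disclaimer", "", model.disclaimer, ""]
    return "\n".join(lines)


def _html_table(headers: list[str], rows: list[list[str]]) -> list[str]:
    out = ["<table>", "<tr>" + "".join(f"<th>{_html.escape(h)}</th>" for h in headers) + "</tr>"]
    for row in rows:
        out.append("<tr>" + "".join(f"<td>{_html.escape(c)}</td>" for c in row) + "</tr>")
    out.append("</table>")
    return out


def _render_html(model: ReportModel) -> str:
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'><title>Pharmacogenomic Report</title>",
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:4px 8px;text-align:left}"
        ".kb-stamp{float:right;text-align:right;font-size:0.9em;color:#333}</style>",
        "</head><body>",
        "<div class='kb-stamp'>"
        f"Knowledge base {_html.escape(model.kb_version)}<br>"
        f"Database last updated: {_html.escape(model.kb_last_updated)}</div>",
        "<h1>Pharmacogenomic Report</h1>",
        f"<p>Generated on {_html.escape(model.generated_on)}</p>",
    ]
    if model.metadata:
        parts.append("<h2>Labels</h2><ul>")
        parts += [f"<li>{_html.escape(k)}: {_html.escape(v)}</li>" for k, v in model.metadata.items()]
        parts.append("</ul>")
    parts.append("<h2>Genetic Results</h2>")
    parts += _html_table(
        ["Gene", "Genotype", "Diplotype", "Inferred phenotype", "Converted phenotype", "Basis", "Note"],
        [
            [r.gene, r.genotype_entered, r.diplotype, r.inferred_phenotype,
             r.converted_phenotype, r.conversion_basis, r.note]
            for r in model.genetic_results
        ],
    )
    parts.append("<h2>Current Medications</h2>")
    parts.append(f"<p>Entered: {_html.escape(_join(model.current_medications))}</p>")
    parts += _html_table(
        ["Gene", "Substrates", "Weak inhibitors", "Moderate inhibitors", "Strong inhibitors", "Inducers"],
        [
            [r.gene, _join(r.substrates), _join(r.weak_inhibitors), _join(r.moderate_inhibitors),
             _join(r.strong_inhibitors), _join(r.inducers)]
            for r in model.current_medication_table
        ],
    )
    if model.unrecognized_current:
        parts.append(f"<p>Unrecognized: {_html.escape(_join(model.unrecognized_current))}</p>")
    parts.append("<h2>Future Medications</h2>")
    parts += _html_table(_REC_HEADERS, _rec_table_rows(model.future_medications))
    parts.append("<h2>Medications Being Considered</h2>")
    if model.considered_medications:
        parts += _html_table(_REC_HEADERS, _rec_table_rows(model.considered_medications))
    else:
        parts.append("<p>None specified.</p>")
    if model.unsupported_considered:
        parts.append(
            f"<p>Not supported by the knowledge base: {_html.escape(_join(model.unsupported_considered))}</p>"
        )
    parts.append("<h2>Disclaimer</h2>")
    parts.append(f"<p>{_html.escape(model.disclaimer)}</p>")
    parts.append("</body></html>")
    return "\n".join(parts) + "\n"
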