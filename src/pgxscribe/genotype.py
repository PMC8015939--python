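"""Patient input parsing and normalization.

The engine consumes a three-part patient record mirroring a three-step entry
workflow: (1) per-gene genotype calls with optional free-text notes, (2) the
current medication list used for phenoconversion adjustment, and (3) a list of
medications being considered for future use. Records arrive as JSON (primary)
or a sectioned TSV dialect; nothing the parser reads is ever persisted.

Genotype values are normalized to canonical lookup keys before translation:
star-allele diplotypes are allele-sorted so ``*2/*1`` and ``*1/*2`` hit the
same table row, HLA presence calls collapse the accepted entry dialects onto
``"<allele> positive|negative"``, and named-variant genotypes (VKORC1) become
a sorted nucleotide pair.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional

from .kb import GeneDefinition, InputMode, KnowledgeBase


class PatientInputError(ValueError):
    """Patient document violates the input schema."""


class DiplotypeParseError(ValueError):
    """A genotype value cannot be normalized for its gene's input mode."""


@dataclass(frozen=True)
class GenotypeEntry:
    gene: str
    raw_value: str
    note: Optional[str] = None


@dataclass
class PatientRecord:
    genotypes: list[GenotypeEntry] = field(default_factory=list)
    current_medications: list[str] = field(default_factory=list)
    considered_medications: list[str] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def genotype_for(self, gene: str) -> Optional[GenotypeEntry]:
        for entry in self.genotypes:
            if entry.gene == gene:
                return entry
        return None


@dataclass(frozen=True)
class NormalizedDrug:
    """Outcome of drug-name normalization; unrecognized names are kept, flagged."""

    name: str
    recognized: bool


_TOP_LEVEL_KEYS = {
    "genotypes",
    "current_medications",
    "current",
    "considered_medications",
    "considered",
    "metadata",
}
_GENOTYPE_KEYS = {"gene", "value", "note"}


def _check_genotypes(entries: list[GenotypeEntry]) -> None:
    seen: set[str] = set()
    for entry in entries:
        if not entry.raw_value:
            raise PatientInputError(f"empty genotype value for gene {entry.gene}")
        if entry.gene in seen:
            raise PatientInputError(f"duplicate genotype entry for gene {entry.gene}")
        seen.add(entry.gene)


def parse_patient_json(text: str) -> PatientRecord:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PatientInputError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise PatientInputError("patient document must be a JSON object")
    unknown = set(doc) - _TOP_LEVEL_KEYS
    if unknown:
        raise PatientInputError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")

    genotypes: list[GenotypeEntry] = []
    for item in doc.get("genotypes", []):
        if not isinstance(item, dict):
            raise PatientInputError(f"genotype entry must be an object, got {item!r}")
        extra = set(item) - _GENOTYPE_KEYS
        if extra:
            raise PatientInputError(f"unknown genotype key(s): {', '.join(sorted(extra))}")
        if "gene" not in item or "value" not in item:
            raise PatientInputError(f"genotype entry needs 'gene' and 'value': {item!r}")
        genotypes.append(
            GenotypeEntry(str(item["gene"]).strip(), str(item["value"]).strip(), item.get("note"))
        )
    _check_genotypes(genotypes)

    def meds(primary: str, alias: str) -> list[str]:
        if primary in doc and alias in doc:
            raise PatientInputError(f"specify either {primary!r} or {alias!r}, not both")
        raw = doc.get(primary, doc.get(alias, []))
        if not isinstance(raw, list):
            raise PatientInputError(f"{primary} must be a list of drug names")
        return [str(d).strip() for d in raw if str(d).strip()]

    return PatientRecord(
        genotypes=genotypes,
        current_medications=meds("current_medications", "current"),
        considered_medications=meds("considered_medications", "considered"),
        metadata={str(k): str(v) for k, v in doc.get("metadata", {}).items()},
    )


_TSV_SECTIONS = {"genotypes", "current_medications", "considered_medications", "metadata"}


def parse_patient_tsv(text: str) -> PatientRecord:
    """Parse the sectioned TSV dialect (``[section]`` headers, tab-split rows)."""
    record = PatientRecord()
    section: Optional[str] = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            section = stripped[1:-1].strip()
            if section not in _TSV_SECTIONS:
                raise PatientInputError(f"line {lineno}: unknown section [{section}]")
            continue
        if section is None:
            raise PatientInputError(f"line {lineno}: content before any [section] header")
        cells = [c.strip() for c in line.split("\t")]
        if section == "genotypes":
            if len(cells) < 2:
                raise PatientInputError(f"line {lineno}: genotype rows need gene<TAB>value")
            record.genotypes.append(
                GenotypeEntry(cells[0], cells[1], cells[2] if len(cells) > 2 and cells[2] else None)
            )
        elif section == "metadata":
            if len(cells) != 2:
                raise PatientInputError(f"line {lineno}: metadata rows need key<TAB>value")
            record.metadata[cells[0]] = cells[1]
        else:
            getattr(record, section).append(cells[0])
    _check_genotypes(record.genotypes)
    return record


def parse_patient_input(text: str, fmt: Optional[str] = None) -> PatientRecord:
    """Parse a patient document; ``fmt`` is 'json', 'tsv', or None to sniff."""
    if fmt is None:
        fmt = "json" if text.lstrip()[:1] == "{" else "tsv"
    if fmt == "json":
        return parse_patient_json(text)
    if fmt == "tsv":
        return parse_patient_tsv(text)
    raise PatientInputError(f"unknown patient input format {fmt!r}")


def serialize_patient(record: PatientRecord) -> str:
    """Render a PatientRecord back to its JSON document form."""
    doc = {
        "genotypes": [
            {"gene": e.gene, "value": e.raw_value, **({"note": e.note} if e.note else {})}
            for e in record.genotypes
        ],
        "current_medications": record.current_medications,
        "considered_medications": record.considered_medications,
        "metadata": record.metadata,
    }
    return json.dumps(doc, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Genotype normalization

_STAR_ALLELE_RE = re.compile(r"^\*(\d+)([A-Z]?)(?:x(\d+|N))?$")
_HLA_RE = re.compile(
    r"^(?:(?:HLA-?)?[A-Z]\s*)?\*?\s*(\d{1,3}:\d{2,3})\s*[: ]?\s*"
    r"(pos|positive|\+|present|detected|carrier|neg|negative|-|absent|not detected|non-carrier)$",
    re.IGNORECASE,
)
_POSITIVE_WORDS = {"pos", "positive", "+", "present", "detected", "carrier"}
_VARIANT_ALLELE_RE = re.compile(r"^[ACGT]$")


def _star_sort_key(token: str) -> tuple[int, str, int]:
    m = _STAR_ALLELE_RE.match(token)
    assert m is not None
    num, letter, copies = m.groups()
    return (int(num), letter or "", 1 if copies is None else (10**6 if copies == "N" else int(copies)))


def normalize_diplotype(gene_def: GeneDefinition, raw: str) -> str:
    """Normalize a raw genotype string to the canonical lookup key for its gene."""
    value = raw.strip()
    if not value:
        raise DiplotypeParseError(f"{gene_def.symbol}: empty genotype value")

    if gene_def.input_mode is InputMode.STAR_DIPLOTYPE:
        tokens = [t.strip() for t in value.split("/")]
        if len(tokens) != 2:
            raise DiplotypeParseError(
                f"{gene_def.symbol}: expected two '/'-separated star alleles, got {len(tokens)} in {raw!r}"
            )
        for token in tokens:
            if not _STAR_ALLELE_RE.match(token):
                raise DiplotypeParseError(f"{gene_def.symbol}: malformed star allele {token!r}")
        return "/".join(sorted(tokens, key=_star_sort_key))

    if gene_def.input_mode is InputMode.HLA_PRESENCE:
        m = _HLA_RE.match(value)
        if not m:
            raise DiplotypeParseError(
                f"{gene_def.symbol}: cannot parse HLA presence call {raw!r} "
                "(expected e.g. '*57:01 positive')"
            )
        allele, status = m.groups()
        word = "positive" if status.lower() in _POSITIVE_WORDS else "negative"
        return f"*{allele} {word}"

    # variant_genotype: a pair of nucleotide alleles, order-insensitive
    tokens = [t.strip().upper() for t in value.split("/")]
    if len(tokens) != 2 or not all(_VARIANT_ALLELE_RE.match(t) for t in tokens):
        raise DiplotypeParseError(
            f"{gene_def.symbol}: expected a nucleotide pair like 'G/A', got {raw!r}"
        )
    return "/".join(sorted(tokens))


# Alternate spellings mapped onto the registry's canonical names (the registry
# keeps its curated spellings verbatim, including 'cavedilol'/'odansetron').
DRUG_SYNONYMS: dict[str, str] = {
    "carvedilol": "cavedilol",
    "ondansetron": "odansetron",
    "st. john's wort": "st john's wort",
    "st johns wort": "st john's wort",
    "asa": "aspirin",
    "acetylsalicylic acid": "aspirin",
    "rifampicin": "rifampin",
}


def normalize_drug_name(kb: KnowledgeBase, raw: str) -> NormalizedDrug:
    """Case-fold and match a drug name against the KB; unknowns are flagged, kept."""
    name = " ".join(raw.strip().lower().split())
    name = DRUG_SYNONYMS.get(name, name)
    return NormalizedDrug(name=name, recognized=name in kb.known_drugs())
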