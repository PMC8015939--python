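"""Versioned pharmacogenomic knowledge base: schema, loader, validator, statistics.

The knowledge base bundles four curated collections — gene definitions,
diplotype-to-phenotype maps, a CYP450 drug interaction catalog, and guideline
recommendation records — plus a registry of supported gene-drug pairs. On disk a
bundle is a directory of tab-delimited files with a ``manifest.json`` carrying
the version identifier and the date of the most recent curation update (the
date is stamped on every report header).
"""

from __future__ import annotations

import csv
import datetime
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional


class KBError(Exception):
    """Base class for knowledge-base errors."""


class KBLoadError(KBError):
    """A bundle file is missing or malformed."""


class KBValidationError(KBError):
    """A loaded bundle violates a schema invariant."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "; ".join(str(v) for v in violations[:10])
        more = "" if len(violations) <= 10 else f" (+{len(violations) - 10} more)"
        super().__init__(f"{len(violations)} violation(s): {lines}{more}")


class InputMode(str, enum.Enum):
    """How genotype data for a gene is entered."""

    STAR_DIPLOTYPE = "star_diplotype"
    HLA_PRESENCE = "hla_presence"
    VARIANT_GENOTYPE = "variant_genotype"


class Role(str, enum.Enum):
    SUBSTRATE = "substrate"
    INHIBITOR = "inhibitor"
    INDUCER = "inducer"


class Strength(str, enum.Enum):
    """Inhibitor strength category; inducers and substrates carry no strength."""

    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"
    NOT_APPLICABLE = "not_applicable"


_STRENGTH_ORDER = {Strength.WEAK: 1, Strength.MODERATE: 2, Strength.STRONG: 3}


class Source(str, enum.Enum):
    """Guideline source, in descending display preference CPIC > DPWG > FDA."""

    CPIC = "CPIC"
    DPWG = "DPWG"
    FDA = "FDA"


#: Lower rank wins during hierarchy resolution.
SOURCE_RANK: dict[Source, int] = {Source.CPIC: 0, Source.DPWG: 1, Source.FDA: 2}


class RecStrength(str, enum.Enum):
    """Strength of a prescribing recommendation (CPIC-aligned vocabulary)."""

    STRONG = "strong"
    MODERATE = "moderate"
    OPTIONAL = "optional"
    NONE = "none"


@dataclass(frozen=True)
class GeneDefinition:
    """A supported pharmacogene.

    ``phenotype_scale`` orders metabolizer terms from lowest to highest enzyme
    activity and is non-empty only for genes whose phenotype is an activity
    level (the CYP450s). Genes reported as categorical results (HLA presence,
    transporter function, warfarin sensitivity, thiopurine methylation) list
    their valid terms in ``categorical_terms`` instead and have no rank.
    """

    symbol: str
    input_mode: InputMode
    phenotype_scale: tuple[str, ...] = ()
    categorical_terms: tuple[str, ...] = ()
    phenoconversion_eligible: bool = False

    @property
    def valid_terms(self) -> tuple[str, ...]:
        return self.phenotype_scale if self.phenotype_scale else self.categorical_terms


@dataclass(frozen=True)
class DiplotypeMapEntry:
    """One row of a gene-specific diplotype-to-phenotype lookup table."""

    gene: str
    diplotype_key: str
    phenotype: str


@dataclass(frozen=True)
class InteractionRecord:
    """A drug's role for one CYP450 gene (substrate, inhibitor, or inducer).

    Inhibitors carry a weak/moderate/strong category; when the underlying
    pharmacokinetic evidence (fold-increase in a probe substrate's plasma AUC,
    or percent decrease in its clearance) is recorded, the stored category must
    equal :func:`classify_inhibitor_strength` applied to that evidence.
    """

    gene: str
    drug: str
    role: Role
    strength: Strength = Strength.NOT_APPLICABLE
    evidence_auc_fold: Optional[float] = None
    evidence_clearance_pct: Optional[float] = None


@dataclass(frozen=True)
class RecommendationRecord:
    """A curated prescribing recommendation for one drug and phenotype context.

    ``phenotype_key`` maps each gene the record depends on to the phenotype
    term it applies to; multi-gene records (e.g. warfarin keyed on CYP2C9 and
    VKORC1 jointly) list several genes. Fixture records carry placeholder prose
    and are flagged so rendered reports can label non-clinical content.
    """

    drug: str
    drug_class: str
    phenotype_key: tuple[tuple[str, str], ...]  # sorted (gene, term) pairs
    text: str
    strength: RecStrength
    source: Source
    pathway_url: str = ""
    actionable: bool = False
    placeholder: bool = False

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.phenotype_key)

    @property
    def phenotypes(self) -> dict[str, str]:
        return dict(self.phenotype_key)


def make_phenotype_key(mapping: Mapping[str, str]) -> tuple[tuple[str, str], ...]:
    """Canonical (sorted, hashable) form of a gene→phenotype-term mapping."""
    return tuple(sorted(mapping.items()))


@dataclass
class KnowledgeBase:
    """In-memory, validated knowledge-base bundle."""

    version: str
    last_updated: str  # ISO-8601 date
    genes: dict[str, GeneDefinition]
    pair_registry: frozenset[tuple[str, str]]
    hla_qualifiers: dict[tuple[str, str], str]  # (gene, drug) -> risk allele
    diplotype_maps: dict[tuple[str, str], str]  # (gene, diplotype_key) -> term
    interactions: tuple[InteractionRecord, ...]
    recommendations: tuple[RecommendationRecord, ...]

    def gene(self, symbol: str) -> GeneDefinition:
        try:
            return self.genes[symbol]
        except KeyError:
            raise KBError(f"unknown gene {symbol!r}") from None

    def registry_drugs(self) -> list[str]:
        return sorted({d for _, d in self.pair_registry})

    def registry_genes_for_drug(self, drug: str) -> list[str]:
        return sorted(g for g, d in self.pair_registry if d == drug)

    def interactions_for(self, gene: str) -> list[InteractionRecord]:
        return [r for r in self.interactions if r.gene == gene]

    def lookup_interaction(self, gene: str, drug: str) -> list[InteractionRecord]:
        return [r for r in self.interactions if r.gene == gene and r.drug == drug]

    def known_drugs(self) -> set[str]:
        """All drug names the KB can recognize (registry plus interaction catalog)."""
        return {d for _, d in self.pair_registry} | {r.drug for r in self.interactions}


@dataclass(frozen=True)
class Violation:
    """One schema-invariant violation: which record, which field, which rule."""

    record: str
    field: str
    rule: str

    def __str__(self) -> str:
        return f"{self.record}: {self.field}: {self.rule}"


def classify_inhibitor_strength(
    auc_fold: Optional[float] = None, clearance_pct: Optional[float] = None
) -> Strength:
    """Categorize an inhibitor as weak/moderate/strong from pharmacokinetic evidence.

    The category follows the fold increase in a substrate drug's plasma AUC
    (weak 1.25–2-fold, moderate >2-fold, strong >5-fold) or the percent
    decrease in its clearance (weak 20–49%, moderate 50–80%, strong >80%).
    When both measurements are supplied the stronger classification governs.

    Raises
    ------
    ValueError
        If no evidence value is supplied, a value is out of range, or every
        supplied value falls below the weak-inhibitor floor.
    """
    if auc_fold is None and clearance_pct is None:
        raise ValueError("at least one evidence value (auc_fold or clearance_pct) required")
    candidates: list[Strength] = []
    if auc_fold is not None:
        if auc_fold <= 0:
            raise ValueError(f"auc_fold must be positive, got {auc_fold}")
        if auc_fold > 5:
            candidates.append(Strength.STRONG)
        elif auc_fold > 2:
            candidates.append(Strength.MODERATE)
        elif auc_fold >= 1.25:
            candidates.append(Strength.WEAK)
    if clearance_pct is not None:
        if not 0 <= clearance_pct <= 100:
            raise ValueError(f"clearance_pct must be in [0, 100], got {clearance_pct}")
        if clearance_pct > 80:
            candidates.append(Strength.STRONG)
        elif clearance_pct >= 50:
            candidates.append(Strength.MODERATE)
        elif clearance_pct >= 20:
            candidates.append(Strength.WEAK)
    if not candidates:
        raise ValueError("below weak-inhibitor floor (AUC fold < 1.25 and clearance decrease < 20%)")
    return max(candidates, key=_STRENGTH_ORDER.__getitem__)


def validate_kb(kb: KnowledgeBase) -> list[Violation]:
    """Check every schema invariant; return violations instead of raising."""
    out: list[Violation] = []

    try:
        datetime.date.fromisoformat(kb.last_updated)
    except ValueError:
        out.append(Violation("manifest", "last_updated", f"not an ISO date: {kb.last_updated!r}"))

    for gd in kb.genes.values():
        rec = f"gene {gd.symbol}"
        if len(set(gd.phenotype_scale)) != len(gd.phenotype_scale):
            out.append(Violation(rec, "phenotype_scale", "duplicate phenotype terms"))
        if gd.input_mode is InputMode.HLA_PRESENCE and gd.phenotype_scale:
            out.append(Violation(rec, "phenotype_scale", "HLA presence genes have no activity scale"))
        if gd.phenoconversion_eligible and not gd.phenotype_scale:
            out.append(
                Violation(rec, "phenoconversion_eligible", "eligible gene needs an activity scale")
            )

    for g, d in sorted(kb.pair_registry):
        if g not in kb.genes:
            out.append(Violation(f"pair ({g}, {d})", "gene", "gene not defined"))

    for (g, key), term in sorted(kb.diplotype_maps.items()):
        rec = f"diplotype map ({g}, {key})"
        if g not in kb.genes:
            out.append(Violation(rec, "gene", "gene not defined"))
            continue
        if term not in kb.genes[g].valid_terms:
            out.append(Violation(rec, "phenotype", f"term {term!r} not valid for {g}"))

    for ir in kb.interactions:
        rec = f"interaction ({ir.gene}, {ir.drug}, {ir.role.value})"
        if ir.gene not in kb.genes:
            out.append(Violation(rec, "gene", "gene not defined"))
        elif not kb.genes[ir.gene].phenoconversion_eligible:
            out.append(Violation(rec, "gene", "interaction catalog covers phenoconversion-eligible genes only"))
        if ir.role is Role.INHIBITOR:
            if ir.strength is Strength.NOT_APPLICABLE:
                out.append(Violation(rec, "strength", "inhibitors must carry weak/moderate/strong"))
            elif ir.evidence_auc_fold is not None or ir.evidence_clearance_pct is not None:
                try:
                    expected = classify_inhibitor_strength(ir.evidence_auc_fold, ir.evidence_clearance_pct)
                except ValueError as exc:
                    out.append(Violation(rec, "evidence", str(exc)))
                else:
                    if expected is not ir.strength:
                        out.append(
                            Violation(
                                rec,
                                "strength",
                                f"stored {ir.strength.value} but evidence classifies as {expected.value}",
                            )
                        )
        else:
            if ir.strength is not Strength.NOT_APPLICABLE:
                out.append(Violation(rec, "strength", f"{ir.role.value}s are not categorized by strength"))

    seen: set[tuple[str, tuple[tuple[str, str], ...], Source]] = set()
    for rr in kb.recommendations:
        rec = f"recommendation ({rr.drug}, {dict(rr.phenotype_key)}, {rr.source.value})"
        for g, term in rr.phenotype_key:
            if g not in kb.genes:
                out.append(Violation(rec, "phenotype_key", f"gene {g} not defined"))
                continue
            if (g, rr.drug) not in kb.pair_registry:
                out.append(Violation(rec, "drug", f"pair ({g}, {rr.drug}) not in registry"))
            if term not in kb.genes[g].valid_terms:
                out.append(Violation(rec, "phenotype_key", f"term {term!r} not valid for {g}"))
        sig = (rr.drug, rr.phenotype_key, rr.source)
        if sig in seen:
            out.append(Violation(rec, "source", "duplicate record for same drug, phenotype context and source"))
        seen.add(sig)

    return out


def kb_stats(kb: KnowledgeBase) -> dict[str, int]:
    """Summary counts over the gene-drug pair registry."""
    genes = {g for g, _ in kb.pair_registry}
    drugs = {d for _, d in kb.pair_registry}
    return {
        "n_genes": len(genes),
        "n_drugs": len(drugs),
        "n_pairs": len(kb.pair_registry),
        "n_phenoconversion_genes": sum(1 for gd in kb.genes.values() if gd.phenoconversion_eligible),
    }


# ---------------------------------------------------------------------------
# TSV bundle serialization

_FILES = {
    "manifest": "manifest.json",
    "genes": "genes.tsv",
    "pairs": "pairs.tsv",
    "diplotypes": "diplotypes.tsv",
    "interactions": "interactions.tsv",
    "recommendations": "recommendations.tsv",
}


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with path.open(newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def _write_tsv(path: Path, fieldnames: list[str], rows: Iterable[Mapping[str, str]]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)


def load_kb(path: str | Path) -> KnowledgeBase:
    """Load and validate a knowledge-base bundle directory.

    Raises :class:`KBLoadError` when a file is missing or malformed and
    :class:`KBValidationError` when the loaded content violates an invariant.
    Loading is read-only and idempotent.
    """
    root = Path(path)
    if not root.is_dir():
        raise KBLoadError(f"knowledge base directory absent: {root}")
    for label, name in _FILES.items():
        if not (root / name).exists():
            raise KBLoadError(f"{label} file absent: {name}")

    try:
        manifest = json.loads((root / _FILES["manifest"]).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise KBLoadError(f"manifest.json malformed: {exc}") from exc
    for key in ("version", "last_updated"):
        if key not in manifest:
            raise KBLoadError(f"manifest.json missing field {key!r}")

    def split(s: str) -> tuple[str, ...]:
        return tuple(t for t in s.split("|") if t)

    genes: dict[str, GeneDefinition] = {}
    for row in _read_tsv(root / _FILES["genes"]):
        try:
            gd = GeneDefinition(
                symbol=row["symbol"],
                input_mode=InputMode(row["input_mode"]),
                phenotype_scale=split(row["phenotype_scale"]),
                categorical_terms=split(row["categorical_terms"]),
                phenoconversion_eligible=row["phenoconversion_eligible"] == "true",
            )
        except (KeyError, ValueError) as exc:
            raise KBLoadError(f"genes.tsv row {row!r}: {exc}") from exc
        genes[gd.symbol] = gd

    pairs: set[tuple[str, str]] = set()
    qualifiers: dict[tuple[str, str], str] = {}
    for row in _read_tsv(root / _FILES["pairs"]):
        pair = (row["gene"], row["drug"])
        pairs.add(pair)
        if row.get("qualifier"):
            qualifiers[pair] = row["qualifier"]

    diplotypes = {
        (row["gene"], row["diplotype"]): row["phenotype"]
        for row in _read_tsv(root / _FILES["diplotypes"])
    }

    interactions = []
    for row in _read_tsv(root / _FILES["interactions"]):
        try:
            interactions.append(
                InteractionRecord(
                    gene=row["gene"],
                    drug=row["drug"],
                    role=Role(row["role"]),
                    strength=Strength(row["strength"]),
                    evidence_auc_fold=float(row["evidence_auc_fold"]) if row["evidence_auc_fold"] else None,
                    evidence_clearance_pct=float(row["evidence_clearance_pct"])
                    if row["evidence_clearance_pct"]
                    else None,
                )
            )
        except (KeyError, ValueError) as exc:
            raise KBLoadError(f"interactions.tsv row {row!r}: {exc}") from exc

    recommendations = []
    for row in _read_tsv(root / _FILES["recommendations"]):
        try:
            key = make_phenotype_key(
                dict(part.split("=", 1) for part in row["phenotype_key"].split("|"))
            )
            recommendations.append(
                RecommendationRecord(
                    drug=row["drug"],
                    drug_class=row["drug_class"],
                    phenotype_key=key,
                    text=row["text"],
                    strength=RecStrength(row["strength"]),
                    source=Source(row["source"]),
                    pathway_url=row.get("pathway_url", ""),
                    actionable=row["actionable"] == "true",
                    placeholder=row["placeholder"] == "true",
                )
            )
        except (KeyError, ValueError) as exc:
            raise KBLoadError(f"recommendations.tsv row {row!r}: {exc}") from exc

    kb = KnowledgeBase(
        version=str(manifest["version"]),
        last_updated=str(manifest["last_updated"]),
        genes=genes,
        pair_registry=frozenset(pairs),
        hla_qualifiers=qualifiers,
        diplotype_maps=diplotypes,
        interactions=tuple(interactions),
        recommendations=tuple(recommendations),
    )
    violations = validate_kb(kb)
    if violations:
        raise KBValidationError(violations)
    return kb


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    """Write a knowledge base as a TSV bundle (the inverse of :func:`load_kb`)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    (root / _FILES["manifest"]).write_text(
        json.dumps({"version": kb.version, "last_updated": kb.last_updated}, indent=2) + "\n",
        encoding="utf-8",
    )
    _write_tsv(
        root / _FILES["genes"],
        ["symbol", "input_mode", "phenotype_scale", "categorical_terms", "phenoconversion_eligible"],
        (
            {
                "symbol": gd.symbol,
                "input_mode": gd.input_mode.value,
                "phenotype_scale": "|".join(gd.phenotype_scale),
                "categorical_terms": "|".join(gd.categorical_terms),
                "phenoconversion_eligible": "true" if gd.phenoconversion_eligible else "false",
            }
            for gd in sorted(kb.genes.values(), key=lambda g: g.symbol)
        ),
    )
    _write_tsv(
        root / _FILES["pairs"],
        ["gene", "drug", "qualifier"],
        (
            {"gene": g, "drug": d, "qualifier": kb.hla_qualifiers.get((g, d), "")}
            for g, d in sorted(kb.pair_registry)
        ),
    )
    _write_tsv(
        root / _FILES["diplotypes"],
        ["gene", "diplotype", "phenotype"],
        (
            {"gene": g, "diplotype": key, "phenotype": term}
            for (g, key), term in sorted(kb.diplotype_maps.items())
        ),
    )
    _write_tsv(
        root / _FILES["interactions"],
        ["gene", "drug", "role", "strength", "evidence_auc_fold", "evidence_clearance_pct"],
        (
            {
                "gene": r.gene,
                "drug": r.drug,
                "role": r.role.value,
                "strength": r.strength.value,
                "evidence_auc_fold": "" if r.evidence_auc_fold is None else repr(r.evidence_auc_fold),
                "evidence_clearance_pct": ""
                if r.evidence_clearance_pct is None
                else repr(r.evidence_clearance_pct),
            }
            for r in sorted(kb.interactions, key=lambda r: (r.gene, r.drug, r.role.value))
        ),
    )
    _write_tsv(
        root / _FILES["recommendations"],
        [
            "drug",
            "drug_class",
            "phenotype_key",
            "text",
            "strength",
            "source",
            "pathway_url",
            "actionable",
            "placeholder",
        ],
        (
            {
                "drug": r.drug,
                "drug_class": r.drug_class,
                "phenotype_key": "|".join(f"{g}={t}" for g, t in r.phenotype_key),
                "text": r.text,
                "strength": r.strength.value,
                "source": r.source.value,
                "pathway_url": r.pathway_url,
                "actionable": "true" if r.actionable else "false",
                "placeholder": "true" if r.placeholder else "false",
            }
            for r in sorted(
                kb.recommendations, key=lambda r: (r.drug, r.phenotype_key, SOURCE_RANK[r.source])
            )
        ),
    )
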