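"""Phenoconversion: adjust inferred CYP450 phenotypes for concomitant drugs.

Concomitant medications can make the clinically observed phenotype diverge
from the genotype-inferred one. For the five eligible CYP450 genes (CYP2B6,
CYP2C9, CYP2C19, CYP2D6, CYP3A5) current medications are classified per gene
as substrates, weak/moderate/strong inhibitors, or inducers, and the inferred
phenotype is adjusted by a deliberately simple rule set:

* strong inhibitor present  -> converted to poor metabolizer, whatever the
  inferred phenotype;
* moderate inhibitor present -> converted one step down the gene's activity
  scale (skipping tiers the gene does not define);
* inducer present            -> converted one step up;
* an adjustment-triggering inhibitor (moderate/strong) together with an
  inducer -> no conversion (conflicting evidence);
* weak inhibitors alone never trigger a conversion but are still displayed;
* phenotypes already at the floor (poor) are not lowered and phenotypes at the
  ceiling are not raised; sentinel phenotypes are never converted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .kb import GeneDefinition, KnowledgeBase, Role, Strength
from .phenotype import PhenotypeCall, PhenotypeTerm, Sentinel, phenotype_rank


class PhenoconversionError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionProfile:
    """Current medications classified by role/strength for one eligible gene."""

    gene: str
    substrates: tuple[str, ...] = ()
    weak_inhibitors: tuple[str, ...] = ()
    moderate_inhibitors: tuple[str, ...] = ()
    strong_inhibitors: tuple[str, ...] = ()
    inducers: tuple[str, ...] = ()

    @property
    def is_empty(self) -> bool:
        return not (
            self.substrates
            or self.weak_inhibitors
            or self.moderate_inhibitors
            or self.strong_inhibitors
            or self.inducers
        )


class ConversionBasis(str, enum.Enum):
    NOT_APPLICABLE = "not_applicable"
    NO_TRIGGER = "no_trigger"
    MODERATE_INHIBITOR = "moderate_inhibitor"
    STRONG_INHIBITOR = "strong_inhibitor"
    INDUCER = "inducer"
    CONFLICT_NO_CHANGE = "conflict_no_change"
    FLOOR_NO_CHANGE = "floor_no_change"
    CEILING_NO_CHANGE = "ceiling_no_change"


#: Bases under which a converted term is actually produced.
CONVERTING_BASES = frozenset(
    {ConversionBasis.MODERATE_INHIBITOR, ConversionBasis.STRONG_INHIBITOR, ConversionBasis.INDUCER}
)


@dataclass(frozen=True)
class ConvertedPhenotypeCall:
    """An inferred phenotype together with its (possible) phenoconversion."""

    base: PhenotypeCall
    converted: Optional[str]
    basis: ConversionBasis
    triggering_drugs: tuple[str, ...] = ()

    @property
    def gene(self) -> str:
        return self.base.gene

    @property
    def effective(self) -> PhenotypeTerm:
        """Phenotype recommendations should use: converted when one applied."""
        return self.converted if self.converted is not None else self.base.inferred

    @property
    def was_converted(self) -> bool:
        return self.converted is not None


def build_interaction_profile(
    kb: KnowledgeBase, gene: str, current_medications: list[str]
) -> InteractionProfile:
    """Place each current medication into every role it holds for this gene.

    Medications with no catalog entry for the gene are omitted (they surface
    elsewhere in the report as neutral/unrecognized, never silently dropped
    from the report as a whole).
    """
    gene_def = kb.gene(gene)
    if not gene_def.phenoconversion_eligible:
        raise PhenoconversionError(f"{gene} is not phenoconversion-eligible")
    buckets: dict[str, list[str]] = {
        "substrates": [],
        "weak_inhibitors": [],
        "moderate_inhibitors": [],
        "strong_inhibitors": [],
        "inducers": [],
    }
    seen: set[tuple[str, str]] = set()
    for drug in current_medications:
        for rec in kb.lookup_interaction(gene, drug):
            if rec.role is Role.SUBSTRATE:
                bucket = "substrates"
            elif rec.role is Role.INDUCER:
                bucket = "inducers"
            else:
                bucket = f"{rec.strength.value}_inhibitors"
            if (drug, bucket) not in seen:
                seen.add((drug, bucket))
                buckets[bucket].append(drug)
    return InteractionProfile(gene=gene, **{k: tuple(v) for k, v in buckets.items()})


def apply_phenoconversion(
    gene_def: GeneDefinition,
    call: PhenotypeCall,
    profile: Optional[InteractionProfile] = None,
) -> ConvertedPhenotypeCall:
    """Apply the adjustment rules to one phenotype call.

    ``profile`` may be omitted (treated as empty) for non-eligible genes.
    """
    if call.gene != gene_def.symbol:
        raise PhenoconversionError(f"call gene {call.gene} != definition {gene_def.symbol}")
    if profile is not None and profile.gene != gene_def.symbol:
        raise PhenoconversionError(f"profile gene {profile.gene} != definition {gene_def.symbol}")

    if not gene_def.phenoconversion_eligible or call.is_sentinel:
        return ConvertedPhenotypeCall(call, None, ConversionBasis.NOT_APPLICABLE)
    if profile is None:
        profile = InteractionProfile(gene=gene_def.symbol)

    scale = gene_def.phenotype_scale
    rank = phenotype_rank(gene_def, call.inferred)
    strong = profile.strong_inhibitors
    moderate = profile.moderate_inhibitors
    inducers = profile.inducers

    if (strong or moderate) and inducers:
        return ConvertedPhenotypeCall(
            call, None, ConversionBasis.CONFLICT_NO_CHANGE, strong + moderate + inducers
        )
    if strong:
        if rank == 0:
            return ConvertedPhenotypeCall(call, None, ConversionBasis.FLOOR_NO_CHANGE, strong)
        return ConvertedPhenotypeCall(call, scale[0], ConversionBasis.STRONG_INHIBITOR, strong)
    if moderate:
        if rank == 0:
            return ConvertedPhenotypeCall(call, None, ConversionBasis.FLOOR_NO_CHANGE, moderate)
        return ConvertedPhenotypeCall(
            call, scale[rank - 1], ConversionBasis.MODERATE_INHIBITOR, moderate
        )
    if inducers:
        if rank == len(scale) - 1:
            return ConvertedPhenotypeCall(call, None, ConversionBasis.CEILING_NO_CHANGE, inducers)
        return ConvertedPhenotypeCall(call, scale[rank + 1], ConversionBasis.INDUCER, inducers)
    return ConvertedPhenotypeCall(call, None, ConversionBasis.NO_TRIGGER)


def convert_all(
    kb: KnowledgeBase, calls: list[PhenotypeCall], current_medications: list[str]
) -> tuple[list[ConvertedPhenotypeCall], dict[str, InteractionProfile]]:
    """Build per-gene profiles and apply phenoconversion to every call."""
    profiles = {
        gd.symbol: build_interaction_profile(kb, gd.symbol, current_medications)
        for gd in kb.genes.values()
        if gd.phenoconversion_eligible
    }
    converted = [
        apply_phenoconversion(kb.gene(c.gene), c, profiles.get(c.gene)) for c in calls
    ]
    return converted, profiles
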