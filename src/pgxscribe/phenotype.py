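"""Genotype-to-phenotype translation.

Each canonical diplotype is translated to an inferred phenotype by exact
lookup in the gene-specific diplotype-to-phenotype table — no interpolation
and no activity-score arithmetic. Two sentinel results are distinguished from
real phenotype terms: ``indeterminate`` (a diplotype was supplied but the
table has no row for it) and ``unknown`` (no genotype data supplied for the
gene). Sentinels are enum values, not strings, so downstream ranking and
phenoconversion cannot silently accept them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Union

from .kb import GeneDefinition, KnowledgeBase


class Sentinel(enum.Enum):
    """Non-phenotype translation outcomes."""

    UNKNOWN = "unknown"
    INDETERMINATE = "indeterminate"

    def __str__(self) -> str:  # pragma: no cover - display convenience
        return self.value


PhenotypeTerm = Union[str, Sentinel]


class PhenotypeRankError(ValueError):
    """Term has no position on the gene's activity scale."""


@dataclass(frozen=True)
class PhenotypeCall:
    """Result of translating one gene's genotype."""

    gene: str
    diplotype: Optional[str]
    inferred: PhenotypeTerm
    note: Optional[str] = None

    @property
    def is_sentinel(self) -> bool:
        return isinstance(self.inferred, Sentinel)

    @property
    def display_inferred(self) -> str:
        return self.inferred.value if isinstance(self.inferred, Sentinel) else self.inferred


def translate_diplotype(
    kb: KnowledgeBase,
    gene: str,
    diplotype: Optional[str] = None,
    note: Optional[str] = None,
) -> PhenotypeCall:
    """Translate a canonical diplotype key into a PhenotypeCall.

    Absent genotype -> ``unknown``; present but unmapped -> ``indeterminate``;
    otherwise the term stored in the lookup table.
    """
    kb.gene(gene)  # raises KBError for unknown genes
    if diplotype is None:
        return PhenotypeCall(gene, None, Sentinel.UNKNOWN, note)
    term = kb.diplotype_maps.get((gene, diplotype))
    if term is None:
        return PhenotypeCall(gene, diplotype, Sentinel.INDETERMINATE, note)
    return PhenotypeCall(gene, diplotype, term, note)


def phenotype_rank(gene_def: GeneDefinition, term: PhenotypeTerm) -> int:
    """0-based position of a term on the gene's activity scale (0 = lowest).

    Sentinels and categorical (non-scale) terms have no rank and raise.
    """
    if isinstance(term, Sentinel):
        raise PhenotypeRankError(f"{gene_def.symbol}: sentinel {term.value!r} has no activity rank")
    try:
        return gene_def.phenotype_scale.index(term)
    except ValueError:
        raise PhenotypeRankError(
            f"{gene_def.symbol}: term {term!r} not on activity scale {list(gene_def.phenotype_scale)}"
        ) from None
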