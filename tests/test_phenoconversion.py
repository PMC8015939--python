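"""Phenoconversion rules, checked cell-by-cell against an independent oracle.

The oracle re-states the adjustment policy directly: a moderate inhibitor
moves the phenotype one step down the activity scale, a strong inhibitor
forces poor metabolizer whatever the starting point, an inducer moves one
step up, floor/ceiling phenotypes are never pushed past the ends of the
scale, a (moderate-or-strong) inhibitor co-occurring with an inducer blocks
any conversion, and weak inhibitors alone never trigger one.
"""

import itertools

import pytest

from pgxscribe.phenoconversion import (
    ConversionBasis,
    InteractionProfile,
    PhenoconversionError,
    apply_phenoconversion,
    build_interaction_profile,
)
from pgxscribe.phenotype import PhenotypeCall, Sentinel


def oracle(scale, term, weak, moderate, strong, inducer):
    """Expected (basis, converted) for one truth-table cell."""
    if isinstance(term, Sentinel):
        return ("not_applicable", None)
    idx = scale.index(term)
    top = len(scale) - 1
    if (moderate or strong) and inducer:
        return ("conflict_no_change", None)
    if strong:
        return ("strong_inhibitor", scale[0]) if idx > 0 else ("floor_no_change", None)
    if moderate:
        return ("moderate_inhibitor", scale[idx - 1]) if idx > 0 else ("floor_no_change", None)
    if inducer:
        return ("inducer", scale[idx + 1]) if idx < top else ("ceiling_no_change", None)
    return ("no_trigger", None)


def _profile(gene, weak, moderate, strong, inducer):
    return InteractionProfile(
        gene=gene,
        weak_inhibitors=("weakdrug",) if weak else (),
        moderate_inhibitors=("moddrug",) if moderate else (),
        strong_inhibitors=("strongdrug",) if strong else (),
        inducers=("inducerdrug",) if inducer else (),
    )


def test_exhaustive_truth_table_agreement(kb):
    """Every eligible gene x every scale term (+ both sentinels) x all 16
    trigger combinations must match the independently coded oracle."""
    eligible = [gd for gd in kb.genes.values() if gd.phenoconversion_eligible]
    assert len(eligible) == 5
    cells = 0
    for gd in eligible:
        terms = list(gd.phenotype_scale) + [Sentinel.UNKNOWN, Sentinel.INDETERMINATE]
        for term, flags in itertools.product(terms, itertools.product([False, True], repeat=4)):
            weak, moderate, strong, inducer = flags
            call = PhenotypeCall(gd.symbol, None if term is Sentinel.UNKNOWN else "*1/*1", term)
            got = apply_phenoconversion(gd, call, _profile(gd.symbol, *flags))
            assert (got.basis.value, got.converted) == oracle(
                gd.phenotype_scale, term, weak, moderate, strong, inducer
            ), (gd.symbol, term, flags)
            cells += 1
    assert cells == (7 + 7 + 5 + 6 + 5) * 16  # scale sizes + sentinels, 16 combos each


def test_conversion_stays_on_scale_and_moves_one_step(kb):
    """Structural invariants over the same enumeration: converted terms lie on
    the gene's scale, single-step bases move exactly one rank, and the strong
    inhibitor basis always lands on the floor."""
    for gd in (g for g in kb.genes.values() if g.phenoconversion_eligible):
        scale = gd.phenotype_scale
        for term, flags in itertools.product(scale, itertools.product([False, True], repeat=4)):
            got = apply_phenoconversion(
                gd, PhenotypeCall(gd.symbol, "*1/*1", term), _profile(gd.symbol, *flags)
            )
            if got.converted is None:
                continue
            assert got.converted in scale
            if got.basis in (ConversionBasis.MODERATE_INHIBITOR, ConversionBasis.INDUCER):
                assert abs(scale.index(got.converted) - scale.index(term)) == 1
            if got.basis is ConversionBasis.STRONG_INHIBITOR:
                assert scale.index(got.converted) == 0


class TestWorkedExamples:
    def test_normal_plus_strong_inhibitor_becomes_poor(self, kb):
        gd = kb.gene("CYP2D6")
        profile = build_interaction_profile(kb, "CYP2D6", ["paroxetine"])
        assert profile.strong_inhibitors == ("paroxetine",)
        got = apply_phenoconversion(
            gd, PhenotypeCall("CYP2D6", "*1/*2", "normal metabolizer"), profile
        )
        assert got.converted == "poor metabolizer"
        assert got.basis is ConversionBasis.STRONG_INHIBITOR
        assert got.triggering_drugs == ("paroxetine",)

    def test_normal_plus_moderate_inhibitor_steps_down(self, kb):
        gd = kb.gene("CYP2C19")
        profile = build_interaction_profile(kb, "CYP2C19", ["omeprazole"])
        got = apply_phenoconversion(
            gd, PhenotypeCall("CYP2C19", "*1/*1", "normal metabolizer"), profile
        )
        assert got.converted == "intermediate metabolizer"
        assert got.basis is ConversionBasis.MODERATE_INHIBITOR

    def test_intermediate_plus_inducer_steps_up(self, kb):
        gd = kb.gene("CYP2C19")
        profile = build_interaction_profile(kb, "CYP2C19", ["rifampin"])
        got = apply_phenoconversion(
            gd, PhenotypeCall("CYP2C19", "*1/*2", "intermediate metabolizer"), profile
        )
        assert got.converted == "normal metabolizer"
        assert got.basis is ConversionBasis.INDUCER

    def test_extremes_are_not_pushed_past_the_scale(self, kb):
        d6 = kb.gene("CYP2D6")
        got = apply_phenoconversion(
            d6,
            PhenotypeCall("CYP2D6", "*4/*4", "poor metabolizer"),
            _profile("CYP2D6", False, False, True, False),
        )
        assert got.basis is ConversionBasis.FLOOR_NO_CHANGE and got.converted is None
        got = apply_phenoconversion(
            d6,
            PhenotypeCall("CYP2D6", "*1/*1x2", "ultrarapid metabolizer"),
            _profile("CYP2D6", False, False, False, True),
        )
        assert got.basis is ConversionBasis.CEILING_NO_CHANGE and got.converted is None

    def test_inhibitor_plus_inducer_conflict_blocks_conversion(self, kb):
        gd = kb.gene("CYP2C19")
        profile = build_interaction_profile(kb, "CYP2C19", ["omeprazole", "rifampin"])
        got = apply_phenoconversion(
            gd, PhenotypeCall("CYP2C19", "*1/*1", "normal metabolizer"), profile
        )
        assert got.basis is ConversionBasis.CONFLICT_NO_CHANGE and got.converted is None

    def test_weak_inhibitor_plus_inducer_still_induces(self, kb):
        # Weak inhibitors never trigger an adjustment, so they do not create a
        # conflict with an inducer.
        gd = kb.gene("CYP2C19")
        profile = build_interaction_profile(kb, "CYP2C19", ["cimetidine", "rifampin"])
        got = apply_phenoconversion(
            gd, PhenotypeCall("CYP2C19", "*1/*2", "intermediate metabolizer"), profile
        )
        assert got.basis is ConversionBasis.INDUCER
        assert got.converted == "normal metabolizer"

    def test_strong_dominates_moderate(self, kb):
        gd = kb.gene("CYP2D6")
        profile = build_interaction_profile(kb, "CYP2D6", ["duloxetine", "paroxetine"])
        got = apply_phenoconversion(
            gd, PhenotypeCall("CYP2D6", "*1/*1x2", "ultrarapid metabolizer"), profile
        )
        assert got.basis is ConversionBasis.STRONG_INHIBITOR
        assert got.converted == "poor metabolizer"


class TestInteractionProfile:
    def test_roles_are_bucketed_from_catalog(self, kb):
        profile = build_interaction_profile(
            kb, "CYP2D6", ["paroxetine", "codeine", "cimetidine", "duloxetine"]
        )
        assert profile.substrates == ("codeine",)
        assert profile.weak_inhibitors == ("cimetidine",)
        assert profile.moderate_inhibitors == ("duloxetine",)
        assert profile.strong_inhibitors == ("paroxetine",)

    def test_empty_and_uncatalogued_medications_yield_empty_profile(self, kb):
        assert build_interaction_profile(kb, "CYP2D6", []).is_empty
        # tacrolimus has no CYP2D6 catalog entry
        assert build_interaction_profile(kb, "CYP2D6", ["tacrolimus"]).is_empty

    def test_non_eligible_gene_rejected(self, kb):
        with pytest.raises(PhenoconversionError, match="not phenoconversion-eligible"):
            build_interaction_profile(kb, "TPMT", ["paroxetine"])

    def test_gene_mismatch_rejected(self, kb):
        with pytest.raises(PhenoconversionError, match="profile gene"):
            apply_phenoconversion(
                kb.gene("CYP2D6"),
                PhenotypeCall("CYP2D6", "*1/*1", "normal metabolizer"),
                InteractionProfile(gene="CYP2C19"),
            )
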