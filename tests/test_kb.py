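"""Knowledge-base schema, loader, classifier, and statistics tests."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxscribe.kb import (
    InteractionRecord,
    KBLoadError,
    KBValidationError,
    RecommendationRecord,
    RecStrength,
    Role,
    Source,
    Strength,
    classify_inhibitor_strength,
    kb_stats,
    load_kb,
    make_phenotype_key,
    save_kb,
    validate_kb,
)

_RANK = {Strength.WEAK: 1, Strength.MODERATE: 2, Strength.STRONG: 3}


class TestClassifyInhibitorStrength:
    @pytest.mark.parametrize(
        "auc, expected",
        [
            (1.25, Strength.WEAK),
            (1.6, Strength.WEAK),
            (2.0, Strength.WEAK),  # weak band is closed at 2-fold
            (2.01, Strength.MODERATE),
            (5.0, Strength.MODERATE),  # strong requires strictly >5-fold
            (5.01, Strength.STRONG),
            (6.0, Strength.STRONG),
        ],
    )
    def test_auc_thresholds(self, auc, expected):
        assert classify_inhibitor_strength(auc_fold=auc) is expected

    @pytest.mark.parametrize(
        "pct, expected",
        [
            (20, Strength.WEAK),
            (49, Strength.WEAK),
            (50, Strength.MODERATE),
            (80, Strength.MODERATE),  # strong requires strictly >80%
            (81, Strength.STRONG),
            (85, Strength.STRONG),
            (100, Strength.STRONG),
        ],
    )
    def test_clearance_thresholds(self, pct, expected):
        assert classify_inhibitor_strength(clearance_pct=pct) is expected

    def test_both_supplied_stronger_wins(self):
        assert classify_inhibitor_strength(auc_fold=1.5, clearance_pct=90) is Strength.STRONG
        assert classify_inhibitor_strength(auc_fold=6.0, clearance_pct=25) is Strength.STRONG

    def test_below_floor_and_missing_evidence_raise(self):
        with pytest.raises(ValueError, match="below weak-inhibitor floor"):
            classify_inhibitor_strength(auc_fold=1.1, clearance_pct=10)
        with pytest.raises(ValueError, match="at least one evidence value"):
            classify_inhibitor_strength()
        with pytest.raises(ValueError):
            classify_inhibitor_strength(clearance_pct=120)

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.floats(min_value=1.25, max_value=50, allow_nan=False),
        b=st.floats(min_value=1.25, max_value=50, allow_nan=False),
    )
    def test_monotone_in_auc(self, a, b):
        lo, hi = sorted((a, b))
        assert _RANK[classify_inhibitor_strength(auc_fold=lo)] <= _RANK[
            classify_inhibitor_strength(auc_fold=hi)
        ]

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.floats(min_value=20, max_value=100, allow_nan=False),
        b=st.floats(min_value=20, max_value=100, allow_nan=False),
    )
    def test_monotone_in_clearance(self, a, b):
        lo, hi = sorted((a, b))
        assert _RANK[classify_inhibitor_strength(clearance_pct=lo)] <= _RANK[
            classify_inhibitor_strength(clearance_pct=hi)
        ]


class TestFixtureKB:
    def test_fixture_self_validates(self, kb):
        assert validate_kb(kb) == []

    def test_stats_match_registry(self, kb):
        stats = kb_stats(kb)
        assert stats["n_pairs"] == 97
        assert stats["n_genes"] == 11
        assert stats["n_phenoconversion_genes"] == 5

    def test_registry_matches_independent_transcription(self, kb, transcribed_registry):
        pairs, qualifiers = transcribed_registry
        assert set(kb.pair_registry) == pairs
        assert kb.hla_qualifiers == qualifiers

    def test_per_gene_drug_counts(self, kb, transcribed_registry):
        pairs, _ = transcribed_registry
        expected = {}
        for g, _d in pairs:
            expected[g] = expected.get(g, 0) + 1
        actual = {}
        for g, _d in kb.pair_registry:
            actual[g] = actual.get(g, 0) + 1
        assert actual == expected

    def test_phenoconversion_gene_set(self, kb):
        eligible = {g.symbol for g in kb.genes.values() if g.phenoconversion_eligible}
        assert eligible == {"CYP2B6", "CYP2C9", "CYP2C19", "CYP2D6", "CYP3A5"}

    def test_paroxetine_is_strong_cyp2d6_inhibitor(self, kb):
        recs = kb.lookup_interaction("CYP2D6", "paroxetine")
        assert [(r.role, r.strength) for r in recs] == [(Role.INHIBITOR, Strength.STRONG)]

    def test_cyp3a5_registry_row(self, kb):
        assert kb.registry_genes_for_drug("tacrolimus") == ["CYP3A5"]
        assert {d for g, d in kb.pair_registry if g == "CYP3A5"} == {"tacrolimus"}

    def test_every_pair_has_a_recommendation(self, kb):
        covered = {(g, r.drug) for r in kb.recommendations for g in r.genes}
        assert covered == set(kb.pair_registry)

    def test_interaction_evidence_consistent_with_classifier(self, kb):
        checked = 0
        for r in kb.interactions:
            if r.role is Role.INHIBITOR and (
                r.evidence_auc_fold is not None or r.evidence_clearance_pct is not None
            ):
                assert (
                    classify_inhibitor_strength(r.evidence_auc_fold, r.evidence_clearance_pct)
                    is r.strength
                ), r
                checked += 1
        assert checked >= 10  # the catalog actually carries evidence

    def test_all_fixture_recommendations_are_placeholder_flagged(self, kb):
        assert all(r.placeholder for r in kb.recommendations)


class TestValidateKB:
    def test_inducer_with_strength_is_flagged(self, kb):
        bad = dataclasses.replace(
            kb,
            interactions=kb.interactions
            + (InteractionRecord("CYP2D6", "rifampin", Role.INDUCER, Strength.STRONG),),
        )
        violations = validate_kb(bad)
        assert len(violations) == 1
        assert "not categorized by strength" in violations[0].rule

    def test_unknown_phenotype_term_is_flagged(self, kb):
        bad = dataclasses.replace(
            kb,
            diplotype_maps={**kb.diplotype_maps, ("CYP2D6", "*1/*9"): "rapid metabolizer"},
        )
        violations = validate_kb(bad)
        assert [v for v in violations if "rapid metabolizer" in v.rule]

    def test_unregistered_pair_is_flagged(self, kb):
        rogue = RecommendationRecord(
            drug="warfarin",
            drug_class="anticoagulant",
            phenotype_key=make_phenotype_key({"CYP2D6": "poor metabolizer"}),
            text="x",
            strength=RecStrength.STRONG,
            source=Source.CPIC,
        )
        bad = dataclasses.replace(kb, recommendations=kb.recommendations + (rogue,))
        violations = validate_kb(bad)
        assert any("(CYP2D6, warfarin) not in registry" in v.rule for v in violations)

    def test_mismatched_evidence_strength_is_flagged(self, kb):
        bad = dataclasses.replace(
            kb,
            interactions=kb.interactions
            + (
                InteractionRecord(
                    "CYP2D6", "somedrug", Role.INHIBITOR, Strength.WEAK, evidence_auc_fold=9.0
                ),
            ),
        )
        violations = validate_kb(bad)
        assert any("evidence classifies as strong" in v.rule for v in violations)


class TestBundleIO:
    def test_round_trip_preserves_everything(self, kb, tmp_path):
        save_kb(kb, tmp_path / "bundle")
        loaded = load_kb(tmp_path / "bundle")
        assert kb_stats(loaded) == kb_stats(kb)
        assert loaded.genes == kb.genes
        assert loaded.pair_registry == kb.pair_registry
        assert loaded.hla_qualifiers == kb.hla_qualifiers
        assert loaded.diplotype_maps == kb.diplotype_maps
        assert set(loaded.interactions) == set(kb.interactions)
        assert set(loaded.recommendations) == set(kb.recommendations)
        assert (loaded.version, loaded.last_updated) == (kb.version, kb.last_updated)

    def test_missing_interactions_file_names_it(self, kb, tmp_path):
        save_kb(kb, tmp_path / "bundle")
        (tmp_path / "bundle" / "interactions.tsv").unlink()
        with pytest.raises(KBLoadError, match="interactions file absent"):
            load_kb(tmp_path / "bundle")

    def test_invalid_bundle_raises_validation_error(self, kb, tmp_path):
        save_kb(kb, tmp_path / "bundle")
        with (tmp_path / "bundle" / "recommendations.tsv").open("a", encoding="utf-8") as fh:
            fh.write(
                "warfarin\tanticoagulant\tCYP2D6=poor metabolizer\tx\tstrong\tCPIC\t\tfalse\tfalse\n"
            )
        with pytest.raises(KBValidationError, match="not in registry"):
            load_kb(tmp_path / "bundle")
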