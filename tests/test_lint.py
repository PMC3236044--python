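"""Rule engine: naming, structured evidence grammar, pseudogene strategies,
locus_tags, structure, and order-independence."""

import random
from collections import Counter

import pytest

from annotqc.config import QCConfig
from annotqc.lint import (
    RULE_CATALOG,
    ExperimentEvidence,
    InferenceEvidence,
    lint_protein_name,
    lint_record,
    parse_experiment,
    parse_inference,
    validate_locus_tags,
    validate_pseudogenes,
    validate_structure,
)
from annotqc.records import Feature, GenomeRecord, Location, Replicon
from annotqc.synth import GenomeSpec, generate, gold_standard


class TestProteinNaming:
    @pytest.mark.parametrize("name", ["hypothetical protein", "uncharacterized protein"])
    def test_the_two_accepted_unknown_function_names_pass(self, name):
        assert lint_protein_name(name) == []

    @pytest.mark.parametrize("name", [
        "conserved hypothetical protein",
        "novel protein",
        "protein of unknown function",
    ])
    def test_banned_synonyms_fail_with_suggestion(self, name):
        findings = lint_protein_name(name)
        assert any(f.rule_id == "NAME001" and f.severity == "FAIL" for f in findings)
        assert findings[0].suggestion == "hypothetical protein"

    def test_whitespace_irregularities_warn(self):
        findings = lint_protein_name("DNA  gyrase subunit A ")
        assert [f.rule_id for f in findings] == ["NAME002"]
        assert findings[0].suggestion == "DNA gyrase subunit A"

    def test_bare_locus_tag_as_name_warns(self):
        assert any(f.rule_id == "NAME005" for f in lint_protein_name("ECK_0001"))

    def test_style_rules_off_by_default(self):
        assert lint_protein_name("ALKALINE PHOSPHATASE") == []
        cfg = QCConfig(style_name_rules=True)
        assert any(f.rule_id == "NAME003"
                   for f in lint_protein_name("ALKALINE PHOSPHATASE", cfg))
        assert any(f.rule_id == "NAME004"
                   for f in lint_protein_name("ABC transporter homolog", cfg))


class TestInferenceGrammar:
    def test_category_type_and_accessioned_basis(self):
        ev, findings = parse_inference("COORDINATES: similar to AA sequence:INSD:AAD51968.1")
        assert findings == []
        assert ev.category == "COORDINATES"
        assert ev.type == "similar to AA sequence"
        assert ev.basis == [("INSD", "AAD51968.1")]

    def test_ab_initio_with_versioned_algorithm(self):
        ev, findings = parse_inference("ab initio prediction:Genscan:2.0")
        assert findings == []
        assert ev.type == "ab initio prediction"
        assert ev.basis == [("Genscan", "2.0")]

    def test_unknown_type_is_ev001(self):
        ev, findings = parse_inference("EXISTENCE: banana")
        assert ev is None
        assert [f.rule_id for f in findings] == ["EV001"]
        assert "banana" in findings[0].message

    def test_basisless_similarity_is_ev002(self):
        ev, findings = parse_inference("profile")
        assert ev is not None
        assert [f.rule_id for f in findings] == ["EV002"]

    def test_same_species_flag(self):
        ev, _ = parse_inference("similar to DNA sequence (same species):INSD:AE000111.1")
        assert ev.same_species

    @pytest.mark.parametrize("raw", [
        "COORDINATES: similar to AA sequence:INSD:AAD51968.1",
        "ab initio prediction:Genscan:2.0",
        "DESCRIPTION: profile:Pfam:PF00001",
        "non-experimental evidence, no additional details recorded",
        "EXISTENCE: similar to RNA sequence, mRNA (same species):INSD:BC010987.2",
    ])
    def test_render_parse_is_canonical_identity(self, raw):
        ev, findings = parse_inference(raw)
        assert ev is not None
        canonical = ev.render()
        ev2, findings2 = parse_inference(canonical)
        assert ev2 == ev
        assert ev2.render() == canonical

    def test_parse_after_render_identity_on_objects(self):
        ev = InferenceEvidence(type="alignment", category="COORDINATES",
                               basis=[("Splign", "1.0")])
        assert parse_inference(ev.render())[0] == ev


class TestExperimentGrammar:
    def test_category_description_citation(self):
        ev, findings = parse_experiment("EXISTENCE: N-terminal sequencing [PMID:1234567]")
        assert findings == []
        assert ev.category == "EXISTENCE"
        assert ev.description == "N-terminal sequencing"
        assert ev.citation == "PMID:1234567"

    def test_category_case_folded(self):
        ev, _ = parse_experiment("coordinates: transcript mapping")
        assert ev.category == "COORDINATES"

    def test_empty_description_is_ev003(self):
        ev, findings = parse_experiment("DESCRIPTION:")
        assert ev is None
        assert [f.rule_id for f in findings] == ["EV003"]

    def test_render_parse_round_trip(self):
        ev = ExperimentEvidence(description="heterologous expression",
                                category="EXISTENCE", citation="PMID:99")
        assert parse_experiment(ev.render())[0] == ev


def _one_feature_record(feat, length=2000):
    return GenomeRecord(replicons=[Replicon("r", "A" * length, features=[feat])])


class TestPseudogeneRules:
    def test_translation_on_pseudo_is_error(self):
        feat = Feature("CDS", Location(((10, 100),), 1),
                       {"pseudo": [None], "translation": ["MK"]})
        findings = validate_pseudogenes(_one_feature_record(feat))
        assert any(f.rule_id == "PSEUDO001" and f.severity == "ERROR" for f in findings)

    def test_pseudo_with_note_only_is_clean(self):
        feat = Feature("CDS", Location(((10, 100),), 1),
                       {"pseudo": [None], "note": ["gyrA pseudogene"]})
        assert validate_pseudogenes(_one_feature_record(feat)) == []

    def test_artificial_location_needs_low_quality_prefix(self):
        feat = Feature("CDS", Location(((10, 100),), 1),
                       {"artificial_location": [None], "product": ["DNA gyrase"]})
        findings = validate_pseudogenes(_one_feature_record(feat))
        (f,) = [x for x in findings if x.rule_id == "PSEUDO004"]
        assert f.suggestion == "LOW-QUALITY PROTEIN: DNA gyrase"

    def test_low_quality_prefix_is_clean(self):
        feat = Feature("CDS", Location(((10, 100),), 1),
                       {"artificial_location": [None],
                        "product": ["LOW-QUALITY PROTEIN: DNA gyrase"]})
        assert validate_pseudogenes(_one_feature_record(feat)) == []

    def test_transcript_exception_requires_evidence(self):
        base = {"exception": ["annotated by transcript or proteomic data"],
                "product": ["x"]}
        bare = Feature("CDS", Location(((10, 100),), 1), dict(base))
        findings = validate_pseudogenes(_one_feature_record(bare))
        assert any(f.rule_id == "PSEUDO003" for f in findings)
        with_ev = Feature("CDS", Location(((10, 100),), 1),
                          dict(base, inference=["similar to AA sequence:INSD:X.1"]))
        assert all(f.rule_id != "PSEUDO003"
                   for f in validate_pseudogenes(_one_feature_record(with_ev)))

    def test_similarity_region_with_locus_tag_is_advisory(self):
        feat = Feature("misc_feature", Location(((10, 100),), 1),
                       {"note": ["region of similarity to RecA"],
                        "locus_tag": ["SYN_0001"]})
        findings = validate_pseudogenes(_one_feature_record(feat))
        assert [f.rule_id for f in findings] == ["PSEUDO005"]

    def test_pseudogene_qualifier_synonym_noted(self):
        feat = Feature("CDS", Location(((10, 100),), 1),
                       {"pseudogene": ["unprocessed"]})
        findings = validate_pseudogenes(_one_feature_record(feat))
        assert any(f.rule_id == "PSEUDO006" and f.severity == "INFO" for f in findings)


def _tagged(key, start, tag):
    return Feature(key, Location(((start, start + 90),), 1), {"locus_tag": [tag]})


class TestLocusTags:
    def test_clean_tags(self):
        rec = _one_feature_record(_tagged("gene", 10, "ECK_0001"))
        rec.replicons[0].features.append(_tagged("gene", 200, "ECK_0002"))
        assert validate_locus_tags(rec) == []

    def test_duplicate_on_distinct_loci_fails(self):
        rec = _one_feature_record(_tagged("gene", 10, "ECK_0001"))
        rec.replicons[0].features.append(_tagged("gene", 200, "ECK_0001"))
        assert any(f.rule_id == "LT001" for f in validate_locus_tags(rec))

    def test_shared_tag_on_gene_and_cds_of_same_locus_is_fine(self):
        gene = _tagged("gene", 10, "ECK_0001")
        cds = Feature("CDS", gene.location, {"locus_tag": ["ECK_0001"],
                                             "product": ["x"]})
        rec = _one_feature_record(gene)
        rec.replicons[0].features.append(cds)
        assert all(f.rule_id != "LT001" for f in validate_locus_tags(rec))

    def test_two_prefixes_fail(self):
        rec = _one_feature_record(_tagged("gene", 10, "ECK_0001"))
        rec.replicons[0].features.append(_tagged("gene", 200, "ABC_0002"))
        assert any(f.rule_id == "LT002" for f in validate_locus_tags(rec))

    @pytest.mark.parametrize("tag", ["ab_0001", "1BC_0001", "ECK_00_01", "ECK0001"])
    def test_bad_syntax_warns(self, tag):
        rec = _one_feature_record(_tagged("gene", 10, tag))
        assert any(f.rule_id == "LT003" for f in validate_locus_tags(rec))

    def test_missing_tag_warns(self):
        feat = Feature("tRNA", Location(((10, 86),), 1), {"product": ["tRNA-Ala"]})
        rec = _one_feature_record(feat)
        assert any(f.rule_id == "LT004" for f in validate_locus_tags(rec))


class TestStructure:
    def test_cds_without_gene_warns(self):
        feat = Feature("CDS", Location(((9, 108),), 1), {"product": ["x"]})
        findings = validate_structure(_one_feature_record(feat))
        assert any(f.rule_id == "STRUCT001" for f in findings)

    def test_translation_conflict_is_error(self):
        rep = Replicon("r", "AAATGAAATAAAAA")
        loc = Location(((2, 11),), 1)
        gene = Feature("gene", loc, {})
        cds = Feature("CDS", loc, {"translation": ["MR"], "product": ["x"]})
        rec = GenomeRecord(replicons=[Replicon("r", rep.sequence, features=[gene, cds])])
        findings = validate_structure(rec)
        assert any(f.rule_id == "STRUCT002" and f.severity == "ERROR" for f in findings)

    def test_matching_translation_is_clean(self):
        loc = Location(((2, 11),), 1)
        gene = Feature("gene", loc, {})
        cds = Feature("CDS", loc, {"translation": ["MK"], "product": ["x"]})
        rec = GenomeRecord(replicons=[Replicon("r", "AAATGAAATAAAAA", features=[gene, cds])])
        assert all(f.rule_id != "STRUCT002" for f in validate_structure(rec))

    def test_span_not_divisible_by_three(self):
        loc = Location(((9, 109),), 1)
        gene = Feature("gene", loc, {})
        cds = Feature("CDS", loc, {"product": ["x"]})
        rec = GenomeRecord(replicons=[Replicon("r", "A" * 200, features=[gene, cds])])
        assert any(f.rule_id == "STRUCT003" for f in validate_structure(rec))

    def test_partial_cds_exempt_from_frame_rule(self):
        loc = Location(((9, 109),), 1, partial5=True)
        gene = Feature("gene", loc, {})
        cds = Feature("CDS", loc, {"product": ["x"]})
        rec = GenomeRecord(replicons=[Replicon("r", "A" * 200, features=[gene, cds])])
        assert all(f.rule_id != "STRUCT003" for f in validate_structure(rec))

    def test_missing_metadata_reported(self):
        rec = _one_feature_record(Feature("gene", Location(((10, 100),), 1), {}))
        ids = {f.rule_id for f in validate_structure(rec)}
        assert {"STRUCT004", "STRUCT005"} <= ids


class TestRuleEngine:
    def test_gold_standard_is_silent_even_with_style_rules(self, gold_record):
        cfg = QCConfig(style_name_rules=True)
        assert lint_record(gold_record, cfg) == []

    def test_findings_multiset_invariant_under_feature_permutation(self):
        record, _ = generate(GenomeSpec(
            seed=13, length_bp=60_000, n_proteins=20,
            protein_len_dist=(100.0, 20.0, 40),
            planted_violations=("NAME001", "LT004", "PSEUDO002", "STRUCT001")))
        before = Counter((f.rule_id, f.feature_handle) for f in lint_record(record))
        rng = random.Random(0)
        for rep in record.replicons:
            rng.shuffle(rep.features)
        after = Counter((f.rule_id, f.feature_handle) for f in lint_record(record))
        assert before == after

    def test_every_emitted_rule_is_registered(self):
        record, _ = generate(GenomeSpec(
            seed=14, planted_violations=("NAME001", "EV001", "PSEUDO001", "LT001",
                                         "STRUCT002", "FMT001")))
        for f in lint_record(record):
            assert f.rule_id in RULE_CATALOG
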