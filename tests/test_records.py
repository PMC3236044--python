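"""Record model, coordinate conventions, flat-file round-trips, translation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from annotqc.records import (
    Feature,
    GenomeRecord,
    Location,
    ParseError,
    Replicon,
    TranslationError,
    InternalStopError,
    extract_feature_seq,
    location_to_genbank,
    parse_genbank,
    parse_gff3,
    translate_cds,
    write_feature_table,
    write_genbank,
    write_gff3,
)
from annotqc.synth import GenomeSpec, generate

TOY_GB = """LOCUS       toyrep                   100 bp    DNA     linear   BCT 01-JAN-2011
DEFINITION  toy record.
ACCESSION   toyrep
FEATURES             Location/Qualifiers
     source          1..100
                     /organism="Synthetica exemplaris"
     CDS             complement(join(10..30,40..60))
                     /product="demo protein"
     CDS             5..13
                     /pseudo
ORIGIN
        1 aaatgcccaa aaatgcccaa aaatgcccaa aaatgcccaa aaatgcccaa aaatgcccaa
       61 aaatgcccaa aaatgcccaa aaatgcccaa aaatgcccaa
//
"""


class TestParseGenbank:
    def test_complement_join_becomes_two_ascending_halfopen_segments(self):
        rec = parse_genbank(TOY_GB)
        feat = rec.replicons[0].features[0]
        assert feat.key == "CDS"
        assert feat.location.segments == ((9, 30), (39, 60))
        assert feat.location.strand == -1

    def test_flag_qualifier_has_no_value(self):
        rec = parse_genbank(TOY_GB)
        pseudo = rec.replicons[0].features[1]
        assert pseudo.qualifiers["pseudo"] == [None]
        assert pseudo.is_pseudo

    def test_source_feature_folds_into_organism(self):
        rec = parse_genbank(TOY_GB)
        assert rec.organism == "Synthetica exemplaris"
        assert all(f.key != "source" for f in rec.replicons[0].features)

    def test_unknown_feature_key_retained_with_info_finding(self):
        text = TOY_GB.replace("     CDS             5..13", "     frobnicator     5..13")
        rec = parse_genbank(text)
        keys = [f.key for f in rec.replicons[0].features]
        assert "frobnicator" in keys
        assert any(f.rule_id == "FMT001" and f.severity == "INFO"
                   for f in rec.parse_findings)

    def test_feature_beyond_linear_bounds_is_parse_error(self):
        text = TOY_GB.replace("5..13", "5..130")
        with pytest.raises(ParseError):
            parse_genbank(text)

    def test_empty_input_is_parse_error(self):
        with pytest.raises(ParseError):
            parse_genbank("no locus here\n")


class TestRoundTrips:
    @pytest.mark.parametrize("seed", range(8))
    def test_genbank_round_trip_identity(self, seed):
        record, _ = generate(GenomeSpec(seed=seed, length_bp=30_000, n_proteins=16,
                                        protein_len_dist=(100.0, 25.0, 40)))
        assert parse_genbank(write_genbank(record)) == record

    @pytest.mark.parametrize("seed", range(8))
    def test_gff3_round_trip_identity(self, seed):
        record, _ = generate(GenomeSpec(seed=seed + 100, length_bp=30_000, n_proteins=16,
                                        protein_len_dist=(100.0, 25.0, 40)))
        assert parse_gff3(write_gff3(record)) == record

    def test_gff3_round_trip_with_pseudo_and_cases(self):
        record, _ = generate(GenomeSpec(seed=4, length_bp=40_000, n_proteins=16,
                                        protein_len_dist=(100.0, 25.0, 40),
                                        pseudo_cases=("1", "3a", "3c", "3d", "4")))
        assert parse_gff3(write_gff3(record)) == record
        assert parse_genbank(write_genbank(record)) == record

    def test_gff3_merges_cds_parts_by_id(self):
        gff = (
            "##gff-version 3\n"
            "##sequence-region chr1 1 100\n"
            "chr1\tx\tCDS\t11\t30\t.\t-\t0\tID=c1;product=demo\n"
            "chr1\tx\tCDS\t40\t60\t.\t-\t0\tID=c1;product=demo\n"
        )
        rec = parse_gff3(gff)
        (feat,) = rec.replicons[0].features
        assert feat.location.segments == ((10, 30), (39, 60))
        assert feat.location.strand == -1

    def test_gff3_pseudo_attribute_maps_to_flag(self):
        gff = (
            "##gff-version 3\n"
            "##sequence-region chr1 1 100\n"
            "chr1\tx\tCDS\t11\t31\t.\t+\t0\tID=c1;pseudo=true\n"
        )
        rec = parse_gff3(gff)
        assert rec.replicons[0].features[0].is_pseudo

    def test_gff3_coordinate_beyond_region_is_parse_error(self):
        gff = (
            "##gff-version 3\n"
            "##sequence-region chr1 1 50\n"
            "chr1\tx\tgene\t11\t90\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(ParseError):
            parse_gff3(gff)

    def test_gff3_missing_version_directive_rejected(self):
        with pytest.raises(ParseError):
            parse_gff3("chr1\tx\tgene\t1\t10\t.\t+\t.\tID=g1\n")


class TestFeatureTable:
    def test_empty_replicon_emits_header_only(self):
        rec = GenomeRecord(replicons=[Replicon("r1", "ACGT" * 10)])
        assert write_feature_table(rec) == ">Feature r1\n"

    def test_partial5_forward_gets_left_angle_prefix(self):
        loc = Location(((4, 20),), 1, partial5=True)
        rec = GenomeRecord(replicons=[
            Replicon("r1", "A" * 30, features=[Feature("CDS", loc, {"product": ["x"]})])])
        lines = write_feature_table(rec).splitlines()
        assert lines[1] == "<5\t20\tCDS"

    def test_minus_strand_intervals_written_high_to_low(self):
        loc = Location(((9, 30), (39, 60)), -1)
        rec = GenomeRecord(replicons=[
            Replicon("r1", "A" * 100, features=[Feature("CDS", loc, {"pseudo": [None]})])])
        lines = write_feature_table(rec).splitlines()
        assert lines[1] == "60\t40\tCDS"
        assert lines[2] == "30\t10"
        assert lines[3] == "\t\t\tpseudo"


class TestExtraction:
    def test_forward_halfopen_extraction(self):
        rep = Replicon("r", "AAATGCCC")
        assert extract_feature_seq(rep, Location(((3, 6),), 1)) == "TGC"

    def test_reverse_is_reverse_complement(self):
        rep = Replicon("r", "AAATGCCC")
        assert extract_feature_seq(rep, Location(((3, 6),), -1)) == "GCA"

    def test_join_equals_per_base_oracle(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        rep = Replicon("r", seq)
        loc = Location(((10, 40), (60, 99)), -1)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        forward = [seq[i] for i in range(10, 40)] + [seq[i] for i in range(60, 99)]
        oracle = "".join(comp[b] for b in reversed(forward))
        assert extract_feature_seq(rep, loc) == oracle

    def test_circular_wrap(self):
        rep = Replicon("r", "AAACCC", topology="circular")
        loc = Location(((4, 6), (0, 2)), 1)
        assert extract_feature_seq(rep, loc) == "CCAA"

    def test_out_of_bounds_on_linear_is_error(self):
        rep = Replicon("r", "AAACCC")
        with pytest.raises(ParseError):
            extract_feature_seq(rep, Location(((4, 9),), 1))


class TestTranslation:
    @pytest.mark.parametrize("nt,expected", [
        ("ATGAAATAA", "MK"),
        ("GTGAAATAA", "MK"),   # alternative start rendered M
        ("TTGAAATAA", "MK"),
        ("ATGAANTAA", "MX"),   # ambiguity -> X
    ])
    def test_simple_cds(self, nt, expected):
        assert translate_cds(nt) == expected

    def test_internal_stop_reports_codon_index(self):
        with pytest.raises(InternalStopError) as err:
            translate_cds("ATGAAATAGAAATAA")
        assert err.value.codon_index == 2

    def test_length_not_multiple_of_three_rejected_when_complete(self):
        with pytest.raises(TranslationError):
            translate_cds("ATGAAAT")

    def test_partial5_keeps_literal_first_residue(self):
        # complete CDS renders GTG as M, partial 5' end does not
        assert translate_cds("GTGAAATAA", partial5=True)[0] == "V"

    def test_random_orfs_match_codon_lookup_oracle(self):
        from Bio.Data import CodonTable
        table = CodonTable.unambiguous_dna_by_id[11]
        lookup = dict(table.forward_table)
        sense = [c for c in lookup if c not in table.stop_codons]
        rng = np.random.default_rng(3)
        for _ in range(25):
            n_codons = int(rng.integers(2, 60))
            codons = [sense[i] for i in rng.integers(0, len(sense), n_codons)]
            nt = "".join(codons) + "TAA"
            expected = "".join(lookup[c] for c in codons)
            if codons[0] in table.start_codons:
                expected = "M" + expected[1:]
            assert translate_cds(nt) == expected


class TestLocationModel:
    def test_segment_order_and_bounds_validated(self):
        with pytest.raises(ValueError):
            Location(((5, 5),), 1)
        with pytest.raises(ValueError):
            Location((), 1)

    @given(st.integers(0, 10_000), st.integers(1, 500))
    @settings(derandomize=True, max_examples=60)
    def test_genbank_coordinate_conversion_is_involution(self, start, span):
        # internal 0-based half-open <-> rendered 1-based inclusive
        loc = Location(((start, start + span),), 1)
        rendered = location_to_genbank(loc)
        a, b = rendered.split("..")
        assert (int(a) - 1, int(b)) == loc.segments[0]

    def test_render_reverse_join(self):
        loc = Location(((9, 30), (39, 60)), -1)
        assert location_to_genbank(loc) == "complement(join(10..30,40..60))"

    def test_extract_translate_consistency(self, small_record):
        # extraction of a forward CDS equals the literal substring
        rep = small_record.replicons[0]
        for feat in rep.features:
            if feat.key != "CDS" or feat.location.strand != 1:
                continue
            (s, e), = feat.location.segments
            assert extract_feature_seq(rep, feat.location) == rep.sequence[s:e]
            break
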