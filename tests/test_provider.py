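"""Fixture generation, persistence and the provider interface contract."""

import json
import random

import pytest
from pyfaidx import Fasta

from hgvskit.provider import (
    FixtureProvider,
    LocusFixture,
    RecordInvariantError,
    SequenceRangeError,
    UnknownAccessionError,
    UnknownAlignmentMethodError,
    implied_transcript_seq,
    revcomp,
)
from hgvskit.synth import GenerationError, LocusConfig, demo_locus, generate_locus
from tests.conftest import random_locus_config


class TestGetSeq:
    def test_single_base_and_full_sequence_slices(self, demo_provider):
        contig = demo_provider.get_seq("CTG01.1")
        assert demo_provider.get_seq("CTG01.1", 1, 1) == contig[0]
        assert demo_provider.get_seq("CTG01.1", 1, len(contig)) == contig
        assert demo_provider.get_seq("CTG01.1", 848, 848) == "G"

    def test_inverted_and_out_of_range_slices_are_rejected(self, demo_provider):
        with pytest.raises(SequenceRangeError):
            demo_provider.get_seq("CTG01.1", 5, 4)
        with pytest.raises(SequenceRangeError):
            demo_provider.get_seq("TX01.1", 1, 10**6)
        with pytest.raises(SequenceRangeError):
            demo_provider.get_seq("TX01.1", 0, 5)

    def test_unknown_accession_is_a_lookup_error(self, demo_provider):
        with pytest.raises(UnknownAccessionError):
            demo_provider.get_seq("NOPE.1")

    def test_full_slice_equals_an_independent_fasta_read(self, tmp_path,
                                                         demo_fixture):
        demo_fixture.write(tmp_path / "fx")
        provider = FixtureProvider(tmp_path / "fx")
        fasta = Fasta(str(tmp_path / "fx" / "sequences.fa"))
        for ac in demo_fixture.sequences:
            assert provider.get_seq(ac) == str(fasta[ac][:]).upper()


class TestGetTranscript:
    def test_lookup_by_triple(self, demo_provider):
        rec = demo_provider.get_transcript("TX01.1", "CTG01.1", "splign")
        assert len(rec.exons) == 3 and rec.strand == -1

    def test_unknown_method_distinguished_from_unknown_transcript(self,
                                                                  demo_provider):
        with pytest.raises(UnknownAccessionError):
            demo_provider.get_transcript("TX99.1", "CTG01.1", "splign")
        with pytest.raises(UnknownAlignmentMethodError):
            demo_provider.get_transcript("TX01.1", "CTG01.1", "nosuch")

    def test_gene_and_protein_queries(self, demo_provider):
        recs = demo_provider.get_transcripts_for_gene("MCL1L")
        assert [r.tx_ac for r in recs] == ["TX01.1", "TX02.1"]
        assert demo_provider.get_protein_accession("TX01.1") == "PR01.1"
        assert demo_provider.get_alignment_methods("TX01.1") == \
            [("CTG01.1", "splign")]
        assert "seed=42" in demo_provider.get_data_version()


class TestFindTranscripts:
    def test_query_inside_an_exon_finds_the_transcript(self, demo_provider):
        hits = demo_provider.find_transcripts("CTG01.1", 800, 850)
        assert {r.tx_ac for r in hits} == {"TX01.1", "TX02.1"}

    def test_intergenic_query_is_empty(self, demo_provider):
        assert demo_provider.find_transcripts("CTG01.1", 1, 100) == []
        with pytest.raises(UnknownAccessionError):
            demo_provider.find_transcripts("NOPE.1", 1, 10)

    def test_per_base_sweep_matches_span_membership(self, locus_for_seed):
        """Sliding a 1-base window across the contig recovers exactly the
        transcripts whose span covers each base (exhaustive sweep oracle)."""
        fx = locus_for_seed(5)
        provider = FixtureProvider(fx)
        contig = fx.sequences[fx.records[0].ref_ac]
        spans = {(r.tx_ac, r.aln_method): (r.g_start, r.g_end) for r in fx.records}
        seen = set()
        for g in range(1, len(contig) + 1, 7):
            hits = provider.find_transcripts(fx.records[0].ref_ac, g, g)
            expected = {key for key, (s, e) in spans.items() if s <= g <= e}
            assert {(r.tx_ac, r.aln_method) for r in hits} == expected
            seen |= expected
        assert seen == set(spans)  # the sweep covers every transcript


class TestGenerator:
    def test_same_seed_gives_byte_identical_fixtures(self, tmp_path):
        cfg = LocusConfig(n_transcripts=2, indels=(("D", 3),))
        a, b = generate_locus(cfg, seed=42), generate_locus(cfg, seed=42)
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for name in ("sequences.fa", "transcripts.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()
        assert generate_locus(cfg, seed=43).sequences != a.sequences

    def test_d_segment_shortens_the_transcript(self):
        """One 3-base genome-only segment: the transcript is 3 bases shorter
        than its spliced genomic exons."""
        cfg = LocusConfig(indels=(("D", 3),), strand="+")
        fx = generate_locus(cfg, seed=1)
        rec = fx.records[0]
        spliced = sum(e.g_length for e in rec.exons)
        assert len(fx.sequences[rec.tx_ac]) == spliced - 3

    def test_i_segment_lengthens_the_transcript(self):
        cfg = LocusConfig(indels=(("I", 2),), strand="+")
        fx = generate_locus(cfg, seed=1)
        rec = fx.records[0]
        spliced = sum(e.g_length for e in rec.exons)
        assert len(fx.sequences[rec.tx_ac]) == spliced + 2

    def test_minus_strand_transcript_is_reverse_complement_of_spliced_exons(self):
        """Independent reverse-complement check on a gapless minus-strand
        transcript (no package splicing code involved)."""
        cfg = LocusConfig(strand="-")
        fx = generate_locus(cfg, seed=3)
        rec = fx.records[0]
        assert all(len(e.segments) == 1 for e in rec.exons)
        contig = fx.sequences[rec.ref_ac]
        spliced = "".join(contig[e.g_start - 1:e.g_end] for e in rec.exons)
        assert fx.sequences[rec.tx_ac] == revcomp(spliced)

    def test_unsatisfiable_configs_are_rejected(self):
        with pytest.raises(GenerationError):
            LocusConfig(exons_per_tx=0)
        with pytest.raises(GenerationError):
            LocusConfig(cds_start_exon=5, exons_per_tx=3)
        with pytest.raises(GenerationError):
            LocusConfig(indels=(("X", 3),))
        with pytest.raises(GenerationError):
            LocusConfig(exon_length=(4, 5), indels=(("D", 8),))

    @pytest.mark.parametrize("seed", range(25))
    def test_random_fixtures_are_self_consistent(self, seed):
        """Record invariants and splice-consistency hold across random
        configurations (strand mix, late CDS start, indels, boundary slides)."""
        rng = random.Random(seed)
        fx = generate_locus(random_locus_config(rng), seed=seed)
        fx.validate()  # raises on any violation
        for rec in fx.records:
            tx = fx.sequences[rec.tx_ac]
            assert implied_transcript_seq(rec, fx.sequences[rec.ref_ac], tx) == tx

    def test_alt_alignment_records_imply_the_same_transcript(self):
        cfg = LocusConfig(alt_aln_shift=2)
        fx = generate_locus(cfg, seed=9)
        methods = {r.aln_method for r in fx.records}
        assert methods == {"splign", "blat"}
        a, b = fx.records
        assert a.tx_ac == b.tx_ac
        assert [e.g_start for e in a.exons] != [e.g_start for e in b.exons] or \
            [e.g_end for e in a.exons] != [e.g_end for e in b.exons]


class TestPersistenceAndConformance:
    def test_round_trip_through_disk(self, tmp_path, demo_fixture):
        demo_fixture.write(tmp_path / "fx")
        back = LocusFixture.read(tmp_path / "fx")
        assert back.sequences == demo_fixture.sequences
        assert back.records == demo_fixture.records
        back.validate()

    def test_corrupted_record_is_caught(self, demo_fixture, tmp_path):
        demo_fixture.write(tmp_path / "fx")
        doc = json.loads((tmp_path / "fx" / "transcripts.json").read_text())
        doc["transcripts"][0]["exons"][0]["g_end"] += 1  # break segment sums
        (tmp_path / "fx" / "transcripts.json").write_text(json.dumps(doc))
        broken = LocusFixture.read(tmp_path / "fx")
        with pytest.raises(RecordInvariantError):
            broken.validate()

    def test_second_independent_reader_agrees(self, tmp_path, demo_fixture):
        """A from-scratch reader (pyfaidx + raw json) must answer the core
        queries identically to FixtureProvider — interface conformance."""
        d = tmp_path / "fx"
        demo_fixture.write(d)
        provider = FixtureProvider(d)

        fasta = Fasta(str(d / "sequences.fa"))
        doc = json.loads((d / "transcripts.json").read_text())
        for t in doc["transcripts"]:
            rec = provider.get_transcript(t["tx_ac"], t["ref_ac"], t["aln_method"])
            assert rec.strand == t["strand"]
            assert rec.cds_start_n == t["cds_start_n"]
            assert [(e.g_start, e.g_end) for e in rec.exons] == \
                [(e["g_start"], e["g_end"]) for e in t["exons"]]
            assert provider.get_seq(t["tx_ac"]) == str(fasta[t["tx_ac"]][:]).upper()

    def test_repeated_queries_return_equal_results(self, demo_provider):
        q = lambda: (demo_provider.get_seq("TX01.1", 5, 25),
                     demo_provider.get_transcript("TX01.1"),
                     demo_provider.find_transcripts("CTG01.1", 840, 860))
        assert q() == q()
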