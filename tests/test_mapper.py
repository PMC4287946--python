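"""Coordinate projection: alignment maps, indel clamping, strand handling,
CDS arithmetic, protein inference and transcript liftover."""

import random
import warnings

import pytest

from hgvskit import models as m
from hgvskit.formatter import format_hgvs
from hgvskit.mapper import (
    AlignmentBuildError,
    AlignmentMap,
    BoundaryWarning,
    GapWarning,
    MappingRangeError,
    UnsupportedOperationError,
    VariantMapper,
    build_alignment_map,
    c_pos_to_n,
    n_pos_to_c,
)
from hgvskit.parser import parse
from hgvskit.provider import Exon, FixtureProvider, revcomp
from hgvskit.synth import LocusConfig, generate_locus
from tests._oracles import (
    apply_nt_edit,
    per_base_table,
    protein_expectation,
    translate_all,
)
from tests.conftest import make_record, random_locus_config


def _n(base, offset=0):
    return m.BaseOffsetPosition(base, offset, m.Datum.SEQ_START)


class TestAlignmentMapStructure:
    def test_three_gapless_exons_give_five_blocks(self, toy1):
        amap = AlignmentMap(toy1)
        assert [b.kind for b in amap.blocks] == ["M", "intron", "M", "intron", "M"]
        assert amap.tx_length == 300

    def test_exon_with_discrepancy_contributes_three_blocks(self):
        rec = make_record([(101, 200, [("M", 100)]),
                           (301, 403, [("M", 40), ("D", 3), ("M", 60)])])
        kinds = [b.kind for b in AlignmentMap(rec).blocks]
        assert kinds == ["M", "intron", "M", "D", "M"]

    def test_inconsistent_record_raises_a_build_error_naming_the_exon(self):
        rec = make_record([(101, 199, [("M", 100)])])
        with pytest.raises(AlignmentBuildError, match="exon 1"):
            build_alignment_map(rec)


class TestPositionProjection:
    def test_exonic_positions_project_exactly(self, toy1):
        amap = AlignmentMap(toy1)
        assert amap.g_to_n(150).pos == _n(50)
        assert not amap.g_to_n(150).gap_flag
        assert amap.n_to_g(50).pos.base == 150

    def test_intron_midpoint_ties_to_the_5prime_boundary(self, toy1):
        amap = AlignmentMap(toy1)
        # intron 1 is g.201-300 (100 bases); g.250 is 50 from the left exon
        # and 51 from the right: nearest is n.100, offset +50
        assert amap.g_to_n(250).pos == _n(100, 50)
        # one base right of the midpoint flips to the 3' anchor
        assert amap.g_to_n(251).pos == _n(101, -50)
        # and n.100+50 projects back to g.250
        assert amap.n_to_g(100, 50).pos.base == 250
        assert amap.n_to_g(101, -50).pos.base == 251

    def test_genome_only_bases_clamp_with_gap_flag(self):
        """Positions inside a D discrepancy have no transcript image; they
        clamp to the transcript base immediately 5' and are flagged."""
        rec = make_record([(101, 200, [("M", 100)]),
                           (301, 403, [("M", 40), ("D", 3), ("M", 60)])])
        amap = AlignmentMap(rec)
        r = amap.g_to_n(342)  # second base of the D run
        assert (r.pos, r.gap_flag) == (_n(140), True)

    def test_transcript_only_bases_clamp_with_gap_flag(self):
        rec = make_record([(101, 200, [("M", 40), ("I", 2), ("M", 60)])])
        amap = AlignmentMap(rec)
        for n in (41, 42):
            r = amap.n_to_g(n)
            assert r.gap_flag and r.pos.base == 140

    def test_out_of_span_positions_raise_range_errors(self, toy1):
        amap = AlignmentMap(toy1)
        with pytest.raises(MappingRangeError):
            amap.g_to_n(100)
        with pytest.raises(MappingRangeError):
            amap.g_to_n(601)
        with pytest.raises(MappingRangeError):
            amap.n_to_g(0)
        with pytest.raises(MappingRangeError):
            amap.n_to_g(301)


class TestCdsArithmetic:
    def test_boundary_cases_skip_position_zero(self, toy1):
        assert n_pos_to_c(toy1, _n(21)).base == 1
        assert n_pos_to_c(toy1, _n(20)).base == -1
        assert n_pos_to_c(toy1, _n(50)).base == 30
        star3 = n_pos_to_c(toy1, _n(263))
        assert (star3.base, star3.datum) == (3, m.Datum.CDS_END)

    def test_offsets_pass_through(self, toy1):
        p = n_pos_to_c(toy1, _n(100, 50))
        assert (p.base, p.offset) == (80, 50)
        back = c_pos_to_n(toy1, p)
        assert (back.base, back.offset) == (100, 50)

    def test_exact_inverse_over_the_whole_transcript(self, toy1):
        for n in range(1, toy1.tx_length + 1):
            assert c_pos_to_n(toy1, n_pos_to_c(toy1, _n(n))).base == n

    def test_non_coding_transcript_is_unsupported(self):
        rec = make_record([(101, 200, [("M", 100)])])
        with pytest.raises(UnsupportedOperationError):
            n_pos_to_c(rec, _n(5))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_mapper_agrees_with_the_per_base_walk(self, seed):
        """The block-arithmetic mapper must agree with a brute-force walk of
        the alignment at every genomic and transcript base, on fixtures that
        exercise both strands, late CDS starts and D/I discrepancies."""
        rng = random.Random(seed)
        fx = generate_locus(random_locus_config(rng), seed=seed)
        for rec in fx.records:
            amap = AlignmentMap(rec, tx_len=len(fx.sequences[rec.tx_ac]))
            g2n, n2g = per_base_table(rec)
            for g, (nb, off, gap) in g2n.items():
                got = amap.g_to_n(g)
                assert (got.pos.base, got.pos.offset, got.gap_flag) == \
                    (nb, off, gap), f"seed {seed} {rec.tx_ac} g.{g}"
                if not gap and off:
                    back = amap.n_to_g(nb, off)
                    assert back.pos.base == g
            for n, (g, gap) in n2g.items():
                got = amap.n_to_g(n)
                assert (got.pos.base, got.gap_flag) == (g, gap), \
                    f"seed {seed} {rec.tx_ac} n.{n}"

    @pytest.mark.parametrize("seed", range(8))
    def test_bijective_on_matched_blocks(self, seed):
        rng = random.Random(seed)
        fx = generate_locus(random_locus_config(rng), seed=seed)
        for rec in fx.records:
            amap = AlignmentMap(rec)
            _, n2g = per_base_table(rec)
            for n, (g, gap) in n2g.items():
                if not gap:
                    assert amap.g_to_n(g).pos == _n(n)

    def test_strand_symmetry_via_mirrored_fixture(self):
        """Mapping on a minus-strand transcript equals mapping on its
        plus-strand mirror after reflecting genomic coordinates."""
        rec = make_record(
            [(101, 200, [("M", 40), ("D", 3), ("M", 57)]),
             (301, 400, [("M", 60), ("I", 2), ("M", 40)]),
             (501, 600, [("M", 100)])],
            strand=-1)
        L = 700  # mirror within a contig of this length: g -> L + 1 - g
        mirrored = make_record(
            [(L + 1 - e.g_end, L + 1 - e.g_start,
              [(s.op, s.length) for s in reversed(e.segments)])
             for e in reversed(rec.exons)],
            strand=1)
        minus = AlignmentMap(rec)
        plus = AlignmentMap(mirrored)
        assert minus.tx_length == plus.tx_length
        for g in range(rec.g_start, rec.g_end + 1):
            a = minus.g_to_n(g)
            b = plus.g_to_n(L + 1 - g)
            assert (a.pos, a.gap_flag) == (b.pos, b.gap_flag), f"g.{g}"


class TestVariantProjection:
    def test_exonic_c_to_g_and_back(self, demo_provider):
        vm = VariantMapper(demo_provider)
        v = parse("TX02.1:c.281C>T")
        vg = vm.c_to_g(v)
        assert format_hgvs(vg) == "CTG01.1:g.848G>A"
        assert vm.g_to_c(vg, "TX02.1") == v

    def test_intronic_variant_projects_through_the_alignment(self, demo_provider):
        vm = VariantMapper(demo_provider)
        v = parse("TX01.1:c.688+403C>T")
        assert format_hgvs(vm.c_to_g(v)) == "CTG01.1:g.848G>A"

    def test_minus_strand_reverse_complements_the_edit(self, demo_provider):
        vm = VariantMapper(demo_provider)
        v = parse("TX02.1:c.278_280delGTTinsAA")
        vg = vm.c_to_g(v)
        assert vg.posedit.edit == m.NARefAlt(revcomp("GTT"), revcomp("AA"))
        assert vg.posedit.pos.start.base < vg.posedit.pos.end.base

    def test_plus_strand_round_trip_on_random_exonic_substitutions(self):
        fx = generate_locus(LocusConfig(strand="+"), seed=21)
        rec = fx.records[0]
        provider = FixtureProvider(fx)
        vm = VariantMapper(provider)
        rng = random.Random(0)
        tx = fx.sequences[rec.tx_ac]
        for _ in range(50):
            npos = rng.randint(rec.cds_start_n, rec.cds_end_n)
            ref = tx[npos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            c = n_pos_to_c(rec, _n(npos))
            v = m.SequenceVariant(
                ac=rec.tx_ac, type=m.SequenceType.c,
                posedit=m.PosEdit(m.Interval.point(c), m.NARefAlt(ref, alt)))
            assert vm.g_to_c(vm.c_to_g(v), rec.tx_ac) == v

    def test_gap_clamp_surfaces_as_a_warning(self):
        fx = generate_locus(LocusConfig(indels=(("I", 2),), strand="+"), seed=2)
        rec = fx.records[0]
        vm = VariantMapper(FixtureProvider(fx))
        # find a transcript base inside the I discrepancy
        _, n2g = per_base_table(rec)
        n_gap = next(n for n, (_, gap) in n2g.items() if gap)
        tx = fx.sequences[rec.tx_ac]
        v = m.SequenceVariant(
            ac=rec.tx_ac, type=m.SequenceType.n,
            posedit=m.PosEdit(m.Interval.point(_n(n_gap)),
                              m.NARefAlt(tx[n_gap - 1], "A" if tx[n_gap - 1] != "A" else "C")))
        with pytest.warns(GapWarning):
            vm.n_to_g(v)

    def test_boundary_spanning_edit_maps_with_a_warning(self, demo_provider):
        vm = VariantMapper(demo_provider)
        # TX01.1 exon 2 ends at c.688; delete across the splice boundary
        v = parse("CTG01.1:g.1249_1253del")
        with pytest.warns(BoundaryWarning):
            out = vm.g_to_c(v, "TX01.1")
        assert out.posedit.pos.start.offset != 0 or out.posedit.pos.end.offset != 0


class TestProteinInference:
    def _cvar(self, rec, c_start, c_end, edit):
        iv = m.Interval(m.BaseOffsetPosition(c_start), m.BaseOffsetPosition(c_end))
        return m.SequenceVariant(ac=rec.tx_ac, type=m.SequenceType.c,
                                 posedit=m.PosEdit(iv, edit))

    def test_fixed_codon_examples(self):
        """ATG GCT AAA TGA: c.4G>T -> Ala2Ser; c.6T>C synonymous; c.4del
        frameshift at residue 2 (expectations from hand translation)."""
        # a tiny in-memory fixture with the exact CDS
        from hgvskit.provider import LocusFixture
        cds = "ATGGCTAAATGA"
        tx = "GG" + cds + "GTTACCA"
        contig = "AAAA" + tx + "TTTT"
        rec2 = make_record([(5, 4 + len(tx), [("M", len(tx))])],
                           cds=(3, 14), tx_ac="TXF.1", ref_ac="CTGF.1",
                           pro_ac="PRF.1")
        fx2 = LocusFixture(sequences={"CTGF.1": contig, "TXF.1": tx},
                           records=(rec2,))
        fx2.validate()
        vm = VariantMapper(FixtureProvider(fx2))
        v = self._cvar(rec2, 4, 4, m.NARefAlt("G", "T"))
        assert format_hgvs(vm.c_to_p(v)) == "PRF.1:p.(Ala2Ser)"
        v = self._cvar(rec2, 6, 6, m.NARefAlt("T", "C"))
        assert format_hgvs(vm.c_to_p(v)) == "PRF.1:p.(=)"
        v = self._cvar(rec2, 4, 4, m.NARefAlt("G", None))
        out = vm.c_to_p(v)
        assert isinstance(out.posedit.edit, m.AAFs)
        assert out.posedit.pos.start.base == 2
        v = self._cvar(rec2, 7, 7, m.NARefAlt("A", "T"))  # AAA -> TAA stop
        assert format_hgvs(vm.c_to_p(v)) == "PRF.1:p.(Lys3Ter)"

    def test_utr_and_boundary_positions_are_unsupported(self, demo_provider):
        vm = VariantMapper(demo_provider)
        with pytest.raises(UnsupportedOperationError, match="UTR"):
            vm.c_to_p(parse("TX02.1:c.-5A>T"))
        with pytest.raises(UnsupportedOperationError, match="boundary"):
            vm.c_to_p(parse("TX01.1:c.688_688+1delCGinsTT"))

    def test_deep_intronic_variant_infers_no_protein_change(self, demo_provider):
        vm = VariantMapper(demo_provider)
        out = vm.c_to_p(parse("TX01.1:c.688+403C>T"))
        assert format_hgvs(out) == "PR01.1:p.(=)"

    @pytest.mark.parametrize("seed", range(4))
    def test_translate_and_diff_oracle_agreement(self, seed):
        """Protein inference agrees with an independent translate-and-diff
        classification over random exonic CDS edits of every class."""
        rng = random.Random(1000 + seed)
        fx = generate_locus(random_locus_config(rng, coding_heavy=True),
                            seed=1000 + seed)
        rec = fx.records[0]
        vm = VariantMapper(FixtureProvider(fx))
        counts = run_protein_oracle(vm, rec, fx.sequences[rec.tx_ac], rng, 250)
        assert counts["identity"] > 0 and counts["sub"] > 0
        assert counts["fs"] > 0 and counts["inframe"] > 0


def run_protein_oracle(vm, rec, tx_seq, rng, n_cases) -> dict:
    """Generate random exonic CDS edits, run c_to_p, and verify every result
    against the translate-and-diff oracle.  Returns per-class counts."""
    cs, ce = rec.cds_start_n, rec.cds_end_n
    cds_len = ce - cs + 1
    region = tx_seq[cs - 1:]
    ref_aa = translate_all(region[:cds_len])
    counts = {"identity": 0, "sub": 0, "fs": 0, "inframe": 0}
    for _ in range(n_cases):
        kind = rng.choice(["sub", "sub", "sub", "del1", "del2", "del3",
                           "ins1", "ins3", "delins", "dup"])
        if kind == "delins":
            c1 = rng.randint(1, cds_len - 4)
            c2 = c1 + rng.randint(1, 4)
            alt = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            edit = m.NARefAlt(region[c1 - 1:c2], alt)
            expected_alt = apply_nt_edit(region, c1, c2, "delins", alt)
        elif kind == "sub":
            c1 = rng.randint(1, cds_len)
            c2 = c1
            ref = region[c1 - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            edit = m.NARefAlt(ref, alt)
            expected_alt = apply_nt_edit(region, c1, c2, "sub", alt)
        elif kind.startswith("del"):
            ln = int(kind[3])
            c1 = rng.randint(1, cds_len - ln + 1)
            c2 = c1 + ln - 1
            edit = m.NARefAlt(region[c1 - 1:c2], None)
            expected_alt = apply_nt_edit(region, c1, c2, "del")
        elif kind.startswith("ins"):
            ln = int(kind[3])
            c1 = rng.randint(1, cds_len - 1)
            c2 = c1 + 1
            ins = "".join(rng.choice("ACGT") for _ in range(ln))
            edit = m.NARefAlt(None, ins)
            expected_alt = apply_nt_edit(region, c1, c2, "ins", ins)
        else:  # dup
            c1 = rng.randint(1, cds_len - 3)
            c2 = c1 + rng.choice([0, 2])  # 1- or 3-base duplication
            edit = m.Dup(region[c1 - 1:c2])
            expected_alt = apply_nt_edit(region, c1, c2, "dup")

        iv = m.Interval(m.BaseOffsetPosition(c1), m.BaseOffsetPosition(c2))
        var = m.SequenceVariant(ac=rec.tx_ac, type=m.SequenceType.c,
                                posedit=m.PosEdit(iv, edit))
        out = vm.c_to_p(var)
        alt_aa = translate_all(expected_alt)
        exp = protein_expectation(ref_aa, alt_aa)
        _check_protein_result(out, exp, ref_aa, alt_aa, counts)
    return counts


def _check_protein_result(out, exp, ref_aa, alt_aa, counts) -> None:
    pe = out.posedit
    assert pe.inferred
    edit = pe.edit
    if exp.get("identical"):
        assert isinstance(edit, m.AAIdentity), (exp, str(out))
        counts["identity"] += 1
        return
    i = exp["first_diff"]
    if isinstance(edit, m.AASub):
        assert pe.pos.start.base == i
        assert m.AA3_TO_AA1[edit.ref] == exp["ref_res"]
        assert m.AA3_TO_AA1[edit.alt] == exp["alt_res"]
        counts["sub"] += 1
        return
    if isinstance(edit, m.AAFs):
        assert pe.pos.start.base == i, (str(out), exp)
        assert m.AA3_TO_AA1[pe.pos.start.aa] == exp["ref_res"]
        if edit.terminus is not None:
            assert alt_aa[i - 1 + edit.terminus - 1] == "*"
            assert "*" not in alt_aa[i - 1:i - 1 + edit.terminus - 1]
        else:
            assert "*" not in alt_aa[i - 1:]
        counts["fs"] += 1
        return
    assert isinstance(edit, m.AADelIns), str(out)
    # reconstruct the alt translation from the protein edit
    p1, p2 = pe.pos.start.base, pe.pos.end.base
    alt_run = "" if edit.alt is None else "".join(
        m.AA3_TO_AA1[edit.alt[k:k + 3]] for k in range(0, len(edit.alt), 3))
    if edit.deleted:
        rebuilt = ref_aa[:p1 - 1] + alt_run + ref_aa[p2:]
    else:  # insertion between p1 and p2
        rebuilt = ref_aa[:p1] + alt_run + ref_aa[p1:]
    assert rebuilt == alt_aa, (str(out), ref_aa, alt_aa)
    counts["inframe"] += 1


class TestLiftover:
    def test_two_transcript_workflow_produces_five_representations(
            self, demo_provider):
        """The end-to-end workflow: c. source, genomic projection, liftover
        to the sibling transcript, and the two inferred protein changes."""
        vm = VariantMapper(demo_provider)
        v1 = parse("TX01.1:c.688+403C>T")
        vg = vm.c_to_g(v1)
        v2 = vm.liftover(v1, "TX02.1")
        p1 = vm.c_to_p(v1)
        p2 = vm.c_to_p(v2)
        rendered = {format_hgvs(x) for x in (v1, vg, v2, p1, p2)}
        assert rendered == {
            "TX01.1:c.688+403C>T",
            "CTG01.1:g.848G>A",
            "TX02.1:c.281C>T",
            "PR01.1:p.(=)",
            "PR02.1:p.(Ser94Phe)",
        }

    def test_liftover_to_the_same_transcript_is_identity(self, demo_provider):
        vm = VariantMapper(demo_provider)
        v = parse("TX02.1:c.281C>T")
        assert vm.liftover(v, "TX02.1") == v

    def test_liftover_between_alignment_methods(self):
        """With a 2-base exon-boundary slide between two alignments of the
        same transcript, boundary-adjacent variants change representation
        while interior variants do not."""
        fx = generate_locus(LocusConfig(alt_aln_shift=2, strand="+"), seed=9)
        provider = FixtureProvider(fx)
        vm = VariantMapper(provider)
        a, b = fx.records
        tx = fx.sequences[a.tx_ac]
        # locate the slid boundary (first exon whose end differs)
        j = next(k for k in range(len(a.exons))
                 if a.exons[k].g_end != b.exons[k].g_end)
        g_boundary = a.exons[j].g_end  # exonic under A; B's exon extends past
        amap_a = AlignmentMap(a)
        n_interior = amap_a.g_to_n(a.exons[j].g_end - 10).pos.base
        n_edge = amap_a.g_to_n(g_boundary).pos.base

        def cvar(npos, offset=0):
            cpos = n_pos_to_c(a, _n(npos, offset))
            ref = tx[npos - 1] if offset == 0 else "A"
            alt = "A" if ref != "A" else "G"
            return m.SequenceVariant(
                ac=a.tx_ac, type=m.SequenceType.c,
                posedit=m.PosEdit(m.Interval.point(cpos), m.NARefAlt(ref, alt)))

        interior = cvar(n_interior)
        assert vm.liftover(interior, a.tx_ac, from_method="splign",
                           to_method="blat") == interior
        # the first intron base under alignment A is exonic under B
        edge = cvar(n_edge, offset=1)
        lifted = vm.liftover(edge, a.tx_ac, from_method="splign",
                             to_method="blat")
        assert lifted != edge
        assert lifted.posedit.pos.start.offset == 0

    def test_liftover_requires_a_shared_reference(self, demo_provider):
        vm = VariantMapper(demo_provider)
        from hgvskit.mapper import HgvsMapperError
        from hgvskit.provider import UnknownAccessionError
        with pytest.raises((HgvsMapperError, UnknownAccessionError)):
            vm.liftover(parse("TX01.1:c.10A>T"), "TX99.1")
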