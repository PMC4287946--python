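"""Synthetic-locus generation.

Real transcript archives supply the exon structures, alignments and
sequences that variant mapping needs.  This module fabricates loci with the
same structural features instead, so the whole mapping/validation stack can
be exercised hermetically and deterministically: multi-exon transcripts on
either strand, a CDS that may start after exon 1, genome-transcript
alignment indels (D = genome-only, I = transcript-only segments), and a
second alignment method whose exon boundaries slide by a few bases — the
kind of discrepancy two alignment programs (e.g. Splign and BLAT) produce
for the same transcript.  Boundary slides are made biologically coherent by
planting a short sequence repeat at the intron boundary, which is exactly
what makes real alignments ambiguous there.

Generated CDSs always begin with ATG, end with a stop codon and contain no
internal stop, so protein-consequence inference is well-defined on every
fixture.  ``demo_locus`` builds a fixed two-transcript minus-strand locus
with the structure that makes cross-transcript projection interesting (the
MCL1 gene is a well-known real instance): a variant deep in one
transcript's intron is exonic — and coding — in a sibling transcript that
has an extra exon there.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from . import models as m_
from .provider import (
    AlignmentSegment,
    Exon,
    LocusFixture,
    RecordInvariantError,
    TranscriptRecord,
)

__all__ = ["LocusConfig", "GenerationError", "generate_locus", "demo_locus",
           "random_variant", "DEMO_CONTIG", "DEMO_TX1", "DEMO_TX2"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_SENSE_CODONS = [a + b + c
                 for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in ("TAA", "TAG", "TGA")]
_STOPS = ("TAA", "TAG", "TGA")


class GenerationError(ValueError):
    """The requested locus configuration is unsatisfiable."""


@dataclass(frozen=True)
class LocusConfig:
    """Tunable shape of a generated locus.

    ``indels`` lists (op, length) alignment discrepancies, each placed in
    the interior of a randomly chosen exon of every transcript; op 'D'
    makes the exon span ``length`` more genomic bases than transcript
    bases, 'I' the reverse.  ``alt_aln_shift`` > 0 adds a second alignment
    record per transcript (method ``alt_aln_method``) whose chosen intron
    boundary slides 3' by that many bases.
    """

    n_transcripts: int = 1
    exons_per_tx: int = 3
    exon_length: Tuple[int, int] = (60, 120)
    intron_length: Tuple[int, int] = (60, 160)
    strand: str = "random"          # '+', '-' or 'random'
    indels: Tuple[Tuple[str, int], ...] = ()
    cds_start_exon: int = 1          # transcript-order exon containing the CDS start
    utr_margin: int = 10             # min bases kept as UTR at each transcript end
    alt_aln_shift: int = 0
    aln_method: str = "splign"
    alt_aln_method: str = "blat"
    ref_ac: str = "CTG01.1"
    gene_prefix: str = "GENE"
    flank: int = 50                  # intergenic bases before/between/after loci

    def __post_init__(self) -> None:
        if self.n_transcripts < 1 or self.exons_per_tx < 1:
            raise GenerationError("need at least one transcript and one exon")
        if self.cds_start_exon > self.exons_per_tx:
            raise GenerationError(
                f"cds_start_exon {self.cds_start_exon} exceeds exon count "
                f"{self.exons_per_tx}")
        for name in ("exon_length", "intron_length"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise GenerationError(f"bad {name} range ({lo}, {hi})")
        for op, ln in self.indels:
            if op not in ("D", "I") or ln < 1:
                raise GenerationError(f"bad indel spec ({op!r}, {ln})")
        if self.strand not in ("+", "-", "random"):
            raise GenerationError(f"bad strand {self.strand!r}")
        if self.alt_aln_shift and self.exons_per_tx < 2:
            raise GenerationError("a boundary slide needs at least two exons")
        min_exon = self.exon_length[0]
        edge = max(2, self.alt_aln_shift + 1)
        needed = 2 * edge + max([ln for op, ln in self.indels] or [0])
        if self.indels and min_exon < needed:
            raise GenerationError(
                f"exons of length >= {needed} are required to hold the "
                "requested indels in their interior")


def _rand_seq(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def _build_exon_segments(rng: random.Random, tx_side_len: int,
                         indel: Optional[Tuple[str, int]],
                         min_edge: int = 2) -> Tuple[AlignmentSegment, ...]:
    """Segments for one exon, placing at most one indel in its interior.

    ``min_edge`` keeps a matched run of at least that many bases at each
    exon edge (a boundary slide must never touch a discrepancy segment).
    """
    if indel is None:
        return (AlignmentSegment("M", tx_side_len),)
    op, ln = indel
    a = rng.randint(min_edge, tx_side_len - min_edge)
    b = tx_side_len - a
    return (AlignmentSegment("M", a), AlignmentSegment(op, ln), AlignmentSegment("M", b))


def generate_locus(config: LocusConfig = LocusConfig(), seed: int = 0) -> LocusFixture:
    """Build a deterministic synthetic locus for the given configuration.

    The same (config, seed) pair always yields a byte-identical fixture.
    Every emitted record satisfies the transcript-record invariants, and the
    fixture as a whole is self-consistent (splicing each alignment against
    the contig reproduces the stored transcript sequence exactly).
    """
    rng = random.Random(seed)
    contig: List[str] = []
    records: List[TranscriptRecord] = []
    sequences: Dict[str, str] = {}

    def emit_random(n: int) -> None:
        contig.extend(_rand_seq(rng, n))

    emit_random(config.flank)
    for t in range(1, config.n_transcripts + 1):
        tx_ac = f"TX{t:02d}.1"
        strand = (rng.choice((1, -1)) if config.strand == "random"
                  else (1 if config.strand == "+" else -1))

        # --- structure: per-exon transcript-side lengths and segments -----
        n_ex = config.exons_per_tx
        tx_side = [rng.randint(*config.exon_length) for _ in range(n_ex)]
        indel_exon: Dict[int, Tuple[str, int]] = {}
        for op, ln in config.indels:
            candidates = [i for i in range(n_ex) if i not in indel_exon]
            if not candidates:
                raise GenerationError("more indels than exons")
            indel_exon[rng.choice(candidates)] = (op, ln)
        seg_lists = [
            _build_exon_segments(rng, tx_side[i], indel_exon.get(i),
                                 min_edge=max(2, config.alt_aln_shift + 1))
            for i in range(n_ex)
        ]
        # transcript-order exon list; genomic-ascending is its reverse on '-'
        tx_order = list(range(n_ex))
        g_order = tx_order if strand == 1 else tx_order[::-1]

        shift = config.alt_aln_shift
        intron_lens = [rng.randint(*config.intron_length) for _ in range(n_ex - 1)]
        slide_intron = rng.randrange(n_ex - 1) if (shift and n_ex > 1) else None
        if slide_intron is not None and intron_lens[slide_intron] <= shift + 2:
            intron_lens[slide_intron] = shift + 3

        # --- genomic placement (ascending) --------------------------------
        g_exons: List[Tuple[int, int, Tuple[AlignmentSegment, ...]]] = []
        cursor = len(contig) + 1  # 1-based start of this transcript's span
        for gi, ei in enumerate(g_order):
            segs = seg_lists[ei]
            if strand == -1:
                segs = tuple(reversed(segs))  # store in genomic order
            g_len = sum(s.length for s in segs if s.op in ("M", "D"))
            g_exons.append((cursor, cursor + g_len - 1, segs))
            if gi < n_ex - 1:
                cursor += g_len + intron_lens[gi]
            else:
                cursor += g_len
        span_len = cursor - (len(contig) + 1)

        # --- transcript sequence with a clean CDS --------------------------
        ex_tx_len = [sum(s.length for s in segs if s.op in ("M", "I"))
                     for segs in seg_lists]
        tx_len = sum(ex_tx_len)
        cum = [0]
        for L in ex_tx_len:
            cum.append(cum[-1] + L)
        ex0 = config.cds_start_exon - 1
        lo = max(cum[ex0] + 1, config.utr_margin + 1)
        hi = cum[ex0 + 1]
        if lo > hi or lo > tx_len - config.utr_margin - 6:
            raise GenerationError(
                f"exon {config.cds_start_exon} cannot hold a CDS start "
                f"(transcript length {tx_len})")
        cds_start_n = rng.randint(lo, min(hi, lo + (hi - lo) // 2))
        max_codons = (tx_len - config.utr_margin - cds_start_n + 1) // 3
        if max_codons < 3:
            raise GenerationError("transcript too short for a CDS")
        n_codons = rng.randint(3, max_codons)
        cds_end_n = cds_start_n + 3 * n_codons - 1
        coding = ["ATG"]
        coding += [rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2)]
        coding.append(rng.choice(_STOPS))
        tx_seq = (_rand_seq(rng, cds_start_n - 1)
                  + "".join(coding)
                  + _rand_seq(rng, tx_len - cds_end_n))
        assert len(tx_seq) == tx_len

        # --- back-propagate exonic bases onto the contig -------------------
        span_start0 = len(contig)  # 0-based
        contig.extend(_rand_seq(rng, span_len))  # introns, D bases; overwritten below
        tx_pos = 0
        exon_iter = g_exons if strand == 1 else list(reversed(g_exons))
        for g_start, g_end, segs in exon_iter:
            walk = segs if strand == 1 else tuple(reversed(segs))
            g = g_start - 1 if strand == 1 else g_end  # 0-based cursor
            for seg in walk:
                if seg.op == "M":
                    piece = tx_seq[tx_pos:tx_pos + seg.length]
                    if strand == 1:
                        contig[g:g + seg.length] = list(piece)
                        g += seg.length
                    else:
                        rc = piece.translate(_COMPLEMENT)[::-1]
                        contig[g - seg.length:g] = list(rc)
                        g -= seg.length
                    tx_pos += seg.length
                elif seg.op == "D":
                    g += seg.length if strand == 1 else -seg.length
                else:  # I: transcript-only, nothing on the genome
                    tx_pos += seg.length
        assert tx_pos == tx_len

        exons = tuple(Exon(gs, ge, segs) for gs, ge, segs in g_exons)
        base = dict(
            tx_ac=tx_ac, gene=f"{config.gene_prefix}{t}", strand=strand,
            ref_ac=config.ref_ac, exons=exons, cds_start_n=cds_start_n,
            cds_end_n=cds_end_n, aln_method=config.aln_method,
            pro_ac=f"PR{t:02d}.1",
        )
        records.append(TranscriptRecord(**base))
        sequences[tx_ac] = tx_seq

        # --- optional second alignment method with a boundary slide --------
        if slide_intron is not None:
            # genomic index of the exon 5' (genomic) of the slid intron
            j = slide_intron
            left = exons[j]
            right = exons[j + 1]
            if left.segments[-1].op != "M" or right.segments[0].op != "M" \
                    or right.segments[0].length <= shift:
                raise GenerationError(
                    "the slid boundary must sit between matched runs longer "
                    "than the shift; enlarge exon_length or drop indels")
            # plant the repeat that makes the two alignments equivalent:
            # first `shift` intron bases := first `shift` bases of the right exon
            for k in range(shift):
                contig[left.g_end + k] = contig[right.g_start - 1 + k]
            new_left = Exon(
                left.g_start, left.g_end + shift,
                left.segments[:-1] + (AlignmentSegment(
                    "M", left.segments[-1].length + shift),))
            new_right = Exon(
                right.g_start + shift, right.g_end,
                (AlignmentSegment("M", right.segments[0].length - shift),)
                + right.segments[1:])
            alt_exons = exons[:j] + (new_left, new_right) + exons[j + 2:]
            records.append(TranscriptRecord(**{
                **base, "exons": alt_exons, "aln_method": config.alt_aln_method}))

        emit_random(config.flank)

    sequences[config.ref_ac] = "".join(contig)
    fixture = LocusFixture(
        sequences=sequences, records=tuple(records), seed=seed,
        params={"config": repr(config)},
    )
    fixture.validate()
    return fixture


# ---------------------------------------------------------------------------
# The fixed two-transcript demo locus


DEMO_CONTIG = "CTG01.1"
DEMO_TX1 = "TX01.1"
DEMO_TX2 = "TX02.1"


def demo_locus(seed: int = 42) -> LocusFixture:
    """A fixed minus-strand locus mirroring the classic two-transcript case.

    Two transcripts of gene MCL1L share their first two and last exons;
    TX02.1 has an extra internal exon inside TX01.1's second intron.  The
    locus is built so that:

    * TX01.1:c.688+403 (deep in intron 2) and TX02.1:c.281 (exonic, coding)
      are the same genomic base, g.848 on CTG01.1;
    * the transcript-strand base there is C (genomic G, minus strand);
    * TX02.1 codon 94 is TCC (Ser), so c.281C>T yields p.(Ser94Phe);
    * TX02.1's CDS starts in its second exon.

    Only filler bases depend on the seed; every coordinate above is fixed.
    """
    rng = random.Random(seed)

    tx2_len = 1170
    tx2 = list(_rand_seq(rng, tx2_len, "ACG"))  # no T: no stray stop codons
    tx2[12:15] = "ATG"      # TX1 CDS start (n.13, shared exon 1)
    tx2[433:436] = "ATG"    # TX2 CDS start (n.434, exon 2)
    tx2[712:715] = "TCC"    # TX2 codon 94 (c.280-282), Ser
    tx2[1132:1135] = "TAA"  # TX2 stop (c.700-702)
    tx2[1149:1152] = "TAA"  # TX1 stop (TX1 n.1030-1032, TX2 3' UTR)
    tx2_seq = "".join(tx2)
    tx1_seq = tx2_seq[:700] + tx2_seq[820:]  # drop the extra exon (TX2 n.701-820)

    contig = list(_rand_seq(rng, 2600))
    tx2_exons_g = [(301, 650), (742, 861), (1251, 1650), (2051, 2350)]
    # back-propagate TX2 (superset of TX1's exons) onto the minus strand
    tx_pos = 0
    for g_start, g_end in reversed(tx2_exons_g):  # transcript order on '-'
        length = g_end - g_start + 1
        piece = tx2_seq[tx_pos:tx_pos + length]
        contig[g_start - 1:g_end] = list(piece.translate(_COMPLEMENT)[::-1])
        tx_pos += length
    assert tx_pos == tx2_len
    contig_seq = "".join(contig)

    def mk(tx_ac, pro_ac, exon_spans, cds_start_n, cds_end_n):
        return TranscriptRecord(
            tx_ac=tx_ac, gene="MCL1L", strand=-1, ref_ac=DEMO_CONTIG,
            exons=tuple(Exon(s, e, (AlignmentSegment("M", e - s + 1),))
                        for s, e in exon_spans),
            cds_start_n=cds_start_n, cds_end_n=cds_end_n,
            aln_method="splign", pro_ac=pro_ac,
        )

    records = (
        mk(DEMO_TX1, "PR01.1", [(301, 650), (1251, 1650), (2051, 2350)], 13, 1032),
        mk(DEMO_TX2, "PR02.1", tx2_exons_g, 434, 1135),
    )
    fixture = LocusFixture(
        sequences={DEMO_CONTIG: contig_seq, DEMO_TX1: tx1_seq, DEMO_TX2: tx2_seq},
        records=records, seed=seed, params={"kind": "demo_locus"},
    )
    fixture.validate()
    return fixture


# ---------------------------------------------------------------------------
# Random well-formed model objects (for round-trip and property testing)


def _rand_accession(rng: random.Random) -> str:
    first = rng.choice("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    body = "".join(rng.choice("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_")
                   for _ in range(rng.randint(1, 8)))
    return f"{first}{body}.{rng.randint(1, 9)}"


def _rand_simple_interval(rng: random.Random) -> "m_.Interval":
    a = rng.randint(1, 10**6)
    b = a + rng.randint(0, 50)
    return m_.Interval(m_.SimplePosition(a), m_.SimplePosition(b))


def _rand_bo_pos(rng: random.Random, datum) -> "m_.BaseOffsetPosition":
    if datum is m_.Datum.CDS_START:
        base = rng.choice([rng.randint(1, 5000), -rng.randint(1, 300)])
    else:
        base = rng.randint(1, 5000)
    offset = rng.choice([0, 0, 0, rng.randint(1, 400), -rng.randint(1, 400)])
    return m_.BaseOffsetPosition(base, offset, datum)


def _rand_bo_interval(rng: random.Random, seq_start: bool) -> "m_.Interval":
    if seq_start:
        d1 = d2 = m_.Datum.SEQ_START
    else:
        d1 = rng.choice([m_.Datum.CDS_START, m_.Datum.CDS_END])
        d2 = m_.Datum.CDS_END if d1 is m_.Datum.CDS_END \
            else rng.choice([m_.Datum.CDS_START, m_.Datum.CDS_END])
    a = _rand_bo_pos(rng, d1)
    b = _rand_bo_pos(rng, d2)
    from .models import position_order
    if a.datum is b.datum and position_order(a, b) > 0:
        a, b = b, a
    return m_.Interval(a, b)


def _rand_na_edit(rng: random.Random, alphabet: str):
    seq = lambda lo=1, hi=6: "".join(rng.choice(alphabet)
                                     for _ in range(rng.randint(lo, hi)))
    kind = rng.choice(
        ["sub", "del", "del_seq", "ins", "delins", "bare_delins",
         "dup", "dup_seq", "repeat", "identity", "identity_seq"])
    if kind == "sub":
        return m_.NARefAlt(seq(1, 1), seq(1, 1))
    if kind == "del":
        return m_.NARefAlt(None, None)
    if kind == "del_seq":
        return m_.NARefAlt(seq(), None)
    if kind == "ins":
        return m_.NARefAlt(None, seq())
    if kind == "delins":
        return m_.NARefAlt(seq(2, 6), seq())
    if kind == "bare_delins":
        return m_.NARefAlt(None, seq(), deleted=True)
    if kind == "dup":
        return m_.Dup(None)
    if kind == "dup_seq":
        return m_.Dup(seq())
    if kind == "repeat":
        lo = rng.randint(1, 9)
        return m_.Repeat(seq(1, 4), lo, lo + rng.choice([0, 0, rng.randint(1, 5)]))
    if kind == "identity":
        return m_.NARefAlt("", "")
    s = seq(2, 5)
    return m_.NARefAlt(s, s)


def _rand_aa_posedit(rng: random.Random) -> "m_.PosEdit":
    aa = lambda: rng.choice(m_.AA3_CODES[:-1])  # exclude Ter for interval refs
    run = lambda: "".join(aa() for _ in range(rng.randint(1, 4)))
    inferred = rng.random() < 0.5
    kind = rng.choice(["sub", "identity", "identity_pos", "del", "ins",
                       "delins", "fs", "fs_full"])
    if kind == "identity":
        return m_.PosEdit(None, m_.AAIdentity(), inferred=inferred)
    a = rng.randint(1, 2000)
    b = a + rng.randint(0, 20)
    iv = m_.Interval(m_.AAPosition(a, aa()), m_.AAPosition(b, aa()))
    point = m_.Interval.point(iv.start)
    if kind == "sub":
        alt = rng.choice(m_.AA3_CODES)
        return m_.PosEdit(point, m_.AASub(iv.start.aa, alt), inferred=inferred)
    if kind == "identity_pos":
        return m_.PosEdit(iv, m_.AAIdentity(), inferred=inferred)
    if kind == "del":
        return m_.PosEdit(iv, m_.AADelIns(deleted=True, alt=None), inferred=inferred)
    if kind == "ins":
        return m_.PosEdit(iv, m_.AADelIns(deleted=False, alt=run()), inferred=inferred)
    if kind == "delins":
        return m_.PosEdit(iv, m_.AADelIns(deleted=True, alt=run()), inferred=inferred)
    if kind == "fs":
        return m_.PosEdit(point, m_.AAFs(alt=None, terminus=None), inferred=inferred)
    return m_.PosEdit(
        point,
        m_.AAFs(alt=aa(), terminus=rng.choice([None, rng.randint(1, 200)])),
        inferred=inferred)


def random_variant(rng: random.Random) -> "m_.SequenceVariant":
    """A random well-formed, canonical-form variant object.

    Spans the six sequence types and every edit kind the grammar accepts;
    useful for round-trip (parse of format, format of parse) testing at
    scale with a caller-controlled seed.
    """
    stype = rng.choice(list(m_.SequenceType))
    ac = _rand_accession(rng)
    if stype is m_.SequenceType.p:
        return m_.SequenceVariant(ac=ac, type=stype, posedit=_rand_aa_posedit(rng))
    if stype in (m_.SequenceType.g, m_.SequenceType.m):
        iv = _rand_simple_interval(rng)
        edit = _rand_na_edit(rng, "ACGT")
    elif stype is m_.SequenceType.n:
        iv = _rand_bo_interval(rng, seq_start=True)
        edit = _rand_na_edit(rng, "ACGT")
    elif stype is m_.SequenceType.c:
        iv = _rand_bo_interval(rng, seq_start=False)
        edit = _rand_na_edit(rng, "ACGT")
    else:  # r
        iv = _rand_bo_interval(rng, seq_start=False)
        edit = _rand_na_edit(rng, "acgu")
    return m_.SequenceVariant(ac=ac, type=stype, posedit=m_.PosEdit(iv, edit))
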