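"""Coordinate projection between g., n., c. and p. representations.

The centrepiece is an indel-aware alignment map built from a transcript
record: the transcript's genomic span is partitioned into blocks (matched
run, genome-only discrepancy D, transcript-only discrepancy I, intron) and
positions are projected block-wise in either direction.  Positions falling
inside a discrepancy block cannot be projected exactly — the bases simply
do not exist on the other sequence — so they are *clamped* to the nearest
transcript-5' position and flagged, rather than rejected; this is what lets
variants in the ~1-2% of transcripts with genome-transcript indels be
mapped at all, where a gapless exon model silently mis-places them.

Intronic positions map to base/offset coordinates anchored at the nearest
exon boundary; at the exact midpoint of an even-length intron the 5' exon
boundary (in transcript orientation) wins, a fixed tie-break that keeps
round-trips deterministic.

All internal arithmetic is 0-based half-open; the 1-based inclusive HGVS
convention applies only at the module boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

from Bio.Seq import Seq

from . import models as m
from .provider import DataProvider, TranscriptRecord, revcomp

__all__ = [
    "HgvsMapperError",
    "MappingRangeError",
    "UnsupportedOperationError",
    "AlignmentBuildError",
    "GapWarning",
    "BoundaryWarning",
    "MappedPosition",
    "AlignmentMap",
    "build_alignment_map",
    "n_pos_to_c",
    "c_pos_to_n",
    "VariantMapper",
]


class HgvsMapperError(Exception):
    """Base class for mapping failures."""


class MappingRangeError(HgvsMapperError, ValueError):
    """Position lies outside the mappable range."""


class UnsupportedOperationError(HgvsMapperError):
    """The projection is undefined for this variant (e.g. protein inference
    for a UTR position)."""


class AlignmentBuildError(HgvsMapperError, ValueError):
    """The transcript record cannot produce a consistent alignment map."""


class GapWarning(UserWarning):
    """A position fell inside an alignment discrepancy and was clamped."""


class BoundaryWarning(UserWarning):
    """An edit spans an exon/intron boundary; endpoints mapped positionally."""


@dataclass(frozen=True)
class MappedPosition:
    """Projection result: the position plus a flag recording an indel clamp."""

    pos: m.Position
    gap_flag: bool = False


@dataclass(frozen=True)
class _Block:
    kind: str          # 'M', 'D', 'I', 'intron'
    g_start: int       # 0-based half-open genomic span (g_start == g_end for I)
    g_end: int
    n_start: int = 0   # 0-based half-open transcript span (empty for D/intron,
    n_end: int = 0     # where n_start == n_end records the 5'-side base count)


class AlignmentMap:
    """Bidirectional projector between genomic and transcript coordinates."""

    def __init__(self, rec: TranscriptRecord, tx_len: Optional[int] = None):
        try:
            rec.validate(tx_len=tx_len)
        except Exception as exc:
            raise AlignmentBuildError(str(exc)) from exc
        self.rec = rec
        self.strand = rec.strand
        raw: List[Tuple[str, int, int]] = []  # (kind, g_start0, g_end0)
        prev_end = None
        for exon in rec.exons:
            if prev_end is not None:
                raw.append(("intron", prev_end, exon.g_start - 1))
            g = exon.g_start - 1
            for seg in exon.segments:
                if seg.op == "M":
                    raw.append(("M", g, g + seg.length))
                    g += seg.length
                elif seg.op == "D":
                    raw.append(("D", g, g + seg.length))
                    g += seg.length
                else:  # I — zero genomic width, remember transcript width
                    raw.append((f"I{seg.length}", g, g))
            prev_end = exon.g_end
        # assign transcript coordinates in transcript orientation
        order = range(len(raw)) if self.strand == 1 else range(len(raw) - 1, -1, -1)
        n = 0
        blocks: List[Optional[_Block]] = [None] * len(raw)
        for i in order:
            kind, gs, ge = raw[i]
            if kind == "M":
                blocks[i] = _Block("M", gs, ge, n, n + (ge - gs))
                n += ge - gs
            elif kind.startswith("I"):
                ln = int(kind[1:])
                blocks[i] = _Block("I", gs, ge, n, n + ln)
                n += ln
            else:
                blocks[i] = _Block(kind, gs, ge, n, n)
        self.blocks: Tuple[_Block, ...] = tuple(blocks)  # genomic-ascending
        self.tx_length = n
        self.g_span = (rec.g_start, rec.g_end)  # 1-based inclusive

    # -- position projection ----------------------------------------------

    def g_to_n(self, g: int) -> MappedPosition:
        """Project a 1-based genomic position to a transcript base/offset."""
        g0 = g - 1
        lo, hi = self.g_span
        if not (lo <= g <= hi):
            raise MappingRangeError(
                f"g.{g} outside the transcript span g.{lo}_{hi} of {self.rec.tx_ac}")
        blk = self._block_at_g(g0)
        if blk.kind == "M":
            if self.strand == 1:
                n0 = blk.n_start + (g0 - blk.g_start)
            else:
                n0 = blk.n_start + (blk.g_end - 1 - g0)
            return MappedPosition(self._npos(n0 + 1, 0))
        if blk.kind == "D":
            return MappedPosition(self._npos(max(blk.n_start, 1), 0), gap_flag=True)
        # intron: anchor at the nearest exon boundary; ties go 5'
        if self.strand == 1:
            d5 = g0 - blk.g_start + 1
            d3 = blk.g_end - g0
        else:
            d5 = blk.g_end - g0
            d3 = g0 - blk.g_start + 1
        if d5 <= d3:
            return MappedPosition(self._npos(blk.n_start, d5))
        return MappedPosition(self._npos(blk.n_start + 1, -d3))

    def n_to_g(self, n: int, offset: int = 0) -> MappedPosition:
        """Project a transcript base (with optional intronic offset) to g."""
        if not (1 <= n <= self.tx_length):
            raise MappingRangeError(
                f"n.{n} outside 1..{self.tx_length} of {self.rec.tx_ac}")
        n0 = n - 1
        blk = self._block_at_n(n0)
        if blk.kind == "I":
            if offset:
                raise MappingRangeError(
                    f"n.{n}{offset:+d}: offsets are only defined at exon boundaries")
            g0 = blk.g_start - 1 if self.strand == 1 else blk.g_start
            return MappedPosition(m.SimplePosition(g0 + 1), gap_flag=True)
        if self.strand == 1:
            g0 = blk.g_start + (n0 - blk.n_start) + offset
        else:
            g0 = blk.g_end - 1 - (n0 - blk.n_start) - offset
        lo, hi = self.g_span
        if not (lo <= g0 + 1 <= hi):
            raise MappingRangeError(
                f"n.{n}{offset:+d} projects to g.{g0 + 1}, outside the "
                f"transcript span g.{lo}_{hi}")
        return MappedPosition(m.SimplePosition(g0 + 1))

    # -- internals ---------------------------------------------------------

    def _npos(self, base: int, offset: int) -> m.BaseOffsetPosition:
        return m.BaseOffsetPosition(base, offset, m.Datum.SEQ_START)

    def _block_at_g(self, g0: int) -> _Block:
        for blk in self.blocks:
            if blk.g_start <= g0 < blk.g_end:
                return blk
        raise MappingRangeError(f"no alignment block covers g.{g0 + 1}")

    def _block_at_n(self, n0: int) -> _Block:
        for blk in self.blocks:
            if blk.kind in ("M", "I") and blk.n_start <= n0 < blk.n_end:
                return blk
        raise MappingRangeError(f"no alignment block covers n.{n0 + 1}")


def build_alignment_map(rec: TranscriptRecord,
                        tx_len: Optional[int] = None) -> AlignmentMap:
    """Build the block-wise alignment map for a transcript record."""
    return AlignmentMap(rec, tx_len=tx_len)


# ---------------------------------------------------------------------------
# CDS <-> transcript coordinate arithmetic (pure, exact inverse pair)


def n_pos_to_c(rec: TranscriptRecord, pos: m.BaseOffsetPosition) -> m.BaseOffsetPosition:
    """n. base/offset -> c. base/offset for a coding transcript.

    Bases before the CDS become negative (there is no c.0); bases after the
    CDS become ``*`` (cds_end datum) positions.  Intronic offsets pass
    through unchanged.
    """
    if not rec.is_coding:
        raise UnsupportedOperationError(
            f"{rec.tx_ac} is non-coding; c. coordinates are undefined")
    cs, ce = rec.cds_start_n, rec.cds_end_n
    if pos.base < cs:
        return m.BaseOffsetPosition(pos.base - cs, pos.offset, m.Datum.CDS_START)
    if pos.base <= ce:
        return m.BaseOffsetPosition(pos.base - cs + 1, pos.offset, m.Datum.CDS_START)
    return m.BaseOffsetPosition(pos.base - ce, pos.offset, m.Datum.CDS_END)


def c_pos_to_n(rec: TranscriptRecord, pos: m.BaseOffsetPosition) -> m.BaseOffsetPosition:
    """Exact inverse of :func:`n_pos_to_c`."""
    if not rec.is_coding:
        raise UnsupportedOperationError(
            f"{rec.tx_ac} is non-coding; c. coordinates are undefined")
    cs, ce = rec.cds_start_n, rec.cds_end_n
    if pos.datum is m.Datum.CDS_END:
        n = ce + pos.base
    elif pos.base < 0:
        n = cs + pos.base
    else:
        n = cs + pos.base - 1
    if not (1 <= n <= rec.tx_length):
        raise MappingRangeError(
            f"c. position {pos} lies outside the transcript (n.{n})")
    return m.BaseOffsetPosition(n, pos.offset, m.Datum.SEQ_START)


# ---------------------------------------------------------------------------
# Variant-level projection


def _revcomp_edit(edit: m.Edit) -> m.Edit:
    def rc(s):
        return revcomp(s) if s is not None else None

    if isinstance(edit, m.NARefAlt):
        return m.NARefAlt(rc(edit.ref), rc(edit.alt), deleted=edit.deleted)
    if isinstance(edit, m.Dup):
        return m.Dup(rc(edit.ref))
    if isinstance(edit, m.Repeat):
        return m.Repeat(revcomp(edit.unit), edit.min, edit.max)
    raise UnsupportedOperationError(
        f"cannot strand-flip edit {type(edit).__name__}")


class VariantMapper:
    """Projects whole variants through a data provider's alignments."""

    def __init__(self, provider: DataProvider):
        self.provider = provider
        self._maps = {}

    def _alignment(self, tx_ac: str, ref_ac: Optional[str] = None,
                   aln_method: Optional[str] = None):
        rec = self.provider.get_transcript(tx_ac, ref_ac, aln_method)
        key = (rec.tx_ac, rec.ref_ac, rec.aln_method)
        if key not in self._maps:
            tx_len = len(self.provider.get_seq(tx_ac))
            self._maps[key] = AlignmentMap(rec, tx_len=tx_len)
        return rec, self._maps[key]

    # -- g <-> n -----------------------------------------------------------

    def g_to_n(self, var_g: m.SequenceVariant, tx_ac: str,
               aln_method: Optional[str] = None) -> m.SequenceVariant:
        self._expect(var_g, (m.SequenceType.g, m.SequenceType.m))
        rec, amap = self._alignment(tx_ac, var_g.ac, aln_method)
        mstart = amap.g_to_n(var_g.posedit.pos.start.base)
        mend = amap.g_to_n(var_g.posedit.pos.end.base)
        if rec.strand == -1:
            mstart, mend = mend, mstart
        self._warn_gaps(var_g, mstart, mend)
        edit = var_g.posedit.edit if rec.strand == 1 \
            else _revcomp_edit(var_g.posedit.edit)
        iv = m.Interval(mstart.pos, mend.pos)
        self._warn_boundary(iv, var_g)
        return m.SequenceVariant(ac=tx_ac, type=m.SequenceType.n,
                                 posedit=m.PosEdit(iv, edit))

    def n_to_g(self, var_n: m.SequenceVariant, ref_ac: Optional[str] = None,
               aln_method: Optional[str] = None) -> m.SequenceVariant:
        self._expect(var_n, (m.SequenceType.n,))
        rec, amap = self._alignment(var_n.ac, ref_ac, aln_method)
        ps, pe = var_n.posedit.pos.start, var_n.posedit.pos.end
        mstart = amap.n_to_g(ps.base, ps.offset)
        mend = amap.n_to_g(pe.base, pe.offset)
        if rec.strand == -1:
            mstart, mend = mend, mstart
        self._warn_gaps(var_n, mstart, mend)
        edit = var_n.posedit.edit if rec.strand == 1 \
            else _revcomp_edit(var_n.posedit.edit)
        return m.SequenceVariant(ac=rec.ref_ac, type=m.SequenceType.g,
                                 posedit=m.PosEdit(m.Interval(mstart.pos, mend.pos),
                                                   edit))

    # -- c <-> n -----------------------------------------------------------

    def c_to_n(self, var_c: m.SequenceVariant) -> m.SequenceVariant:
        self._expect(var_c, (m.SequenceType.c,))
        rec = self.provider.get_transcript(var_c.ac)
        iv = var_c.posedit.pos
        niv = m.Interval(c_pos_to_n(rec, iv.start), c_pos_to_n(rec, iv.end))
        return m.SequenceVariant(ac=var_c.ac, type=m.SequenceType.n,
                                 posedit=m.PosEdit(niv, var_c.posedit.edit))

    def n_to_c(self, var_n: m.SequenceVariant) -> m.SequenceVariant:
        self._expect(var_n, (m.SequenceType.n,))
        rec = self.provider.get_transcript(var_n.ac)
        iv = var_n.posedit.pos
        civ = m.Interval(n_pos_to_c(rec, iv.start), n_pos_to_c(rec, iv.end))
        return m.SequenceVariant(ac=var_n.ac, type=m.SequenceType.c,
                                 posedit=m.PosEdit(civ, var_n.posedit.edit))

    # -- g <-> c -----------------------------------------------------------

    def g_to_c(self, var_g: m.SequenceVariant, tx_ac: str,
               aln_method: Optional[str] = None) -> m.SequenceVariant:
        return self.n_to_c(self.g_to_n(var_g, tx_ac, aln_method))

    def c_to_g(self, var_c: m.SequenceVariant, ref_ac: Optional[str] = None,
               aln_method: Optional[str] = None) -> m.SequenceVariant:
        return self.n_to_g(self.c_to_n(var_c), ref_ac, aln_method)

    # -- protein inference -------------------------------------------------

    def c_to_p(self, var_c: m.SequenceVariant) -> m.SequenceVariant:
        """Infer the protein consequence of a CDS variant.

        Exonic CDS edits are applied to the coding sequence (plus 3' UTR, so
        a frameshift can run to its new stop) and both sequences are
        translated with the standard nuclear code; the protein change is the
        difference between the translations.  A variant lying entirely
        within an intron cannot change the mature transcript under this
        model and yields p.(=).  UTR positions and edits touching an
        exon/intron boundary are not projectable to a protein consequence
        and raise; express those at g. or n. level instead.
        """
        self._expect(var_c, (m.SequenceType.c,))
        rec = self.provider.get_transcript(var_c.ac)
        if not rec.is_coding:
            raise UnsupportedOperationError(f"{var_c.ac} is non-coding")
        pro_ac = self.provider.get_protein_accession(var_c.ac) or f"{var_c.ac}(p)"
        iv = var_c.posedit.pos
        offsets = (iv.start.offset, iv.end.offset)
        if all(o != 0 for o in offsets):
            return m.SequenceVariant(
                ac=pro_ac, type=m.SequenceType.p,
                posedit=m.PosEdit(None, m.AAIdentity(), inferred=True))
        if any(o != 0 for o in offsets):
            raise UnsupportedOperationError(
                f"{var_c}: edit touches an exon/intron boundary; protein "
                "inference is undefined — map at g. or n. level instead")
        for pos in (iv.start, iv.end):
            if pos.datum is not m.Datum.CDS_START or pos.base < 0:
                raise UnsupportedOperationError(
                    f"{var_c}: UTR positions have no protein consequence; "
                    "map at g. or n. level instead")
        cs, ce = rec.cds_start_n, rec.cds_end_n
        cds_len = ce - cs + 1
        if cds_len % 3 != 0:
            raise HgvsMapperError(
                f"{var_c.ac}: CDS length {cds_len} is not a multiple of 3")
        if not (iv.start.base <= cds_len and iv.end.base <= cds_len):
            raise MappingRangeError(f"{var_c}: position beyond the CDS")
        tx_seq = self.provider.get_seq(var_c.ac)
        region = tx_seq[cs - 1:]          # CDS plus 3' UTR
        edited = _apply_edit(region, iv.start.base, iv.end.base, var_c.posedit.edit)
        ref_aa = _translate(region[:cds_len])
        alt_aa = _translate(edited)
        dlen = len(edited) - len(region)
        edit = _diff_proteins(ref_aa, alt_aa, frameshift=dlen % 3 != 0)
        return m.SequenceVariant(ac=pro_ac, type=m.SequenceType.p, posedit=edit)

    # -- liftover ----------------------------------------------------------

    def liftover(self, var_c: m.SequenceVariant, to_tx: str,
                 from_method: Optional[str] = None,
                 to_method: Optional[str] = None,
                 ref_ac: Optional[str] = None) -> m.SequenceVariant:
        """Re-express a c. variant on another transcript (or another
        alignment of the same transcript) via their shared genomic reference."""
        self._expect(var_c, (m.SequenceType.c,))
        rec_from = self.provider.get_transcript(var_c.ac, ref_ac, from_method)
        rec_to = self.provider.get_transcript(to_tx, None, to_method)
        if rec_to.ref_ac != rec_from.ref_ac:
            raise HgvsMapperError(
                f"no shared genomic reference: {var_c.ac} is on {rec_from.ref_ac}, "
                f"{to_tx} on {rec_to.ref_ac}")
        var_g = self.c_to_g(var_c, rec_from.ref_ac, rec_from.aln_method)
        return self.g_to_c(var_g, to_tx, rec_to.aln_method)

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _expect(var: m.SequenceVariant, types) -> None:
        if var.type not in types:
            wanted = "/".join(t.value for t in types)
            raise UnsupportedOperationError(
                f"expected a {wanted}. variant, got {var.type.value}. ({var})")

    @staticmethod
    def _warn_gaps(src: m.SequenceVariant, *mapped: MappedPosition) -> None:
        if any(p.gap_flag for p in mapped):
            warnings.warn(
                f"{src}: position(s) fall inside a genome-transcript alignment "
                "discrepancy and were clamped to the nearest 5' base",
                GapWarning, stacklevel=3)

    @staticmethod
    def _warn_boundary(iv: m.Interval, src: m.SequenceVariant) -> None:
        s, e = iv.start, iv.end
        if isinstance(s, m.BaseOffsetPosition) and (s.offset == 0) != (e.offset == 0):
            warnings.warn(
                f"{src}: edit spans an exon/intron boundary; endpoints were "
                "mapped positionally", BoundaryWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# Protein-inference helpers


def _translate(seq: str) -> str:
    """Translate to 1-letter amino acids, stopping after the first stop."""
    trimmed = seq[:len(seq) - len(seq) % 3]
    aa = str(Seq(trimmed).translate())
    stop = aa.find("*")
    return aa[:stop + 1] if stop >= 0 else aa


def _apply_edit(region: str, c_start: int, c_end: int, edit: m.Edit) -> str:
    """Apply a CDS edit to region (CDS+3'UTR, c.1 at index 0)."""
    s0, e0 = c_start - 1, c_end
    if isinstance(edit, m.NARefAlt):
        if edit.ref == edit.alt and edit.ref is not None:
            return region
        if edit.alt is None:  # deletion
            return region[:s0] + region[e0:]
        if edit.ref is None and not edit.deleted:  # insertion between s and e
            if c_end != c_start + 1:
                raise UnsupportedOperationError(
                    "insertion interval must be two flanking bases")
            return region[:c_start] + edit.alt + region[c_start:]
        return region[:s0] + edit.alt + region[e0:]  # delins (ref'd or bare)
    if isinstance(edit, m.Dup):
        return region[:e0] + region[s0:e0] + region[e0:]
    raise UnsupportedOperationError(
        f"protein inference for {type(edit).__name__} edits is not defined")


def _aa3(letter: str) -> str:
    return m.AA1_TO_AA3[letter]


def _diff_proteins(ref_aa: str, alt_aa: str, frameshift: bool) -> m.PosEdit:
    """Describe alt vs ref translation as an inferred protein posedit."""
    if alt_aa == ref_aa:
        return m.PosEdit(None, m.AAIdentity(), inferred=True)
    limit = min(len(ref_aa), len(alt_aa))
    i = next((k for k in range(limit) if ref_aa[k] != alt_aa[k]), limit)
    if i >= len(ref_aa):  # ref is a proper prefix: change begins at/after Ter
        i = len(ref_aa) - 1
    ref_res = ref_aa[i]
    pos = m.AAPosition(i + 1, _aa3(ref_res))
    alt_res = alt_aa[i] if i < len(alt_aa) else None
    if alt_res == "*":
        return m.PosEdit(m.Interval.point(pos), m.AASub(_aa3(ref_res), "Ter"),
                         inferred=True)
    if frameshift:
        stop = alt_aa.find("*", i)
        terminus = stop - i + 1 if stop >= 0 else None
        return m.PosEdit(
            m.Interval.point(pos),
            m.AAFs(alt=_aa3(alt_res) if alt_res else None, terminus=terminus),
            inferred=True)
    if len(ref_aa) == len(alt_aa):
        diffs = [k for k in range(len(ref_aa)) if ref_aa[k] != alt_aa[k]]
        if len(diffs) == 1:
            return m.PosEdit(m.Interval.point(pos),
                             m.AASub(_aa3(ref_res), _aa3(alt_aa[i])), inferred=True)
    # in-frame multi-residue change: trim common prefix/suffix
    p = i
    s = 0
    while s < min(len(ref_aa) - p, len(alt_aa) - p) \
            and ref_aa[len(ref_aa) - 1 - s] == alt_aa[len(alt_aa) - 1 - s]:
        s += 1
    if p == 0 and s == len(ref_aa):
        s -= 1  # N-terminal insertion: no 5' flanking residue exists, so
        # borrow residue 1 and describe a delins at position 1 instead
    ref_mid = ref_aa[p:len(ref_aa) - s]
    alt_mid = alt_aa[p:len(alt_aa) - s]
    alt3 = "".join(_aa3(ch) for ch in alt_mid) or None
    if not ref_mid:  # pure insertion between residues p and p+1
        iv = m.Interval(m.AAPosition(p, _aa3(ref_aa[p - 1])),
                        m.AAPosition(p + 1, _aa3(ref_aa[p])))
        return m.PosEdit(iv, m.AADelIns(deleted=False, alt=alt3), inferred=True)
    iv = m.Interval(m.AAPosition(p + 1, _aa3(ref_mid[0])),
                    m.AAPosition(p + len(ref_mid), _aa3(ref_mid[-1])))
    return m.PosEdit(iv, m.AADelIns(deleted=True, alt=alt3), inferred=True)
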