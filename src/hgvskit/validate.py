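"""Intrinsic and extrinsic variant validation.

Intrinsic validation asserts internal correctness of the variant object
alone — interval ordering, the flanking-base rule for insertions, agreement
between a stated reference sequence and the interval span.  Extrinsic
validation additionally consults a data provider: the accession must be
known, the interval must lie within the sequence, and any stated reference
bases must match the provider's sequence (projected through the
genome-transcript alignment for intronic transcript positions).

Failures are collected as findings in a report, never raised: a validator
that throws on the first problem is useless for batch curation.  Extrinsic
validation is skipped when intrinsic validation fails, since span arithmetic
on an intrinsically broken variant is not meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from Bio.Seq import Seq

from . import models as m
from .mapper import (
    HgvsMapperError,
    VariantMapper,
    c_pos_to_n,
)
from .provider import DataProvider, DataProviderError

__all__ = ["Finding", "ValidationReport", "validate_intrinsic",
           "validate_extrinsic", "validate"]


@dataclass(frozen=True)
class Finding:
    level: str  # 'error' or 'warning'
    code: str
    message: str
    span: Optional[str] = None

    def __str__(self) -> str:
        return f"{self.level.upper()} {self.code} {self.message}"


@dataclass
class ValidationReport:
    findings: List[Finding] = field(default_factory=list)

    @property
    def level(self) -> str:
        return "error" if any(f.level == "error" for f in self.findings) else "ok"

    @property
    def is_valid(self) -> bool:
        return self.level == "ok"

    def lines(self) -> List[str]:
        return [str(f) for f in self.findings]

    def _add(self, code: str, message: str, span=None, level: str = "error") -> None:
        self.findings.append(Finding(level, code, message,
                                     span=str(span) if span is not None else None))

    def extend(self, other: "ValidationReport") -> "ValidationReport":
        self.findings.extend(other.findings)
        return self


# ---------------------------------------------------------------------------
# Intrinsic


def _flanking_adjacent(a: m.Position, b: m.Position) -> bool:
    """Can (a, b) be the two flanking bases of an insertion site?

    Decidable without reference data: consecutive exonic bases, consecutive
    intronic offsets on the same anchor base, or the exon-boundary pairs
    (n / n+1-offset) are adjacent.  Pairs whose adjacency depends on intron
    sizes (e.g. 688+5 / 689) are rejected — the object alone cannot
    justify them.
    """
    if isinstance(a, (m.SimplePosition, m.AAPosition)):
        return b.base - a.base == 1
    if a.datum is not b.datum:
        # crossing the CDS-end datum (e.g. c.702_*1); span not intrinsically
        # computable, accept and leave it to extrinsic bounds checks
        return True
    if a.base == b.base:
        return b.offset == a.offset + 1
    step = b.base - a.base
    if a.datum is m.Datum.CDS_START and a.base == -1 and b.base == 1:
        step = 1  # there is no c.0
    return step == 1 and a.offset == 0 and b.offset == 0


def _stated_ref(edit: m.Edit) -> Optional[str]:
    """The reference sequence the edit claims, if any."""
    if isinstance(edit, m.NARefAlt):
        return edit.ref or None
    if isinstance(edit, m.Dup):
        return edit.ref or None
    return None


def _span_length(iv: m.Interval) -> Optional[int]:
    """Number of bases in the interval, when computable without reference
    data (same datum, both offsets zero for base/offset positions)."""
    a, b = iv.start, iv.end
    if isinstance(a, m.SimplePosition):
        return b.base - a.base + 1
    if isinstance(a, m.AAPosition):
        return b.base - a.base + 1
    if a.datum is not b.datum or a.offset != 0 or b.offset != 0:
        return None
    span = b.base - a.base + 1
    if a.datum is m.Datum.CDS_START and a.base < 0 < b.base:
        span -= 1  # no c.0
    return span


def validate_intrinsic(v: m.SequenceVariant) -> ValidationReport:
    """Check the variant object for internal consistency (provider-free)."""
    rep = ValidationReport()
    pe = v.posedit
    iv = pe.pos
    if iv is None:
        return rep
    if not iv.is_ordered:
        rep._add("interval-order",
                 f"interval start {iv.start} is 3' of end {iv.end}", span=iv)
        return rep  # span arithmetic below assumes an ordered interval
    edit = pe.edit
    cat = m.variant_category(v)
    span = _span_length(iv)
    if cat is m.VariantCategory.INS:
        if not _flanking_adjacent(iv.start, iv.end):
            rep._add("ins-span",
                     "an insertion interval must be the two flanking bases "
                     f"(length-1 range), got {iv}", span=iv)
    elif cat is m.VariantCategory.SUB:
        if span is not None and span != 1:
            rep._add("ref-length",
                     f"substitution of one base needs a one-base interval, got {iv}",
                     span=iv)
    ref = _stated_ref(edit) if cat is not m.VariantCategory.INS else None
    if ref is not None and span is not None and len(ref) != span:
        rep._add("ref-length",
                 f"stated reference {ref!r} has {len(ref)} bases but the "
                 f"interval {iv} spans {span}", span=iv)
    return rep


# ---------------------------------------------------------------------------
# Extrinsic


def _expected_exonic(v, rec, provider, n_start: int, n_end: int) -> str:
    return provider.get_seq(v.ac, n_start, n_end)


def validate_extrinsic(v: m.SequenceVariant,
                       provider: DataProvider) -> ValidationReport:
    """Check the variant against reference data from the provider.

    Errors exactly when the accession is unknown, the interval exceeds the
    sequence bounds, or stated reference bases disagree with the provider's
    sequence at the variant interval.  Intronic c./n. positions are checked
    after projection to genomic coordinates through the transcript's
    alignment.  Provider failures become findings, not exceptions.
    """
    rep = ValidationReport()
    try:
        if v.type in (m.SequenceType.g, m.SequenceType.m):
            _extrinsic_genomic(v, provider, rep)
        elif v.type in (m.SequenceType.c, m.SequenceType.n):
            _extrinsic_transcript(v, provider, rep)
        elif v.type is m.SequenceType.p:
            _extrinsic_protein(v, provider, rep)
        else:  # r.: validate against the DNA transcript via transliteration
            rep._add("unsupported", "extrinsic validation of r. variants is "
                     "not supported; validate the c./n. form", level="warning")
    except DataProviderError as exc:
        rep._add("unknown-accession", str(exc))
    return rep


def _check_ref(rep, stated: Optional[str], actual: str, where: str) -> None:
    if stated is not None and stated != actual:
        rep._add("ref-mismatch",
                 f"reference nucleotide mismatch at {where}: variant states "
                 f"{stated!r}, reference has {actual!r}")


def _extrinsic_genomic(v, provider, rep) -> None:
    seq_len = len(provider.get_seq(v.ac))
    iv = v.posedit.pos
    if iv.end.base > seq_len or iv.start.base > seq_len:
        rep._add("bounds", f"position {iv.end} exceeds {v.ac} length {seq_len}")
        return
    stated = _stated_ref(v.posedit.edit)
    if m.variant_category(v) is m.VariantCategory.INS:
        stated = None
    if stated is not None:
        actual = provider.get_seq(v.ac, iv.start.base, iv.end.base)
        _check_ref(rep, stated, actual, f"{v.ac}:g.{iv}")


def _extrinsic_transcript(v, provider, rep) -> None:
    rec = provider.get_transcript(v.ac)
    tx_len = len(provider.get_seq(v.ac))
    iv = v.posedit.pos
    if v.type is m.SequenceType.c:
        try:
            n_start = c_pos_to_n(rec, iv.start)
            n_end = c_pos_to_n(rec, iv.end)
        except HgvsMapperError as exc:
            rep._add("bounds", str(exc))
            return
    else:
        n_start, n_end = iv.start, iv.end
    for pos in (n_start, n_end):
        if not (1 <= pos.base <= tx_len):
            rep._add("bounds",
                     f"position {pos} exceeds transcript {v.ac} length {tx_len}")
            return
    stated = _stated_ref(v.posedit.edit)
    if m.variant_category(v) is m.VariantCategory.INS:
        stated = None
    if stated is None:
        return
    if n_start.offset == 0 and n_end.offset == 0:
        actual = provider.get_seq(v.ac, n_start.base, n_end.base)
        _check_ref(rep, stated, actual, f"{v.ac}:{v.type.value}.{iv}")
        return
    # intronic bases live only on the genome: project through the alignment
    vm = VariantMapper(provider)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            var_g = (vm.c_to_g(v) if v.type is m.SequenceType.c else vm.n_to_g(v))
    except HgvsMapperError as exc:
        rep._add("bounds", f"cannot project {v} to genomic coordinates: {exc}")
        return
    g_iv = var_g.posedit.pos
    actual = provider.get_seq(var_g.ac, g_iv.start.base, g_iv.end.base)
    # var_g's edit is already on the genomic strand
    _check_ref(rep, _stated_ref(var_g.posedit.edit), actual,
               f"{var_g.ac}:g.{g_iv}")


def _extrinsic_protein(v, provider, rep) -> None:
    lookup = getattr(provider, "transcript_for_protein", None)
    if lookup is None:
        rep._add("unsupported", "provider cannot resolve protein accessions",
                 level="warning")
        return
    rec = lookup(v.ac)
    cds = provider.get_seq(rec.tx_ac, rec.cds_start_n, rec.cds_end_n)
    prot = str(Seq(cds).translate())  # 1-letter, '*' for the stop
    iv = v.posedit.pos
    if iv is None:
        return
    endpoints = (iv.start,) if iv.is_point else (iv.start, iv.end)
    for pos in endpoints:
        if pos.base > len(prot):
            rep._add("bounds",
                     f"residue {pos} exceeds protein length {len(prot)}")
            return
        actual = m.AA1_TO_AA3[prot[pos.base - 1]]
        if pos.aa != actual:
            rep._add("ref-mismatch",
                     f"reference amino acid mismatch at {v.ac} residue "
                     f"{pos.base}: variant states {pos.aa}, translation has {actual}")


def validate(v: m.SequenceVariant, provider: Optional[DataProvider] = None
             ) -> ValidationReport:
    """Intrinsic validation, then extrinsic when a provider is given.

    Extrinsic checks are skipped when intrinsic validation already failed.
    """
    rep = validate_intrinsic(v)
    if provider is not None and rep.is_valid:
        rep.extend(validate_extrinsic(v, provider))
    return rep
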