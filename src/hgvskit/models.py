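"""Typed object model for HGVS sequence variants.

An HGVS string such as ``NM_182763.2:c.688+403C>T`` decomposes into an
accession (``NM_182763.2``), a sequence type (``c``) and a *posedit* — a
location interval paired with an edit.  Every component is modelled here as
an immutable dataclass so that a variant can be inspected, transformed and
re-rendered without re-parsing text.

Coordinate conventions follow HGVS throughout: positions are 1-based and
intervals are inclusive.  CDS-relative (``c.``) positions are base/offset
pairs with an explicit datum — ``cds_start`` for ordinary and 5'-UTR
positions (negative base, no base 0) and ``cds_end`` for ``*`` 3'-UTR
positions counted from the first base after the stop codon.  A non-zero
offset counts bases into an intron from the nearest exon boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)
from typing import Optional, Union

__all__ = [
    "SequenceType",
    "Datum",
    "SimplePosition",
    "BaseOffsetPosition",
    "AAPosition",
    "Position",
    "Interval",
    "NARefAlt",
    "Dup",
    "Repeat",
    "AASub",
    "AAIdentity",
    "AADelIns",
    "AAFs",
    "Edit",
    "PosEdit",
    "SequenceVariant",
    "VariantCategory",
    "position_order",
    "variant_category",
    "HgvsModelError",
    "AA3_CODES",
    "AA1_TO_AA3",
    "AA3_TO_AA1",
    "DNA_ALPHABET",
    "RNA_ALPHABET",
]


class HgvsModelError(ValueError):
    """Raised when a model object would violate its type invariants."""


class SequenceType(str, enum.Enum):
    """The six HGVS sequence-type prefixes."""

    g = "g"  # genomic
    m = "m"  # mitochondrial (genomic semantics)
    c = "c"  # coding DNA (CDS-relative)
    n = "n"  # non-coding transcript
    r = "r"  # RNA
    p = "p"  # protein


class Datum(enum.Enum):
    """Reference point a base/offset coordinate is counted from."""

    SEQ_START = "seq_start"
    CDS_START = "cds_start"
    CDS_END = "cds_end"  # HGVS '*' positions (3' UTR)


DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("acgu")

AA3_CODES = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr "
    "Trp Tyr Val Ter".split()
)
AA1_TO_AA3 = dict(
    zip("ARNDCQEGHILKMFPSTWYV*", AA3_CODES)
)
AA3_TO_AA1 = {v: k for k, v in AA1_TO_AA3.items()}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise HgvsModelError(msg)


# ---------------------------------------------------------------------------
# Positions


@dataclass(frozen=True, order=False)
class SimplePosition:
    """A plain 1-based residue number, used for g. and m. coordinates."""

    base: int

    def __post_init__(self) -> None:
        _require(isinstance(self.base, int) and self.base >= 1,
                 f"SimplePosition base must be >= 1, got {self.base!r}")

    def _sort_key(self):
        return (0, self.base, 0)

    def __str__(self) -> str:
        from . import formatter

        return formatter.format_hgvs(self)


@dataclass(frozen=True, order=False)
class BaseOffsetPosition:
    """CDS or transcript coordinate with intronic offset.

    ``base`` is 1-based; with ``datum=CDS_START`` a negative base denotes a
    5'-UTR position (there is no base 0), and ``datum=CDS_END`` encodes HGVS
    ``*`` positions.  ``offset`` is 0 for exonic positions, +k for the k-th
    base after the exon boundary (into the intron) and -k before it.
    """

    base: int
    offset: int = 0
    datum: Datum = Datum.CDS_START

    def __post_init__(self) -> None:
        _require(isinstance(self.base, int), "base must be an integer")
        _require(isinstance(self.offset, int), "offset must be an integer")
        if self.datum is Datum.CDS_START:
            _require(self.base != 0, "HGVS has no CDS position 0")
        else:
            _require(self.base >= 1,
                     f"base must be >= 1 for datum {self.datum.value}, got {self.base}")

    @property
    def is_exonic(self) -> bool:
        return self.offset == 0

    def _sort_key(self):
        # cds_end ('*') positions sort after every cds_start position;
        # seq_start positions form their own family.
        rank = {Datum.SEQ_START: 0, Datum.CDS_START: 0, Datum.CDS_END: 1}[self.datum]
        return (rank, self.base, self.offset)

    def __str__(self) -> str:
        from . import formatter

        return formatter.format_hgvs(self)


@dataclass(frozen=True, order=False)
class AAPosition:
    """A protein residue: 1-based number plus the reference amino acid.

    The amino acid is stored as a 3-letter code (``Ter`` for a stop);
    1-letter input is normalised on construction.
    """

    base: int
    aa: str

    def __post_init__(self) -> None:
        _require(isinstance(self.base, int) and self.base >= 1,
                 f"AAPosition base must be >= 1, got {self.base!r}")
        aa = self.aa
        if len(aa) == 1:
            _require(aa in AA1_TO_AA3, f"unknown amino acid code {aa!r}")
            object.__setattr__(self, "aa", AA1_TO_AA3[aa])
        else:
            _require(aa in AA3_CODES, f"unknown amino acid code {aa!r}")

    def _sort_key(self):
        return (0, self.base, 0)

    def __str__(self) -> str:
        from . import formatter

        return formatter.format_hgvs(self)


Position = Union[SimplePosition, BaseOffsetPosition, AAPosition]


def position_order(a: Position, b: Position) -> int:
    """Total order on positions of the same kind: -1 (a<b), 0 (a=b) or +1.

    CDS_START- and CDS_END-datum positions are mutually comparable (every
    ``*`` position lies 3' of every CDS-datum position); SEQ_START positions
    compare only among themselves.  Comparing different position classes, or
    SEQ_START against a CDS datum, raises ``TypeError``.
    """
    if type(a) is not type(b):
        raise TypeError(f"cannot order {type(a).__name__} against {type(b).__name__}")
    if isinstance(a, BaseOffsetPosition):
        fam = {Datum.SEQ_START: 0, Datum.CDS_START: 1, Datum.CDS_END: 1}
        if fam[a.datum] != fam[b.datum]:
            raise TypeError(
                f"cannot order datum {a.datum.value} against {b.datum.value}")
    ka, kb = a._sort_key(), b._sort_key()
    return (ka > kb) - (ka < kb)


# ---------------------------------------------------------------------------
# Intervals


@dataclass(frozen=True)
class Interval:
    """Inclusive location range.

    Both endpoints must be the same, mutually comparable position kind.  A
    mis-ordered interval (start 3' of end) is representable — HGVS text such
    as ``g.7_5del`` must survive parsing so the intrinsic validator can
    report it — and is exposed via :attr:`is_ordered`.
    """

    start: Position
    end: Position

    def __post_init__(self) -> None:
        try:
            position_order(self.start, self.end)
        except TypeError as exc:
            raise HgvsModelError(str(exc)) from exc

    @property
    def is_ordered(self) -> bool:
        """True when start lies at or 5' of end."""
        return position_order(self.start, self.end) <= 0

    @classmethod
    def point(cls, pos: Position) -> "Interval":
        return cls(pos, pos)

    @property
    def is_point(self) -> bool:
        return self.start == self.end

    def __str__(self) -> str:
        from . import formatter

        return formatter.format_hgvs(self)


# ---------------------------------------------------------------------------
# Edits (nucleotide)


class _StrMixin:
    def __str__(self) -> str:
        from . import formatter

        return formatter.format_hgvs(self)


@dataclass(frozen=True)
class NARefAlt(_StrMixin):
    """Ref/alt nucleotide edit; the shape of (ref, alt) determines the kind.

    ==================  ==========================================
    shape               kind
    ==================  ==========================================
    ref=alt, not None   identity (``=``; a bare ``=`` stores ``''``/``''``)
    alt is None         deletion (ref optional; None = unstated sequence)
    ref None, alt set   insertion, or deletion-insertion when ``deleted``
    len 1 / 1           substitution
    otherwise           deletion-insertion (both present)
    ==================  ==========================================

    ``deleted`` marks a deletion-insertion whose deleted sequence is
    unstated (the common ``5_7delinsTT`` text form); it is meaningful only
    for the ref-absent/alt-present shape and is normalised to False
    everywhere else, so structurally equal edits compare equal.
    """

    ref: Optional[str] = None
    alt: Optional[str] = None
    deleted: bool = False

    def __post_init__(self) -> None:
        for name, s in (("ref", self.ref), ("alt", self.alt)):
            if s is not None:
                _require(isinstance(s, str), f"{name} must be a string or None")
        if not (self.ref is None and self.alt is not None):
            object.__setattr__(self, "deleted", False)
        if self.ref == self.alt and self.ref is not None:
            return  # identity; '' == '' encodes a bare '='
        if self.ref is None and self.alt is None:
            return  # deletion with unstated sequence
        for name, s in (("ref", self.ref), ("alt", self.alt)):
            if s is not None:
                _require(len(s) > 0,
                         f"empty {name} is only legal in an identity edit")


@dataclass(frozen=True)
class Dup(_StrMixin):
    """Duplication; the duplicated sequence may be stated explicitly."""

    ref: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref is not None:
            _require(len(self.ref) > 0, "explicit dup sequence must be non-empty")


@dataclass(frozen=True)
class Repeat(_StrMixin):
    """Tandem repeat: ``unit[min]`` or ``unit[min_max]``."""

    unit: str
    min: int
    max: int

    def __post_init__(self) -> None:
        _require(len(self.unit) >= 1, "repeat unit must be non-empty")
        _require(1 <= self.min <= self.max,
                 f"repeat bounds must satisfy 1 <= min <= max, got {self.min}_{self.max}")


# ---------------------------------------------------------------------------
# Edits (protein)


@dataclass(frozen=True)
class AASub(_StrMixin):
    """Single-residue substitution; ``alt='Ter'`` encodes a nonsense change."""

    ref: str
    alt: str

    def __post_init__(self) -> None:
        for name in ("ref", "alt"):
            aa = getattr(self, name)
            if len(aa) == 1:
                _require(aa in AA1_TO_AA3, f"unknown amino acid {aa!r}")
                object.__setattr__(self, name, AA1_TO_AA3[aa])
            else:
                _require(aa in AA3_CODES, f"unknown amino acid {aa!r}")


@dataclass(frozen=True)
class AAIdentity(_StrMixin):
    """No protein change (``p.(=)`` when inferred)."""


@dataclass(frozen=True)
class AADelIns(_StrMixin):
    """Protein deletion / insertion / deletion-insertion.

    ``deleted`` says whether the residues in the interval are removed; ``alt``
    is the inserted residue run (3-letter codes, concatenated) or None.
    del: deleted, alt None.  ins: not deleted, alt set.  delins: both.
    """

    deleted: bool = True
    alt: Optional[str] = None

    def __post_init__(self) -> None:
        _require(self.deleted or self.alt,
                 "protein edit must delete residues, insert residues, or both")
        if self.alt is not None:
            _require(len(self.alt) % 3 == 0 and all(
                self.alt[i:i + 3] in AA3_CODES for i in range(0, len(self.alt), 3)),
                f"alt must be concatenated 3-letter amino acid codes, got {self.alt!r}")


@dataclass(frozen=True)
class AAFs(_StrMixin):
    """Frameshift starting at the anchored residue.

    ``alt`` is the first new-frame residue (or None when unstated);
    ``terminus`` is the 1-based distance to the first downstream stop in the
    new frame, counting the frameshifted residue as 1, or None when no stop
    is found before the end of the known sequence (rendered ``fs``).
    """

    alt: Optional[str] = None
    terminus: Optional[int] = None

    def __post_init__(self) -> None:
        if self.alt is not None:
            if len(self.alt) == 1:
                _require(self.alt in AA1_TO_AA3, f"unknown amino acid {self.alt!r}")
                object.__setattr__(self, "alt", AA1_TO_AA3[self.alt])
            else:
                _require(self.alt in AA3_CODES, f"unknown amino acid {self.alt!r}")
        if self.terminus is not None:
            _require(self.terminus >= 1, "terminus distance must be >= 1")


NAEdit = Union[NARefAlt, Dup, Repeat]
AAEdit = Union[AASub, AAIdentity, AADelIns, AAFs]
Edit = Union[NAEdit, AAEdit]


# ---------------------------------------------------------------------------
# PosEdit and SequenceVariant


@dataclass(frozen=True)
class PosEdit(_StrMixin):
    """A located edit.  ``pos`` may be None only for a bare protein ``(=)``.

    ``inferred`` marks a predicted (not observed) protein consequence and
    renders with surrounding parentheses, as in ``p.(Ala2Ser)``.
    """

    pos: Optional[Interval]
    edit: Edit
    inferred: bool = False

    def __post_init__(self) -> None:
        if self.pos is None:
            _require(isinstance(self.edit, AAIdentity),
                     "only a protein identity edit may omit its position")


_POSITION_KIND = {
    SequenceType.g: SimplePosition,
    SequenceType.m: SimplePosition,
    SequenceType.c: BaseOffsetPosition,
    SequenceType.n: BaseOffsetPosition,
    SequenceType.r: BaseOffsetPosition,
    SequenceType.p: AAPosition,
}


def _check_alphabet(stype: SequenceType, edit: Edit) -> None:
    if isinstance(edit, (AASub, AAIdentity, AADelIns, AAFs)):
        _require(stype is SequenceType.p,
                 f"protein edit illegal on sequence type {stype.value}")
        return
    _require(stype is not SequenceType.p,
             "nucleotide edit illegal on a protein variant")
    alphabet = RNA_ALPHABET if stype is SequenceType.r else DNA_ALPHABET
    label = "RNA" if stype is SequenceType.r else "DNA"
    strings = []
    if isinstance(edit, NARefAlt):
        strings = [s for s in (edit.ref, edit.alt) if s]
    elif isinstance(edit, Dup):
        strings = [edit.ref] if edit.ref else []
    elif isinstance(edit, Repeat):
        strings = [edit.unit]
    for s in strings:
        _require(all(ch in alphabet for ch in s),
                 f"{s!r} is not a {label} sequence (type {stype.value})")


@dataclass(frozen=True)
class SequenceVariant(_StrMixin):
    """A complete variant: accession, sequence type and posedit."""

    ac: str
    type: SequenceType
    posedit: PosEdit

    def __post_init__(self) -> None:
        _require(isinstance(self.ac, str) and len(self.ac) > 0,
                 "accession must be a non-empty string")
        if isinstance(self.type, str):
            object.__setattr__(self, "type", SequenceType(self.type))
        kind = _POSITION_KIND[self.type]
        iv = self.posedit.pos
        if iv is not None:
            for pos in (iv.start, iv.end):
                _require(isinstance(pos, kind),
                         f"{type(pos).__name__} is illegal for a {self.type.value}. variant")
                if isinstance(pos, BaseOffsetPosition) and self.type is SequenceType.n:
                    _require(pos.datum is Datum.SEQ_START,
                             "n. positions count from the transcript start")
                    _require(pos.base >= 1, "n. positions must be >= 1")
        _check_alphabet(self.type, self.posedit.edit)


# ---------------------------------------------------------------------------
# Classification


class VariantCategory(enum.Enum):
    SUB = "sub"
    DEL = "del"
    INS = "ins"
    DELINS = "delins"
    DUP = "dup"
    REPEAT = "repeat"
    IDENTITY = "identity"
    AA_SUB = "aa_sub"
    AA_DEL = "aa_del"
    AA_INS = "aa_ins"
    AA_DELINS = "aa_delins"
    AA_FS = "aa_fs"
    AA_IDENTITY = "aa_identity"


def variant_category(v: SequenceVariant) -> VariantCategory:
    """Classify a variant by its edit's union tag and ref/alt shape alone."""
    e = v.posedit.edit
    if isinstance(e, NARefAlt):
        if e.ref == e.alt and e.ref is not None:
            return VariantCategory.IDENTITY
        if e.alt is None:
            return VariantCategory.DEL
        if e.ref is None:
            return VariantCategory.DELINS if e.deleted else VariantCategory.INS
        if len(e.ref) == 1 and len(e.alt) == 1:
            return VariantCategory.SUB
        return VariantCategory.DELINS
    if isinstance(e, Dup):
        return VariantCategory.DUP
    if isinstance(e, Repeat):
        return VariantCategory.REPEAT
    if isinstance(e, AASub):
        return VariantCategory.AA_SUB
    if isinstance(e, AAIdentity):
        return VariantCategory.AA_IDENTITY
    if isinstance(e, AAFs):
        return VariantCategory.AA_FS
    if isinstance(e, AADelIns):
        if e.deleted and e.alt is None:
            return VariantCategory.AA_DEL
        if not e.deleted:
            return VariantCategory.AA_INS
        return VariantCategory.AA_DELINS
    raise TypeError(f"unknown edit type {type(e).__name__}")
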