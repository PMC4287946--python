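"""Canonical HGVS text rendering for every model object.

``format_hgvs`` is a pure function: equal objects always produce identical
bytes, and the output re-parses to an equal object.  Degenerate intervals
(start == end) render as a single position; inferred protein posedits are
wrapped in parentheses; protein residues use 3-letter codes by default with
an opt-in 1-letter mode.
"""

from __future__ import annotations

from functools import singledispatch
from typing import Union

from . import models as m

__all__ = ["format_hgvs", "as_rna"]

_RNA_COMPLEMENTARY_TYPES = (m.NARefAlt, m.Dup, m.Repeat)


@singledispatch
def format_hgvs(obj, *, one_letter_aa: bool = False) -> str:
    """Render a variant, posedit, interval, position or edit as HGVS text."""
    raise TypeError(f"cannot format object of type {type(obj).__name__}")


@format_hgvs.register
def _(obj: m.SequenceVariant, *, one_letter_aa: bool = False) -> str:
    pe = format_hgvs(obj.posedit, one_letter_aa=one_letter_aa)
    return f"{obj.ac}:{obj.type.value}.{pe}"


@format_hgvs.register
def _(obj: m.PosEdit, *, one_letter_aa: bool = False) -> str:
    edit = format_hgvs(obj.edit, one_letter_aa=one_letter_aa)
    if obj.pos is None:
        body = edit
    else:
        body = format_hgvs(obj.pos, one_letter_aa=one_letter_aa) + edit
    return f"({body})" if obj.inferred else body


@format_hgvs.register
def _(obj: m.Interval, *, one_letter_aa: bool = False) -> str:
    s = format_hgvs(obj.start, one_letter_aa=one_letter_aa)
    if obj.is_point:
        return s
    return f"{s}_{format_hgvs(obj.end, one_letter_aa=one_letter_aa)}"


# -- positions --------------------------------------------------------------


@format_hgvs.register
def _(obj: m.SimplePosition, *, one_letter_aa: bool = False) -> str:
    return str(obj.base)


@format_hgvs.register
def _(obj: m.BaseOffsetPosition, *, one_letter_aa: bool = False) -> str:
    star = "*" if obj.datum is m.Datum.CDS_END else ""
    off = f"{obj.offset:+d}" if obj.offset else ""
    return f"{star}{obj.base}{off}"


def _aa(code3: str, one_letter: bool) -> str:
    return m.AA3_TO_AA1[code3] if one_letter else code3


def _aa_run(codes: str, one_letter: bool) -> str:
    return "".join(_aa(codes[i:i + 3], one_letter) for i in range(0, len(codes), 3))


@format_hgvs.register
def _(obj: m.AAPosition, *, one_letter_aa: bool = False) -> str:
    return f"{_aa(obj.aa, one_letter_aa)}{obj.base}"


# -- nucleotide edits -------------------------------------------------------


@format_hgvs.register
def _(obj: m.NARefAlt, *, one_letter_aa: bool = False) -> str:
    if obj.ref is not None and obj.alt is not None \
            and len(obj.ref) == 1 and len(obj.alt) == 1:
        # includes ref == alt: 'A>A' is the canonical single-base identity
        return f"{obj.ref}>{obj.alt}"
    if obj.ref == obj.alt and obj.ref is not None:
        return f"{obj.ref}="
    if obj.alt is None:
        return f"del{obj.ref or ''}"
    if obj.ref is None:
        return f"delins{obj.alt}" if obj.deleted else f"ins{obj.alt}"
    return f"del{obj.ref}ins{obj.alt}"


@format_hgvs.register
def _(obj: m.Dup, *, one_letter_aa: bool = False) -> str:
    return f"dup{obj.ref or ''}"


@format_hgvs.register
def _(obj: m.Repeat, *, one_letter_aa: bool = False) -> str:
    bounds = str(obj.min) if obj.min == obj.max else f"{obj.min}_{obj.max}"
    return f"{obj.unit}[{bounds}]"


# -- protein edits ----------------------------------------------------------


@format_hgvs.register
def _(obj: m.AASub, *, one_letter_aa: bool = False) -> str:
    return _aa(obj.alt, one_letter_aa)


@format_hgvs.register
def _(obj: m.AAIdentity, *, one_letter_aa: bool = False) -> str:
    return "="


@format_hgvs.register
def _(obj: m.AADelIns, *, one_letter_aa: bool = False) -> str:
    alt = _aa_run(obj.alt, one_letter_aa) if obj.alt else ""
    if obj.deleted and obj.alt is None:
        return "del"
    if not obj.deleted:
        return f"ins{alt}"
    return f"delins{alt}"


@format_hgvs.register
def _(obj: m.AAFs, *, one_letter_aa: bool = False) -> str:
    alt = _aa(obj.alt, one_letter_aa) if obj.alt else ""
    if obj.terminus is None:
        return f"{alt}fs"
    ter = "*" if one_letter_aa else "Ter"
    return f"{alt}fs{ter}{obj.terminus}"


# -- RNA transliteration ----------------------------------------------------

_DNA_TO_RNA = str.maketrans("ACGT", "acgu")


def _edit_to_rna(edit: m.Edit) -> m.Edit:
    def tr(s):
        return s.translate(_DNA_TO_RNA) if s is not None else None

    if isinstance(edit, m.NARefAlt):
        return m.NARefAlt(tr(edit.ref), tr(edit.alt))
    if isinstance(edit, m.Dup):
        return m.Dup(tr(edit.ref))
    if isinstance(edit, m.Repeat):
        return m.Repeat(tr(edit.unit), edit.min, edit.max)
    raise TypeError(f"cannot transliterate edit {type(edit).__name__} to RNA")


def as_rna(variant: m.SequenceVariant) -> m.SequenceVariant:
    """Re-express a c. or n. variant as r. by alphabet transliteration.

    Coordinates are unchanged — an r. position on a coding transcript uses
    the same CDS-relative numbering as c. — so only the nucleotide alphabet
    (upper-case DNA to lower-case RNA) and the type letter change.
    """
    if variant.type not in (m.SequenceType.c, m.SequenceType.n):
        raise TypeError(f"cannot transliterate a {variant.type.value}. variant to r.")
    pe = variant.posedit
    return m.SequenceVariant(
        ac=variant.ac,
        type=m.SequenceType.r,
        posedit=m.PosEdit(pe.pos, _edit_to_rna(pe.edit), pe.inferred),
    )
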