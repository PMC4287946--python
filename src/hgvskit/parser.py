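"""Recursive-descent HGVS parser with independently invocable named rules.

The grammar is organised as a registry of named productions, any of which can
be used as an entry point through :meth:`HgvsParser.parse_rule` — e.g.
``parse_rule("c_posedit", "688+403C>T")`` returns a ``PosEdit`` while
``parse_rule("base_offset_position", "88-2")`` returns a single position.
The start rule ``hgvs_variant`` parses a complete ``accession:type.posedit``
string; every rule consumes its entire input, so trailing garbage is a
syntax error rather than a silent truncation.

Accepted syntax covers the six sequence types (g/m/c/n/r/p) and the edit
kinds substitution, del, ins, delins, dup, repeat and identity on nucleotide
sequences, and substitution, del/ins/delins, frameshift and identity on
proteins.  Deliberately out of scope, mirroring the library's documented
limitations: compound alleles (``[...;...]``), mosaic/chimeric variants,
inversions, conversions and uncertain positions.
"""

from __future__ import annotations

import re
import warnings
from typing import Callable, Dict, Optional

from . import models as m

__all__ = ["HgvsParser", "HgvsParseError", "parse", "parse_rule"]


class HgvsParseError(ValueError):
    """Syntax error with the failing offset and the deepest rule attempted."""

    def __init__(self, message: str, text: str, pos: int, rule: str):
        self.text = text
        self.pos = pos
        self.rule = rule
        super().__init__(f"{message} (rule {rule!r}, char {pos} in {text!r})")


_ACCESSION_RE = re.compile(r"[A-Za-z][A-Za-z0-9_.-]*")
_GENE_RE = re.compile(r"\(([A-Za-z0-9_-]+)\)")
_NUM_RE = re.compile(r"\d+")
_DNA_RE = re.compile(r"[ACGT]+")
_RNA_RE = re.compile(r"[acgu]+")
_AA3_RE = re.compile("|".join(sorted(m.AA3_CODES, key=len, reverse=True)))
_AA1_RE = re.compile(r"[ARNDCQEGHILKMFPSTWYV*]")


class _Cursor:
    __slots__ = ("text", "pos", "rule")

    def __init__(self, text: str, rule: str):
        self.text = text
        self.pos = 0
        self.rule = rule

    def match(self, regex: re.Pattern) -> Optional[str]:
        mo = regex.match(self.text, self.pos)
        if mo is None:
            return None
        self.pos = mo.end()
        return mo.group(0)

    def literal(self, lit: str) -> bool:
        if self.text.startswith(lit, self.pos):
            self.pos += len(lit)
            return True
        return False

    def peek(self, lit: str) -> bool:
        return self.text.startswith(lit, self.pos)

    def at_end(self) -> bool:
        return self.pos >= len(self.text)

    def fail(self, message: str):
        raise HgvsParseError(message, self.text, self.pos, self.rule)


class HgvsParser:
    """Parser over the HGVS grammar; stateless and safe to share."""

    def __init__(self) -> None:
        self._rules: Dict[str, Callable[[_Cursor], object]] = {
            "hgvs_variant": self._r_hgvs_variant,
            "accession": self._r_accession,
            "simple_position": self._r_simple_position,
            "base_offset_position": self._r_base_offset_position,
            "aa_position": self._r_aa_position,
            "g_interval": self._r_g_interval,
            "m_interval": self._r_g_interval,
            "c_interval": lambda c: self._r_bo_interval(c, allow_utr=True),
            "n_interval": lambda c: self._r_bo_interval(c, allow_utr=False),
            "r_interval": lambda c: self._r_bo_interval(c, allow_utr=True),
            "p_interval": self._r_p_interval,
            "dna_edit": lambda c: self._r_na_edit(c, _DNA_RE, "DNA"),
            "rna_edit": lambda c: self._r_na_edit(c, _RNA_RE, "RNA"),
            "pro_edit": self._r_pro_edit_entry,
            "g_posedit": lambda c: self._r_na_posedit(c, "g"),
            "m_posedit": lambda c: self._r_na_posedit(c, "m"),
            "c_posedit": lambda c: self._r_na_posedit(c, "c"),
            "n_posedit": lambda c: self._r_na_posedit(c, "n"),
            "r_posedit": lambda c: self._r_na_posedit(c, "r"),
            "p_posedit": self._r_p_posedit,
            "g_variant": lambda c: self._r_typed_variant(c, "g"),
            "m_variant": lambda c: self._r_typed_variant(c, "m"),
            "c_variant": lambda c: self._r_typed_variant(c, "c"),
            "n_variant": lambda c: self._r_typed_variant(c, "n"),
            "r_variant": lambda c: self._r_typed_variant(c, "r"),
            "p_variant": lambda c: self._r_typed_variant(c, "p"),
        }

    @property
    def rule_names(self):
        return sorted(self._rules)

    def parse(self, text: str) -> m.SequenceVariant:
        """Parse a complete HGVS variant string."""
        return self.parse_rule("hgvs_variant", text)

    def parse_rule(self, rule: str, text: str):
        """Parse ``text`` with the named production, consuming all input."""
        try:
            fn = self._rules[rule]
        except KeyError:
            raise KeyError(
                f"unknown grammar rule {rule!r}; known rules: {', '.join(self.rule_names)}"
            ) from None
        if not isinstance(text, str):
            raise HgvsParseError("input must be a string", repr(text), 0, rule)
        cur = _Cursor(text, rule)
        try:
            result = fn(cur)
        except m.HgvsModelError as exc:
            raise HgvsParseError(str(exc), text, cur.pos, cur.rule) from exc
        if not cur.at_end():
            cur.fail("trailing characters after a complete parse")
        return result

    # -- top level ---------------------------------------------------------

    def _r_hgvs_variant(self, cur: _Cursor) -> m.SequenceVariant:
        cur.rule = "hgvs_variant"
        ac = self._r_accession(cur)
        gene = cur.match(_GENE_RE)
        if gene is not None:
            warnings.warn(
                f"gene symbol annotation {gene} on {ac} is accepted but discarded",
                stacklevel=3)
        if not cur.literal(":"):
            cur.fail("expected ':' after accession")
        stype = self.__type_letter(cur)
        posedit = self.__posedit_for(cur, stype)
        return m.SequenceVariant(ac=ac, type=m.SequenceType(stype), posedit=posedit)

    def _r_typed_variant(self, cur: _Cursor, stype: str) -> m.SequenceVariant:
        cur.rule = f"{stype}_variant"
        ac = self._r_accession(cur)
        cur.match(_GENE_RE)
        if not cur.literal(":"):
            cur.fail("expected ':' after accession")
        got = self.__type_letter(cur)
        if got != stype:
            cur.fail(f"expected a {stype}. variant, found {got}.")
        posedit = self.__posedit_for(cur, stype)
        return m.SequenceVariant(ac=ac, type=m.SequenceType(stype), posedit=posedit)

    def __type_letter(self, cur: _Cursor) -> str:
        for letter in "gmcnrp":
            if cur.peek(letter + "."):
                cur.pos += 2
                return letter
        cur.fail("expected sequence type prefix g./m./c./n./r./p.")

    def __posedit_for(self, cur: _Cursor, stype: str) -> m.PosEdit:
        if stype == "p":
            return self._r_p_posedit(cur)
        return self._r_na_posedit(cur, stype)

    def _r_accession(self, cur: _Cursor) -> str:
        cur.rule = "accession"
        ac = cur.match(_ACCESSION_RE)
        if ac is None:
            cur.fail("expected an accession (letter followed by [A-Za-z0-9_.-])")
        return ac

    # -- positions ---------------------------------------------------------

    def _r_simple_position(self, cur: _Cursor) -> m.SimplePosition:
        cur.rule = "simple_position"
        num = cur.match(_NUM_RE)
        if num is None:
            cur.fail("expected a 1-based position")
        if num.startswith("0"):
            cur.fail("positions may not have leading zeros" if len(num) > 1
                     else "HGVS positions are 1-based; 0 is not a position")
        return m.SimplePosition(int(num))

    def _r_base_offset_position(
        self, cur: _Cursor, *, allow_utr: bool = True, datum_default: m.Datum = m.Datum.CDS_START,
    ) -> m.BaseOffsetPosition:
        cur.rule = "base_offset_position"
        datum = datum_default
        sign = 1
        if cur.literal("*"):
            if not allow_utr:
                cur.fail("'*' (3'-UTR) positions are only legal on c./r. sequences")
            datum = m.Datum.CDS_END
        elif cur.literal("-"):
            if not allow_utr:
                cur.fail("negative (5'-UTR) positions are only legal on c./r. sequences")
            sign = -1
        num = cur.match(_NUM_RE)
        if num is None:
            cur.fail("expected a base position")
        if num.startswith("0"):
            cur.fail("base 0 / leading zeros are not legal HGVS positions")
        base = sign * int(num)
        offset = 0
        if cur.peek("+") or cur.peek("-"):
            osign = -1 if cur.text[cur.pos] == "-" else 1
            cur.pos += 1
            onum = cur.match(_NUM_RE)
            if onum is None or onum.startswith("0"):
                cur.fail("expected a positive intronic offset")
            offset = osign * int(onum)
        if datum_default is m.Datum.SEQ_START and datum is m.Datum.SEQ_START:
            return m.BaseOffsetPosition(base, offset, m.Datum.SEQ_START)
        return m.BaseOffsetPosition(base, offset, datum)

    def _r_aa_position(self, cur: _Cursor) -> m.AAPosition:
        cur.rule = "aa_position"
        aa = self.__aa_token(cur)
        if aa is None:
            cur.fail("expected an amino acid (3-letter or 1-letter code)")
        num = cur.match(_NUM_RE)
        if num is None or num.startswith("0"):
            cur.fail("expected a 1-based residue number")
        return m.AAPosition(int(num), aa)

    def __aa_token(self, cur: _Cursor) -> Optional[str]:
        tok = cur.match(_AA3_RE)
        if tok is not None:
            return tok
        tok = cur.match(_AA1_RE)
        return tok

    # -- intervals ---------------------------------------------------------

    def _r_g_interval(self, cur: _Cursor) -> m.Interval:
        cur.rule = "g_interval"
        start = self._r_simple_position(cur)
        cur.rule = "g_interval"
        if cur.literal("_"):
            end = self._r_simple_position(cur)
        else:
            end = start
        return m.Interval(start, end)

    def _r_bo_interval(self, cur: _Cursor, *, allow_utr: bool) -> m.Interval:
        cur.rule = "c_interval" if allow_utr else "n_interval"
        datum = m.Datum.CDS_START if allow_utr else m.Datum.SEQ_START
        start = self._r_base_offset_position(cur, allow_utr=allow_utr, datum_default=datum)
        cur.rule = "c_interval" if allow_utr else "n_interval"
        if cur.literal("_"):
            end = self._r_base_offset_position(cur, allow_utr=allow_utr, datum_default=datum)
        else:
            end = start
        return m.Interval(start, end)

    def _r_p_interval(self, cur: _Cursor) -> m.Interval:
        cur.rule = "p_interval"
        start = self._r_aa_position(cur)
        cur.rule = "p_interval"
        if cur.literal("_"):
            end = self._r_aa_position(cur)
        else:
            end = start
        return m.Interval(start, end)

    # -- nucleotide posedits / edits ---------------------------------------

    def _r_na_posedit(self, cur: _Cursor, stype: str) -> m.PosEdit:
        cur.rule = f"{stype}_posedit"
        if stype in ("g", "m"):
            iv = self._r_g_interval(cur)
        elif stype == "n":
            iv = self._r_bo_interval(cur, allow_utr=False)
        else:
            iv = self._r_bo_interval(cur, allow_utr=True)
        seq_re = _RNA_RE if stype == "r" else _DNA_RE
        label = "RNA" if stype == "r" else "DNA"
        cur.rule = f"{stype}_posedit"
        edit = self._r_na_edit(cur, seq_re, label)
        return m.PosEdit(pos=iv, edit=edit)

    def _r_na_edit(self, cur: _Cursor, seq_re: re.Pattern, label: str) -> m.Edit:
        cur.rule = f"{label.lower()}_edit"
        seq = cur.match(seq_re)
        if seq is not None:
            if cur.literal(">"):
                alt = cur.match(seq_re)
                if alt is None:
                    cur.fail(f"expected a {label} base after '>'")
                if len(seq) != 1 or len(alt) != 1:
                    cur.fail("substitution requires exactly one base on each side of '>'")
                return m.NARefAlt(ref=seq, alt=alt)
            if cur.literal("="):
                return m.NARefAlt(ref=seq, alt=seq)
            if cur.literal("["):
                return self.__repeat_bounds(cur, seq)
            cur.fail(f"expected '>', '=' or '[' after {label} sequence")
        if cur.literal("del"):
            ref = cur.match(seq_re)
            if cur.literal("ins"):
                alt = cur.match(seq_re)
                if alt is None:
                    cur.fail(f"expected an inserted {label} sequence after 'ins'")
                return m.NARefAlt(ref=ref, alt=alt, deleted=ref is None)
            return m.NARefAlt(ref=ref, alt=None)
        if cur.literal("ins"):
            alt = cur.match(seq_re)
            if alt is None:
                cur.fail(f"expected an inserted {label} sequence after 'ins'")
            return m.NARefAlt(ref=None, alt=alt)
        if cur.literal("dup"):
            ref = cur.match(seq_re)
            return m.Dup(ref=ref)
        if cur.literal("="):
            return m.NARefAlt(ref="", alt="")
        cur.fail(f"expected a {label} edit (substitution, del, ins, delins, dup, "
                 "repeat or '=')")

    def __repeat_bounds(self, cur: _Cursor, unit: str) -> m.Repeat:
        lo = cur.match(_NUM_RE)
        if lo is None:
            cur.fail("expected a repeat count after '['")
        hi = lo
        if cur.literal("_"):
            hi = cur.match(_NUM_RE)
            if hi is None:
                cur.fail("expected an upper repeat bound after '_'")
        if not cur.literal("]"):
            cur.fail("expected ']' closing the repeat count")
        try:
            return m.Repeat(unit=unit, min=int(lo), max=int(hi))
        except m.HgvsModelError as exc:
            cur.fail(str(exc))

    # -- protein posedits / edits ------------------------------------------

    def _r_p_posedit(self, cur: _Cursor) -> m.PosEdit:
        cur.rule = "p_posedit"
        inferred = cur.literal("(")
        pe = self.__p_posedit_body(cur)
        if inferred and not cur.literal(")"):
            cur.fail("expected ')' closing an inferred protein change")
        return m.PosEdit(pe.pos, pe.edit, inferred=inferred)

    def _r_pro_edit_entry(self, cur: _Cursor):
        pe = self.__p_posedit_body(cur)
        return pe.edit if pe.pos is None else pe

    def __p_posedit_body(self, cur: _Cursor) -> m.PosEdit:
        cur.rule = "p_posedit"
        if cur.literal("="):
            return m.PosEdit(pos=None, edit=m.AAIdentity())
        iv = self._r_p_interval(cur)
        cur.rule = "pro_edit"
        if cur.literal("fs"):
            return m.PosEdit(iv, self.__fs_tail(cur, alt=None))
        if cur.literal("delins"):
            alt = self.__aa_run(cur)
            if alt is None:
                cur.fail("expected inserted residues after 'delins'")
            return m.PosEdit(iv, m.AADelIns(deleted=True, alt=alt))
        if cur.literal("del"):
            return m.PosEdit(iv, m.AADelIns(deleted=True, alt=None))
        if cur.literal("ins"):
            alt = self.__aa_run(cur)
            if alt is None:
                cur.fail("expected inserted residues after 'ins'")
            return m.PosEdit(iv, m.AADelIns(deleted=False, alt=alt))
        if cur.literal("="):
            return m.PosEdit(iv, m.AAIdentity())
        alt = self.__aa_token(cur)
        if alt is not None:
            if cur.literal("fs"):
                return m.PosEdit(iv, self.__fs_tail(cur, alt=alt))
            if not iv.is_point:
                cur.fail("a substitution takes a single residue position")
            return m.PosEdit(iv, m.AASub(ref=iv.start.aa, alt=alt))
        cur.fail("expected a protein edit (substitution, fs, del, ins, delins or '=')")

    def __fs_tail(self, cur: _Cursor, alt: Optional[str]) -> m.AAFs:
        if cur.literal("Ter") or cur.literal("*"):
            if cur.literal("?"):
                return m.AAFs(alt=alt, terminus=None)
            num = cur.match(_NUM_RE)
            if num is None:
                cur.fail("expected the new-frame stop distance (or '?') after 'Ter'")
            return m.AAFs(alt=alt, terminus=int(num))
        return m.AAFs(alt=alt, terminus=None)

    def __aa_run(self, cur: _Cursor) -> Optional[str]:
        parts = []
        while True:
            tok = self.__aa_token(cur)
            if tok is None:
                break
            parts.append(tok if len(tok) == 3 else m.AA1_TO_AA3[tok])
        return "".join(parts) if parts else None


_DEFAULT = HgvsParser()


def parse(text: str) -> m.SequenceVariant:
    """Parse a complete HGVS variant string with the shared default parser."""
    return _DEFAULT.parse(text)


def parse_rule(rule: str, text: str):
    """Parse ``text`` under any named grammar rule (module-level convenience)."""
    return _DEFAULT.parse_rule(rule, text)
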