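"""Independent brute-force oracles used to cross-check the implementation.

Nothing here imports the alignment-map or protein-inference code paths it
checks: the per-base coordinate table is built by literally walking the
alignment one base at a time, and the protein classifier works directly on
the two translations.
"""

from __future__ import annotations

import re
from typing import Dict, Optional, Tuple

from Bio.Seq import Seq


def per_base_table(rec) -> Tuple[Dict[int, Tuple[int, int, bool]],
                                 Dict[int, Tuple[int, bool]]]:
    """Walk a transcript's alignment base by base, in transcript orientation.

    Returns ``(g2n, n2g)``:

    * ``g2n[g] = (n_base, offset, gap)`` for every 1-based genomic base in
      the transcript span — exonic bases get their exact n with offset 0;
      intronic bases get the nearest exon-boundary n with a signed offset
      (ties to the transcript-5' boundary); genome-only (D) bases get the
      clamped 5' n with gap=True.
    * ``n2g[n] = (g, gap)`` for every transcript base — transcript-only (I)
      bases clamp to the genomic base just visited (5') with gap=True.
    """
    plus = rec.strand == 1
    events = []  # ('M'|'D'|'I'|'intron', g or None), transcript orientation
    exons = rec.exons if plus else tuple(reversed(rec.exons))
    prev = None
    for exon in exons:
        if prev is not None:
            rng = (range(prev.g_end + 1, exon.g_start) if plus
                   else range(prev.g_start - 1, exon.g_end, -1))
            for g in rng:
                events.append(("intron", g))
        segs = exon.segments if plus else tuple(reversed(exon.segments))
        g = exon.g_start if plus else exon.g_end
        step = 1 if plus else -1
        for seg in segs:
            for _ in range(seg.length):
                if seg.op == "I":
                    events.append(("I", None))
                else:
                    events.append((seg.op, g))
                    g += step
        prev = exon

    g2n: Dict[int, Tuple[int, int, bool]] = {}
    n2g: Dict[int, Tuple[int, bool]] = {}
    n = 0
    prev_g: Optional[int] = None
    intron_run = []
    n_at_5 = 0

    def flush() -> None:
        length = len(intron_run)
        for idx, g in enumerate(intron_run):
            d5, d3 = idx + 1, length - idx
            if d5 <= d3:
                g2n[g] = (n_at_5, d5, False)
            else:
                g2n[g] = (n_at_5 + 1, -d3, False)
        intron_run.clear()

    for kind, g in events:
        if kind == "intron":
            if not intron_run:
                n_at_5 = n
            intron_run.append(g)
            continue
        flush()
        if kind == "M":
            n += 1
            g2n[g] = (n, 0, False)
            n2g[n] = (g, False)
            prev_g = g
        elif kind == "D":
            g2n[g] = (max(n, 1), 0, True)
            prev_g = g
        else:  # I
            n += 1
            n2g[n] = (prev_g, True)
    flush()
    return g2n, n2g


# ---------------------------------------------------------------------------
# Regular-expression decomposition of the delins string family


_DELINS_RE = re.compile(
    r"^(?P<ac>[A-Za-z][A-Za-z0-9_.-]*):(?P<type>[gmcn])\."
    r"(?P<start>-?\d+|\*\d+)(?:_(?P<end>-?\d+|\*\d+))?"
    r"del(?P<ref>[ACGT]*)ins(?P<alt>[ACGT]+)$")


def decompose_delins(text: str):
    """Regex decomposition of simple (offset-free) delins strings."""
    mo = _DELINS_RE.match(text)
    if mo is None:
        return None
    d = mo.groupdict()
    d["end"] = d["end"] or d["start"]
    d["ref"] = d["ref"] or None
    return d


# ---------------------------------------------------------------------------
# Translate-and-diff protein classification


def translate_all(seq: str) -> str:
    """1-letter translation of the longest whole-codon prefix, cut at the
    first stop (stop included as '*')."""
    aa = str(Seq(seq[:len(seq) - len(seq) % 3]).translate())
    i = aa.find("*")
    return aa[:i + 1] if i >= 0 else aa


def apply_nt_edit(region: str, c_start: int, c_end: int, kind: str,
                  alt: str = "") -> str:
    """Apply an edit to the CDS+3'UTR string (c.1 at index 0), brute force."""
    s0, e0 = c_start - 1, c_end
    if kind == "sub" or kind == "delins":
        return region[:s0] + alt + region[e0:]
    if kind == "del":
        return region[:s0] + region[e0:]
    if kind == "ins":  # between c_start and c_end = c_start+1
        return region[:c_start] + alt + region[c_start:]
    if kind == "dup":
        return region[:e0] + region[s0:e0] + region[e0:]
    raise ValueError(kind)


def protein_expectation(ref_aa: str, alt_aa: str) -> dict:
    """Structural facts about the ref->alt protein change.

    ``first_diff`` is the 1-based first differing residue (None if the
    translations are identical); ``stop_dist`` is the distance from that
    residue to the first stop in the new translation (counting the residue
    itself as 1), or None when no stop is reached.
    """
    if ref_aa == alt_aa:
        return {"identical": True}
    limit = min(len(ref_aa), len(alt_aa))
    i = next((k for k in range(limit) if ref_aa[k] != alt_aa[k]), limit)
    stop = alt_aa.find("*", i)
    return {
        "identical": False,
        "first_diff": i + 1,
        "ref_res": ref_aa[i] if i < len(ref_aa) else None,
        "alt_res": alt_aa[i] if i < len(alt_aa) else None,
        "stop_dist": stop - i + 1 if stop >= 0 else None,
        "n_diffs_same_len": (sum(a != b for a, b in zip(ref_aa, alt_aa))
                             if len(ref_aa) == len(alt_aa) else None),
    }
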