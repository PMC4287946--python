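"""Reference-data access: transcript records, the provider interface and a
file-backed fixture provider.

Mapping and extrinsic validation need sequences and genome-transcript
alignments.  The :class:`DataProvider` abstract base declares the seven
query methods the rest of the package consumes; :class:`FixtureProvider`
implements them over a :class:`LocusFixture` — a self-contained bundle of
FASTA sequences plus structured transcript metadata that a synthetic-locus
generator (see :mod:`hgvskit.synth`) emits.  All coordinates in records and
fixture files are 1-based and inclusive; alignment discrepancies between a
transcript and its genomic reference are run-length segment lists per exon
(M aligned, D genome-only, I transcript-only).
"""

from __future__ import annotations

import abc
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignmentSegment",
    "Exon",
    "TranscriptRecord",
    "LocusFixture",
    "DataProvider",
    "FixtureProvider",
    "DataProviderError",
    "UnknownAccessionError",
    "UnknownAlignmentMethodError",
    "SequenceRangeError",
    "RecordInvariantError",
    "implied_transcript_seq",
    "revcomp",
]


class DataProviderError(Exception):
    """Base class for provider lookup and range failures."""


class UnknownAccessionError(DataProviderError, KeyError):
    """The requested sequence, transcript or gene is not known."""


class UnknownAlignmentMethodError(DataProviderError, KeyError):
    """The transcript is known but not under the requested alignment method."""


class SequenceRangeError(DataProviderError, ValueError):
    """A sequence slice is empty, inverted or out of bounds."""


class RecordInvariantError(ValueError):
    """A transcript record violates its structural invariants."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Records


@dataclass(frozen=True)
class AlignmentSegment:
    """Run-length alignment operation within one exon.

    op 'M': aligned bases present on both sides; 'D': genome-only bases
    (absent from the transcript); 'I': transcript-only bases (absent from
    the genome).  Segments are stored in genomic-ascending order.
    """

    op: str
    length: int

    def __post_init__(self) -> None:
        if self.op not in ("M", "D", "I"):
            raise RecordInvariantError(f"segment op must be M, D or I, got {self.op!r}")
        if self.length < 1:
            raise RecordInvariantError(f"segment length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class Exon:
    """Genomic exon span (1-based inclusive) with its alignment segments."""

    g_start: int
    g_end: int
    segments: Tuple[AlignmentSegment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def g_length(self) -> int:
        return self.g_end - self.g_start + 1

    @property
    def tx_length(self) -> int:
        return sum(s.length for s in self.segments if s.op in ("M", "I"))


@dataclass(frozen=True)
class TranscriptRecord:
    """Everything needed to map between a transcript and its reference.

    Exons are stored in genomic-ascending order regardless of strand; the
    strand flag (+1/-1) determines transcript-order traversal.  CDS bounds
    are transcript (n.) coordinates, or None for a non-coding transcript.
    """

    tx_ac: str
    gene: str
    strand: int
    ref_ac: str
    exons: Tuple[Exon, ...]
    cds_start_n: Optional[int] = None
    cds_end_n: Optional[int] = None
    aln_method: str = "splign"
    pro_ac: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        if self.strand not in (1, -1):
            raise RecordInvariantError(f"strand must be +1 or -1, got {self.strand!r}")

    # -- derived geometry --------------------------------------------------

    @property
    def g_start(self) -> int:
        return self.exons[0].g_start

    @property
    def g_end(self) -> int:
        return self.exons[-1].g_end

    @property
    def tx_length(self) -> int:
        return sum(e.tx_length for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start_n is not None

    def exons_tx_order(self) -> Tuple[Exon, ...]:
        """Exons ordered 5'→3' along the transcript (computed, not stored)."""
        return self.exons if self.strand == 1 else tuple(reversed(self.exons))

    def validate(self, tx_len: Optional[int] = None) -> None:
        """Raise :class:`RecordInvariantError` on any structural violation."""
        if not self.exons:
            raise RecordInvariantError(f"{self.tx_ac}: transcript has no exons")
        prev_end = None
        for i, e in enumerate(self.exons, 1):
            if e.g_start > e.g_end:
                raise RecordInvariantError(
                    f"{self.tx_ac} exon {i}: inverted span {e.g_start}..{e.g_end}")
            if prev_end is not None and e.g_start <= prev_end:
                raise RecordInvariantError(
                    f"{self.tx_ac} exon {i}: overlaps or touches previous exon")
            prev_end = e.g_end
            if not e.segments:
                raise RecordInvariantError(f"{self.tx_ac} exon {i}: no segments")
            g_side = sum(s.length for s in e.segments if s.op in ("M", "D"))
            if g_side != e.g_length:
                raise RecordInvariantError(
                    f"{self.tx_ac} exon {i}: genomic segment lengths sum to "
                    f"{g_side}, span is {e.g_length}")
            for a, b in zip(e.segments, e.segments[1:]):
                if a.op == b.op:
                    raise RecordInvariantError(
                        f"{self.tx_ac} exon {i}: adjacent segments share op {a.op}")
        if tx_len is not None and self.tx_length != tx_len:
            raise RecordInvariantError(
                f"{self.tx_ac}: transcript-side segment lengths sum to "
                f"{self.tx_length}, sequence length is {tx_len}")
        if (self.cds_start_n is None) != (self.cds_end_n is None):
            raise RecordInvariantError(
                f"{self.tx_ac}: CDS bounds must both be set or both absent")
        if self.cds_start_n is not None:
            if not (1 <= self.cds_start_n < self.cds_end_n <= self.tx_length):
                raise RecordInvariantError(
                    f"{self.tx_ac}: CDS bounds {self.cds_start_n}..{self.cds_end_n} "
                    f"outside 1..{self.tx_length}")


def implied_transcript_seq(rec: TranscriptRecord, contig_seq: str, tx_seq: str) -> str:
    """Transcript sequence implied by splicing the record against its contig.

    M segments copy genomic bases (reverse-complemented for minus-strand
    transcripts), D segments skip genomic bases, and I segments take their
    bases from ``tx_seq`` (they exist nowhere else).  A fixture is
    self-consistent exactly when the result equals ``tx_seq``.
    """
    out: List[str] = []
    tx_pos = 0  # 0-based cursor into tx_seq
    for exon in rec.exons_tx_order():
        segs = exon.segments if rec.strand == 1 else tuple(reversed(exon.segments))
        # genomic cursor at the transcript-5' end of the exon
        g = exon.g_start - 1 if rec.strand == 1 else exon.g_end
        for seg in segs:
            if seg.op == "M":
                if rec.strand == 1:
                    piece = contig_seq[g:g + seg.length]
                    g += seg.length
                else:
                    piece = revcomp(contig_seq[g - seg.length:g])
                    g -= seg.length
                out.append(piece)
                tx_pos += seg.length
            elif seg.op == "D":
                g += seg.length if rec.strand == 1 else -seg.length
            else:  # I
                out.append(tx_seq[tx_pos:tx_pos + seg.length])
                tx_pos += seg.length
    return "".join(out)


# ---------------------------------------------------------------------------
# Fixture bundle


_FIXTURE_FORMAT_NOTE = (
    "All coordinates are 1-based inclusive genomic positions on ref_ac. "
    "Exon 'segments' are run-length alignment operations in genomic order: "
    "M aligned, D genome-only, I transcript-only. cds_start_n/cds_end_n are "
    "transcript (n.) coordinates."
)


@dataclass
class LocusFixture:
    """A self-contained locus: sequences, transcript records and provenance."""

    sequences: Dict[str, str]
    records: Tuple[TranscriptRecord, ...]
    seed: Optional[int] = None
    params: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = tuple(self.records)

    def validate(self) -> None:
        """Check every record's invariants and fixture self-consistency."""
        for rec in self.records:
            for ac in (rec.ref_ac, rec.tx_ac):
                if ac not in self.sequences:
                    raise RecordInvariantError(f"fixture lacks sequence {ac}")
            tx_seq = self.sequences[rec.tx_ac]
            rec.validate(tx_len=len(tx_seq))
            implied = implied_transcript_seq(rec, self.sequences[rec.ref_ac], tx_seq)
            if implied != tx_seq:
                raise RecordInvariantError(
                    f"{rec.tx_ac} ({rec.aln_method}): implied transcript sequence "
                    "differs from the stored sequence")

    # -- persistence -------------------------------------------------------

    def write(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        seqs = [SeqRecord(Seq(s), id=ac, description="") for ac, s in
                sorted(self.sequences.items())]
        SeqIO.write(seqs, directory / "sequences.fa", "fasta")
        doc = {
            "format": "hgvskit-locus-fixture/1",
            "note": _FIXTURE_FORMAT_NOTE,
            "seed": self.seed,
            "params": self.params,
            "transcripts": [
                {
                    "tx_ac": r.tx_ac,
                    "gene": r.gene,
                    "strand": r.strand,
                    "ref_ac": r.ref_ac,
                    "aln_method": r.aln_method,
                    "pro_ac": r.pro_ac,
                    "cds_start_n": r.cds_start_n,
                    "cds_end_n": r.cds_end_n,
                    "exons": [
                        {
                            "g_start": e.g_start,
                            "g_end": e.g_end,
                            "segments": [[s.op, s.length] for s in e.segments],
                        }
                        for e in r.exons
                    ],
                }
                for r in self.records
            ],
        }
        (directory / "transcripts.json").write_text(json.dumps(doc, indent=1) + "\n")
        return directory

    @classmethod
    def read(cls, directory) -> "LocusFixture":
        directory = Path(directory)
        fasta = directory / "sequences.fa"
        meta = directory / "transcripts.json"
        if not fasta.exists() or not meta.exists():
            raise FileNotFoundError(
                f"{directory} is not a locus fixture (needs sequences.fa and "
                "transcripts.json)")
        sequences = {rec.id: str(rec.seq).upper()
                     for rec in SeqIO.parse(str(fasta), "fasta")}
        doc = json.loads(meta.read_text())
        records = tuple(
            TranscriptRecord(
                tx_ac=t["tx_ac"],
                gene=t["gene"],
                strand=t["strand"],
                ref_ac=t["ref_ac"],
                aln_method=t.get("aln_method", "splign"),
                pro_ac=t.get("pro_ac"),
                cds_start_n=t.get("cds_start_n"),
                cds_end_n=t.get("cds_end_n"),
                exons=tuple(
                    Exon(e["g_start"], e["g_end"],
                         tuple(AlignmentSegment(op, ln) for op, ln in e["segments"]))
                    for e in t["exons"]
                ),
            )
            for t in doc["transcripts"]
        )
        return cls(sequences=sequences, records=records,
                   seed=doc.get("seed"), params=doc.get("params", {}))


# ---------------------------------------------------------------------------
# Provider interface


class DataProvider(abc.ABC):
    """The seven queries mapping and validation require.

    Implementations must behave as pure read-only views: repeated calls
    with equal arguments return equal results.
    """

    @abc.abstractmethod
    def get_seq(self, ac: str, start: Optional[int] = None,
                end: Optional[int] = None) -> str:
        """Upper-case sequence slice, 1-based inclusive; whole sequence if
        no bounds are given."""

    @abc.abstractmethod
    def get_transcript(self, tx_ac: str, ref_ac: Optional[str] = None,
                       aln_method: Optional[str] = None) -> TranscriptRecord:
        """The record for a (transcript, reference, method) triple; when ref
        or method is omitted, the unique (or lexicographically first)
        matching record."""

    @abc.abstractmethod
    def find_transcripts(self, ref_ac: str, g_start: int,
                         g_end: int) -> List[TranscriptRecord]:
        """Records whose genomic span overlaps [g_start, g_end], ordered by
        (tx_ac, aln_method)."""

    @abc.abstractmethod
    def get_transcripts_for_gene(self, gene: str) -> List[TranscriptRecord]:
        """All records for a gene symbol, ordered by (tx_ac, aln_method)."""

    @abc.abstractmethod
    def get_alignment_methods(self, tx_ac: str,
                              ref_ac: Optional[str] = None) -> List[Tuple[str, str]]:
        """(ref_ac, aln_method) pairs under which the transcript is aligned."""

    @abc.abstractmethod
    def get_protein_accession(self, tx_ac: str) -> Optional[str]:
        """Protein accession for a coding transcript, else None."""

    @abc.abstractmethod
    def get_data_version(self) -> str:
        """An identifier for the data snapshot backing this provider."""


class FixtureProvider(DataProvider):
    """Read-only provider over a :class:`LocusFixture` (in memory or on disk)."""

    def __init__(self, fixture) -> None:
        if not isinstance(fixture, LocusFixture):
            fixture = LocusFixture.read(fixture)
        self._fixture = fixture
        self._by_tx: Dict[str, List[TranscriptRecord]] = {}
        self._by_gene: Dict[str, List[TranscriptRecord]] = {}
        self._by_pro: Dict[str, TranscriptRecord] = {}
        for rec in fixture.records:
            self._by_tx.setdefault(rec.tx_ac, []).append(rec)
            self._by_gene.setdefault(rec.gene, []).append(rec)
            if rec.pro_ac is not None:
                self._by_pro.setdefault(rec.pro_ac, rec)
        for recs in (*self._by_tx.values(), *self._by_gene.values()):
            recs.sort(key=lambda r: (r.tx_ac, r.ref_ac, r.aln_method))

    @property
    def fixture(self) -> LocusFixture:
        return self._fixture

    # -- interface ---------------------------------------------------------

    def get_seq(self, ac, start=None, end=None):
        try:
            seq = self._fixture.sequences[ac]
        except KeyError:
            raise UnknownAccessionError(f"unknown sequence accession {ac!r}") from None
        if start is None and end is None:
            return seq
        if start is None or end is None:
            raise SequenceRangeError("give both start and end, or neither")
        if not (1 <= start <= end <= len(seq)):
            raise SequenceRangeError(
                f"range {start}..{end} invalid for {ac} (length {len(seq)})")
        return seq[start - 1:end]

    def get_transcript(self, tx_ac, ref_ac=None, aln_method=None):
        recs = self._by_tx.get(tx_ac)
        if not recs:
            raise UnknownAccessionError(f"unknown transcript {tx_ac!r}")
        hits = [r for r in recs
                if (ref_ac is None or r.ref_ac == ref_ac)
                and (aln_method is None or r.aln_method == aln_method)]
        if not hits:
            raise UnknownAlignmentMethodError(
                f"transcript {tx_ac} is not aligned to "
                f"{ref_ac or 'any reference'} by {aln_method or 'any method'}; "
                f"known: {[(r.ref_ac, r.aln_method) for r in recs]}")
        return hits[0]

    def find_transcripts(self, ref_ac, g_start, g_end):
        if ref_ac not in self._fixture.sequences:
            raise UnknownAccessionError(f"unknown reference accession {ref_ac!r}")
        if g_start > g_end:
            raise SequenceRangeError(f"inverted range {g_start}..{g_end}")
        hits = [r for r in self._fixture.records
                if r.ref_ac == ref_ac and r.g_start <= g_end and g_start <= r.g_end]
        return sorted(hits, key=lambda r: (r.tx_ac, r.aln_method))

    def get_transcripts_for_gene(self, gene):
        if gene not in self._by_gene:
            raise UnknownAccessionError(f"unknown gene {gene!r}")
        return list(self._by_gene[gene])

    def get_alignment_methods(self, tx_ac, ref_ac=None):
        recs = self._by_tx.get(tx_ac)
        if not recs:
            raise UnknownAccessionError(f"unknown transcript {tx_ac!r}")
        pairs = [(r.ref_ac, r.aln_method) for r in recs
                 if ref_ac is None or r.ref_ac == ref_ac]
        return sorted(set(pairs))

    def get_protein_accession(self, tx_ac):
        recs = self._by_tx.get(tx_ac)
        if not recs:
            raise UnknownAccessionError(f"unknown transcript {tx_ac!r}")
        return recs[0].pro_ac

    def get_data_version(self) -> str:
        seed = self._fixture.seed
        return f"hgvskit-fixture/seed={seed if seed is not None else 'none'}"

    # -- convenience (not part of the abstract interface) -------------------

    def transcript_for_protein(self, pro_ac: str) -> TranscriptRecord:
        try:
            return self._by_pro[pro_ac]
        except KeyError:
            raise UnknownAccessionError(f"unknown protein accession {pro_ac!r}") from None
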