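# Methods

This note documents the models, conventions and design choices behind
hgvskit, in the spirit of a statistical package's methods appendix: what is
computed, under which assumptions, and where the edges are.

## Coordinate model

All public coordinates follow HGVS: 1-based, inclusive intervals.  Three
position kinds exist:

* `SimplePosition` — a plain residue number (g./m.).
* `BaseOffsetPosition` — base plus intronic offset plus datum.  With datum
  `cds_start`, base −k means the k-th base 5' of the CDS (there is no base
  0); datum `cds_end` encodes HGVS `*k` positions, counted from the first
  base after the stop codon.  A non-zero offset counts bases into an intron
  from the nearest exon boundary (`+` after the exon, `−` before the next).
* `AAPosition` — residue number plus the reference amino acid, stored as a
  3-letter code (`Ter` for stops); 1-letter input is normalised on
  construction.

`position_order` is a total order within each comparable family: CDS-datum
positions order as negative < positive, offsets break ties, and every `*`
position sorts after every CDS position.  Transcript-start positions and
CDS positions are *not* mutually comparable — their relation depends on the
CDS location, which the object does not carry — and comparing them raises.

One deliberate relaxation: an `Interval` may hold a mis-ordered pair
(e.g. from parsing `g.7_5del`).  Rejecting it at construction would make
the intrinsic validator's start>end rule untestable on real input text; the
constructor therefore only rejects *incomparable* endpoints, and ordering
violations are reported by `validate_intrinsic` (`Interval.is_ordered`
exposes the check).

## Grammar and canonical form

The parser is a hand-written recursive-descent implementation with a
registry of named productions, each usable as an entry point with
whole-input consumption (trailing text is an error, so no accepted string
is a strict prefix of another accepted parse of the same input).  Errors
carry the failing offset and the deepest rule attempted, and parsing is
total: arbitrary input either yields a variant or a structured parse error.

Canonical-form decisions:

* Degenerate intervals collapse (`688+403`, never `688+403_688+403`).
* Single-base identity is written `A>A` (so the substitution shape
  round-trips byte-for-byte); multi-base and bare identities use `=`.
* `del` requires its sequence to be spelled out if stated at all
  (`del3`-style length forms are rejected as unverifiable); `delins` is
  accepted both with (`delGTAins T`) and without (`delinsTT`) the deleted
  sequence, the two being distinguished in the model so both round-trip.
* Nucleotides are upper-case DNA or lower-case RNA; type letters are
  lower-case; whitespace is never legal.  Gene-symbol annotations
  (`NM_x(GENE):…`) are accepted with a warning and discarded.
* Protein changes default to 3-letter codes; a 1-letter rendering mode is
  available and 1-letter input parses to the same objects.  Predicted
  consequences carry an `inferred` flag and render in parentheses,
  `p.(Ala2Ser)`.
* r. positions parse with CDS-relative datum semantics (the coding-
  transcript convention); r. variants are produced from c./n. by alphabet
  transliteration, since the coordinates are identical.

Out of scope, matching the package's documented limitations: compound
alleles, mosaic/chimeric variants, inversions, conversions, uncertain
(`?`, parenthesised-range) positions, and canonicalization/3'-shifting.

## Alignment map and indel-aware projection

A transcript record stores exons in genomic-ascending order (strand is a
flag; transcript-order traversal is computed), each exon carrying a
run-length list of alignment segments: `M` (aligned), `D` (genome-only),
`I` (transcript-only).  `AlignmentMap` compiles a record into blocks that
partition the genomic span (match/D/intron) and the transcript (match/I),
using 0-based half-open arithmetic internally; the 1-based inclusive
convention applies only at the module boundary, which keeps gap and intron
arithmetic off-by-one-proof.

Projection rules:

* Exonic (M) positions map exactly in both directions; the map is a
  bijection over matched bases.
* Intronic genomic positions map to the nearest exon boundary's transcript
  base with a signed offset; at the exact midpoint of an even-length intron
  the 5' boundary (transcript orientation) wins — a fixed tie-break chosen
  to keep round-trips deterministic.
* Positions inside a discrepancy block have no image on the other sequence.
  They are **clamped** to the nearest transcript-5' position and flagged
  (`gap_flag`, surfaced as a `GapWarning` on variants) rather than
  rejected: erroring would make variants in indel-discrepant transcripts
  unmappable, which is precisely the failure mode the indel-aware design
  avoids.
* Minus-strand projection swaps interval endpoints and reverse-complements
  edit sequences.  Edits spanning an exon/intron boundary are mapped
  endpoint-wise with a `BoundaryWarning` — genomic deletions crossing
  splice sites are real and must survive a round-trip through g.

CDS arithmetic (`c = n − cds_start + 1`, no zero; `*k = n − cds_end`) is an
exact inverse pair over the transcript and passes intronic offsets through
unchanged.

Liftover composes projection out of the source alignment and into the
destination alignment over the shared reference, and therefore also works
between two alignment *methods* of the same transcript whose exon
boundaries disagree.

## Protein inference

`c_to_p` applies the edit to the CDS plus 3' UTR (so a frameshift can run
to its new stop), translates reference and edited sequences with the
standard nuclear code, and reports the difference: identity `p.(=)`;
a single changed residue as a substitution (to `Ter` when a stop is
created, regardless of how); in-frame multi-residue changes as
del/ins/delins after trimming the common prefix and suffix (an N-terminal
pure insertion borrows residue 1 and is expressed as a delins, since no 5'
flanking residue exists); and frame-disrupting length changes as a
frameshift anchored at the first changed residue, with the new-frame stop
distance (`fsTer n`) or the short `fs` form when no stop is reached before
the sequence ends.  Variants lying entirely within an intron cannot change
the mature transcript under this model and yield `p.(=)`; UTR positions
and edits touching a splice boundary have no defined protein consequence
and raise, directing the caller to g./n. level.  All inferred protein
variants are marked as predictions (parenthesised).

## Validation semantics

Intrinsic rules (object only): interval ordering; insertions must sit
between two flanking bases — adjacency is accepted only where it is
decidable without reference data (consecutive exonic bases, consecutive
offsets on one anchor, exon-boundary pairs like `688`/`688+1`, and
`-1`/`1` across the CDS start); a stated reference sequence must match the
interval span where the span is computable (both endpoints exonic, same
datum).  `del`/`dup` without an explicit sequence pass intrinsically and
are span/bounds-checked extrinsically.  Extrinsic rules (with a provider):
unknown accession, out-of-bounds positions, and reference mismatches;
intronic transcript positions are verified after projection to the genome
through the alignment (on the genomic strand, hence against the
reverse-complemented edit for minus-strand transcripts); protein variants
are checked against the translated CDS.  Extrinsic validation is skipped
when intrinsic validation fails, and provider failures become findings,
never exceptions.

## Synthetic loci

The generator fabricates the reference data a transcript archive would
supply, with the structural features that exercise the mapper: 1–n
transcripts of 2+ exons on either strand; exon/intron lengths drawn from
configurable ranges (defaults 60–120 and 60–160 bp — compact but large
enough for deep-intronic offsets); optional D/I discrepancy segments
placed in exon interiors; a CDS that can start in a later exon; and an
optional second alignment method whose exon boundary slides by k bases.
The slide is made biologically coherent by planting a k-base repeat at the
intron boundary — the same sequence ambiguity that makes real alignment
programs disagree.  Generated CDSs always begin with ATG, end with a stop
and contain no internal stop, so protein inference is well-defined on
every fixture.  Fixtures are deterministic in (config, seed), written as
FASTA plus a 1-based-inclusive JSON metadata document, and self-checked:
splicing every alignment record against the contig must reproduce the
stored transcript sequence exactly.

`demo_locus` is a fixed two-transcript minus-strand locus built in
transcript coordinates and back-propagated onto the contig: a variant 403
bases into TX01.1's second intron coincides with base 281 of TX02.1's CDS
(codon 94, TCC→TTC, Ser→Phe), TX02.1's CDS starts in its second exon, and
only filler bases depend on the seed.  Non-pinned coding bases are drawn
from {A,C,G} so that no stray stop codon can arise in either overlapping
reading frame.

What the synthetic data does **not** emulate: real genome base composition
and repeats, alternative splicing beyond the constructed isoforms,
multi-contig references, sequence versions that disagree between archive
releases, and alignment artefacts other than clean run-length D/I
segments.  Passing tests therefore demonstrate correctness of the
coordinate and inference algebra under the stated alignment model, not
robustness to malformed real-world archive records.

## Verification strategy and problem sizes

Every mapping claim is checked against a brute-force oracle that walks the
alignment base by base and assigns each genomic base its transcript
coordinate independently of the block arithmetic.  The test suite checks
round-trip identity on 10⁴ random model objects, parser totality on 10⁵
random strings, mapper-oracle agreement on 100 random loci (every base,
both directions), validator soundness on 10³ fixture-derived variants (and
the error flip under single-base ref mutation), and protein-inference
agreement with a translate-and-diff oracle on 10³ random CDS edits; the
acceptance script recomputes the same quantities from scratch at those
sizes.  Loci are kept compact (hundreds of bases to a few kilobases) so
the whole suite runs in seconds while still covering every structural
feature class.

## Known limitations

* No normalization: `c.5dup` and the equivalent `c.4_5insN` descriptions
  are distinct objects, and variants are not 3'-shifted.
* Repeat (`unit[n]`) edits are parsed, formatted and span-validated but not
  projected to protein consequences.
* Protein extrinsic validation checks stated reference residues only; it
  does not re-derive the protein from a stated nucleotide sibling variant.
* The provider interface is read-only and keyed by exact accession strings;
  no version-resolution or fuzzy matching is attempted.
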