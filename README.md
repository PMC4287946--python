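# hgvskit

A Python library for parsing, formatting, validating and mapping biological
sequence variants written in HGVS nomenclature — the
`accession:type.positionEdit` strings (e.g. `NM_182763.2:c.688+403C>T`) used
throughout clinical reports, variant databases and the genetics literature.
It is aimed at people who need to manipulate such variants *locally and
auditable* — clinical bioinformaticians, variant curators and tool authors —
rather than through a remote web service.

## What it does

* **Object model** — every component of a variant is a typed, immutable
  object: a `SequenceVariant` holds an accession, a sequence type
  (`g`/`m`/`c`/`n`/`r`/`p`) and a `PosEdit`; positions are 1-based with HGVS
  semantics, including base/offset coordinates such as `688+403` (CDS base
  688, 403 bases into the following intron), 5'-UTR negatives (`-14`) and
  3'-UTR stars (`*5`).
* **Parser** — a formal grammar implemented as a recursive-descent parser
  whose named rules are independently invocable: `parse_rule("c_posedit",
  "688+403C>T")` returns a `PosEdit`, `parse_rule("base_offset_position",
  "88-2")` a single position.  Covers substitution, del, ins, delins, dup,
  repeat and identity edits on nucleotides, and substitution,
  del/ins/delins, frameshift and identity on proteins.
* **Formatter** — canonical text for any model object; `parse` and
  `format_hgvs` are mutually inverse (`parse(format(v)) == v`, and
  `format(parse(s)) == s` on canonical strings).
* **Validator** — *intrinsic* checks on the object alone (interval ordering;
  an insertion interval must be exactly the two flanking bases; stated
  reference length must match the interval span) and *extrinsic* checks
  against reference data (accession known, positions in bounds, stated
  reference bases match the sequence — projected through the alignment for
  intronic positions).
* **Indel-aware mapper** — projects variants between genomic (g.),
  transcript (n.), CDS (c.) and protein (p.) coordinates through
  genome-transcript alignments that may contain insertion/deletion
  discrepancies.  Positions inside a discrepancy are clamped to the nearest
  transcript-5' base and flagged rather than rejected.  Includes transcript
  liftover: re-expressing a c. variant on another transcript — or another
  alignment of the same transcript — via the shared genomic reference, and
  protein-consequence inference by translating the edited CDS.
* **Data provider** — a seven-method abstract interface
  (`get_seq`, `get_transcript`, `find_transcripts`,
  `get_transcripts_for_gene`, `get_alignment_methods`,
  `get_protein_accession`, `get_data_version`) with a file-backed
  implementation over self-contained locus fixtures (FASTA + JSON), plus a
  deterministic synthetic-locus generator so the whole stack runs without
  any external database.

Deliberately out of scope, as in the underlying method: variant
canonicalization/3'-shifting, compound/mosaic/chimeric variants,
inversions and uncertain positions.

## Worked example

```python
from hgvskit import FixtureProvider, VariantMapper, demo_locus, parse, validate

provider = FixtureProvider(demo_locus(seed=42))
vm = VariantMapper(provider)

v1 = parse("TX01.1:c.688+403C>T")   # deep-intronic on transcript 1
vg = vm.c_to_g(v1)                  # project onto the contig
v2 = vm.liftover(v1, "TX02.1")      # sibling transcript has an exon there
print(vg, v2, vm.c_to_p(v1), vm.c_to_p(v2))
print(validate(parse("TX02.1:c.281A>T"), provider).lines())
```

prints

```
CTG01.1:g.848G>A TX02.1:c.281C>T PR01.1:p.(=) PR02.1:p.(Ser94Phe)
["ERROR ref-mismatch reference nucleotide mismatch at TX02.1:c.281: variant states 'A', reference has 'C'"]
```

One genomic event, five representations: intronic in TX01.1 (so no protein
change there), but exonic and coding in TX02.1 — a missense Ser94Phe.  Both
transcripts lie on the minus strand, so the genomic edit is the reverse
complement (C>T → G>A).  The final line shows extrinsic validation
catching a variant that states the wrong reference nucleotide.

The `examples/` directory has one short script per capability; each prints
the values it computes.  A thin CLI wraps the same functions for shell
pipelines:

```sh
hgvskit fixture --demo --seed 42 demo/
echo "TX01.1:c.688+403C>T" | hgvskit map --fixture demo/ --to g
```

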