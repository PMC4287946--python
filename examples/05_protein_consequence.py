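"""Infer protein consequences by translating the edited CDS.

A tiny hand-built transcript with CDS ATG GCT AAA TGA (Met-Ala-Lys-Ter)
shows each consequence class: missense, synonymous, nonsense, frameshift.
"""

from hgvskit import (
    AlignmentSegment,
    Exon,
    FixtureProvider,
    LocusFixture,
    TranscriptRecord,
    VariantMapper,
    parse,
)

cds = "ATGGCTAAATGA"
tx = "GG" + cds + "GTTACCA"          # 2-base 5' UTR, 7-base 3' UTR
contig = "AAAA" + tx + "TTTT"
rec = TranscriptRecord(
    tx_ac="TXF.1", gene="DEMO", strand=1, ref_ac="CTGF.1",
    exons=(Exon(5, 4 + len(tx), (AlignmentSegment("M", len(tx)),)),),
    cds_start_n=3, cds_end_n=14, pro_ac="PRF.1")
fx = LocusFixture(sequences={"CTGF.1": contig, "TXF.1": tx}, records=(rec,))
fx.validate()
vm = VariantMapper(FixtureProvider(fx))

for text, note in [
    ("TXF.1:c.4G>T", "missense: codon 2 GCT(Ala) -> TCT(Ser)"),
    ("TXF.1:c.6T>C", "synonymous: GCT and GCC both encode Ala"),
    ("TXF.1:c.7A>T", "nonsense: AAA(Lys) -> TAA(Ter)"),
    ("TXF.1:c.4del", "frameshift from residue 2"),
    ("TXF.1:c.4_6del", "in-frame deletion of Ala2"),
]:
    print(f"{text:16s} -> {vm.c_to_p(parse(text))!s:28s} # {note}")
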