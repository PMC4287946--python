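"""Project a variant between transcripts via their shared genome.

The demo locus mirrors a classic two-transcript situation: a variant deep
in TX01.1's second intron (c.688+403) falls inside an extra exon of the
sibling transcript TX02.1, where it is exonic and coding (c.281).  Both
transcripts are on the minus strand, so the genomic edit is the reverse
complement (C>T becomes G>A).
"""

from hgvskit import FixtureProvider, VariantMapper, demo_locus, parse

vm = VariantMapper(FixtureProvider(demo_locus(seed=42)))

v1 = parse("TX01.1:c.688+403C>T")
vg = vm.c_to_g(v1)                    # project onto the contig
v2 = vm.liftover(v1, "TX02.1")        # re-express on the sibling transcript
p1 = vm.c_to_p(v1)                    # intronic -> no protein change
p2 = vm.c_to_p(v2)                    # exonic, coding -> missense

print("source variant:   ", v1)
print("genomic:          ", vg)
print("lifted to TX02.1: ", v2)
print("protein (TX01.1): ", p1)
print("protein (TX02.1): ", p2)
# five representations of one genomic event:
#   TX01.1:c.688+403C>T  CTG01.1:g.848G>A  TX02.1:c.281C>T
#   PR01.1:p.(=)         PR02.1:p.(Ser94Phe)
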