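"""Generate a synthetic locus fixture and query it through the provider.

The generator emits a contig, transcript sequences and alignment records
with the structural features real transcript archives exhibit: both
strands, late CDS starts and genome-transcript indels.  The same seed
always produces byte-identical output.
"""

from hgvskit import FixtureProvider, LocusConfig, generate_locus

cfg = LocusConfig(n_transcripts=2, exons_per_tx=3, strand="random",
                  indels=(("D", 3),), alt_aln_shift=2)
fx = generate_locus(cfg, seed=11)
provider = FixtureProvider(fx)

print("sequences:", {ac: len(s) for ac, s in fx.sequences.items()})
for rec in fx.records:
    print(f"{rec.tx_ac} ({rec.aln_method}, strand {rec.strand:+d}): "
          f"{len(rec.exons)} exons, CDS n.{rec.cds_start_n}-{rec.cds_end_n}, "
          f"span g.{rec.g_start}-{rec.g_end}")

rec = provider.get_transcript("TX01.1")
print("first 30 transcript bases:", provider.get_seq("TX01.1", 1, 30))
print("overlapping g.%d: %s" % (
    rec.g_start + 5,
    [r.tx_ac for r in provider.find_transcripts(rec.ref_ac,
                                                rec.g_start + 5,
                                                rec.g_start + 5)]))
# the D segment makes the transcript 3 bases shorter than its spliced exons
spliced = sum(e.g_length for e in rec.exons)
print("spliced exon bases:", spliced, "| transcript length:", rec.tx_length)
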