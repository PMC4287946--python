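"""Intrinsic and extrinsic validation.

Intrinsic checks need only the variant object (interval ordering, the
flanking-base rule for insertions, ref-length agreement).  Extrinsic checks
compare the stated reference bases against the provider's sequences —
here the synthetic two-transcript demo locus, where c.281 of TX02.1 is a C.
"""

from hgvskit import FixtureProvider, demo_locus, parse, validate, validate_intrinsic

provider = FixtureProvider(demo_locus(seed=42))

print("# intrinsic")
for text in ["X:g.10_11insA", "X:g.10_10insA", "X:g.7_5del", "X:g.5_7delGT"]:
    rep = validate_intrinsic(parse(text))
    print(f"{text:18s} ->", rep.level, ";".join(rep.lines()))

print("\n# extrinsic (against the fixture)")
for text in ["TX02.1:c.281C>T",      # correct reference -> ok
             "TX02.1:c.281A>T",      # wrong reference nucleotide -> error
             "TX01.1:c.688+403C>T",  # intronic: checked via the genome
             "TX02.1:c.99999A>T"]:   # beyond the transcript -> bounds error
    rep = validate(parse(text), provider)
    print(f"{text:22s} ->", rep.level, ";".join(rep.lines()))
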