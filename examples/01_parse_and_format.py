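"""Parse an HGVS string into a typed object and render it back.

The variant NM_182763.2:c.688+403C>T is a C>T substitution 403 bases into
the intron that follows CDS base 688 of transcript NM_182763.2.
"""

from hgvskit import format_hgvs, parse, parse_rule, variant_category

v = parse("NM_182763.2:c.688+403C>T")
start = v.posedit.pos.start
print("accession:     ", v.ac)
print("sequence type: ", v.type.value)
print("base:          ", start.base)      # 688  (CDS-relative position)
print("offset:        ", start.offset)    # 403  (bases into the intron)
print("edit:          ", str(v.posedit.edit))
print("category:      ", variant_category(v).value)
print("canonical form:", format_hgvs(v))  # byte-identical to the input

# any grammar rule is independently invocable on a fragment
pe = parse_rule("c_posedit", "688+403C>T")
print("fragment parse:", str(pe))
pos = parse_rule("base_offset_position", "88-2")
print("position 88-2 ->", (pos.base, pos.offset))
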