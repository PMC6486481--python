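"""Parse glycans from linear notation, classify them, and read compositions.

The linear notation writes an N-glycan tree from the reducing-end GlcNAc
outward; brackets open branches, colons close them, '@' ends the string.
"""

from glycosim import classify, composition, parse_linear, profile_key, serialize

MAN5 = "GlcNAc4.1GlcNAc4.1Man(3.1Man:)_m6.1Man(3.1Man:)_m6.1Man:@"
COMPLEX = (
    "GlcNAc4.1GlcNAc4.1Man(3.1Man2.1GlcNAc4.1Gal:)_m6.1Man2.1GlcNAc4.1Gal6.2Sia:@"
)

for name, s in [("Man5GlcNAc2", MAN5), ("NeuAc1Gal2GlcNAc2Man3GlcNAc2", COMPLEX)]:
    g = parse_linear(s)
    print(f"{name}:")
    print(f"  class       : {classify(g).value}")
    print(f"  composition : {composition(g)}")
    print(f"  profile key : {profile_key(g)}")
    print(f"  round trip  : {serialize(g) == s}")

# The profile key is what mass spectrometry can distinguish: structural
# isomers of one composition collate to the same key in a glycan profile.
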