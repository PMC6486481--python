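# COG-complex-disruption-like scenario: impaired retention/recycling of
# late-acting glycosyltransferases, modeled as reduced effective rates for
# galactosylation, sialylation and fucosylation on the complex-4c machinery.
# Multipliers are this package's choice of a plausible knockdown strength.
name: cog4-like
base: complex-4c
perturbation: {GalT: 0.6, SiaT3: 0.7, SiaT6: 0.7, FUT8: 0.5, antFUT: 0.5}
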