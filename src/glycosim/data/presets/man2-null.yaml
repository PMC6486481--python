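# Swainsonine-like scenario: the complex-4c machinery with mannosidase II
# removed (rate multiplier 0), which blocks the hybrid->complex conversion
# and accumulates hybrid species, including core-fucosylated Man5 hybrids.
name: man2-null
base: complex-4c
perturbation: {MAN2: 0.0}
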