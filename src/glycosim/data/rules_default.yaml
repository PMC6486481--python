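# Default mammalian N-glycan processing rule set.
#
# Reconstructed canonical pathway: alpha-1,2-mannosidase trimming (MAN1),
# endo-mannosidase removal of the Glc-bearing terminal unit, antenna
# initiation by MGAT1/2/4/5 (antenna cap 4), mannosidase II (MAN2)
# hybrid->complex conversion, galactosylation (GalT), arm-specific
# sialylation (SiaT3 / SiaT6), core fucosylation (FUT8), grouped antenna
# fucosylation (antFUT), and the oligomannose-quench pseudo-enzyme
# (OMquench) that marks oligomannose glycans terminally unprocessable.
#
# Linkage codes are acceptor.anomeric (e.g. 2.1 = beta1-2, 6.2 = alpha2-6).
# `match` is a residue-level predicate, `guards` a whole-glycan predicate.

scale_factors:
  # slower conversion of Man6GlcNAc2 to Man5GlcNAc2 (final MAN1 step)
  - id: man1_man6_to_man5
    enzyme: MAN1
    when: {man_count: 6}
    factor: 0.25
  # FUT8 acts on Man5-bearing (hybrid-type) substrates at a reduced rate
  - id: fut8_man5
    enzyme: FUT8
    when: {man_count: 5}
    factor: 0.1
  # galactosylation of tri-/tetra-antennary glycans is slower than bi-antennary
  - id: galt_branching
    enzyme: GalT
    when: {antenna_count: {min: 3}}
    factor: 0.3

rules:
  # stepwise removal of terminal alpha-1,2 mannoses (Man9 -> Man5 ladder)
  - enzyme: MAN1
    match: {sugar: Man, linkage: "2.1", leaf: true}
    action: {remove: true}
    scale_factor_id: man1_man6_to_man5

  # endo-mannosidase removes the terminal Glc-Man unit of glucosylated input
  - enzyme: ENDOM
    match: {sugar: Man, linkage: "2.1", only_child: {sugar: Glc}}
    action: {remove_subtree: true}

  # first antenna: beta1-2 GlcNAc on the 3-arm core mannose of Man5
  - enzyme: MGAT1
    match: {role: arm3_man, leaf: true}
    guards: {man_count: 5, glc_count: 0, antenna_count: 0}
    action: {add: {sugar: GlcNAc, linkage: "2.1"}}

  # mannosidase II removes the two 6-arm mannoses once an antenna exists
  - enzyme: MAN2
    match: {sugar: Man, leaf: true, linkage: ["3.1", "6.1"], parent_role: arm6_man}
    guards: {antenna_count: {min: 1}, glc_count: 0}
    action: {remove: true}

  # second antenna: beta1-2 GlcNAc on the 6-arm core mannose (complex core)
  - enzyme: MGAT2
    match: {role: arm6_man, lacks_child_sugar: GlcNAc}
    guards: {man_count: 3, antenna_count: 1}
    action: {add: {sugar: GlcNAc, linkage: "2.1"}}

  # third antenna: beta1-4 GlcNAc on the 3-arm core mannose; requires the
  # beta1-2 antenna on the same arm to be still unsubstituted, which is how
  # galactosylation activity limits branching
  - enzyme: MGAT4
    match:
      role: arm3_man
      has_bare_child: {sugar: GlcNAc, linkage: "2.1"}
      lacks_child_linkage: "4.1"
    guards: {man_count: 3, antenna_count: {min: 2}}
    action: {add: {sugar: GlcNAc, linkage: "4.1"}}

  # fourth antenna: beta1-6 GlcNAc on the 6-arm core mannose; same
  # bare-antenna requirement as MGAT4
  - enzyme: MGAT5
    match:
      role: arm6_man
      has_bare_child: {sugar: GlcNAc, linkage: "2.1"}
      lacks_child_linkage: "6.1"
    guards: {man_count: 3, antenna_count: {min: 2}}
    action: {add: {sugar: GlcNAc, linkage: "6.1"}}

  # galactosylation of any ungalactosylated antenna GlcNAc
  - enzyme: GalT
    match: {is_antenna_glcnac: true, lacks_child_sugar: Gal}
    action: {add: {sugar: Gal, linkage: "4.1"}}
    scale_factor_id: galt_branching

  # sialylation, separate rates for antennae on the 3-arm and the 6-arm
  - enzyme: SiaT3
    match: {sugar: Gal, parent_is_antenna_glcnac: true, arm: "3", lacks_child_sugar: NeuAc}
    action: {add: {sugar: NeuAc, linkage: "6.2"}}
  - enzyme: SiaT6
    match: {sugar: Gal, parent_is_antenna_glcnac: true, arm: "6", lacks_child_sugar: NeuAc}
    action: {add: {sugar: NeuAc, linkage: "6.2"}}

  # core fucosylation of the reducing-end GlcNAc (requires an antenna)
  - enzyme: FUT8
    match: {role: root, lacks_child_sugar: Fuc}
    guards: {antenna_count: {min: 1}}
    action: {add: {sugar: Fuc, linkage: "6.1"}}
    scale_factor_id: fut8_man5

  # grouped antenna fucosyltransferases: complex glycans only, at most one
  # fucose per antenna, only on non-sialylated antennae
  - enzyme: antFUT
    match: {is_antenna_glcnac: true, lacks_child_sugar: Fuc, subtree_lacks: [NeuAc]}
    guards: {glycan_class: complex}
    action: {add: {sugar: Fuc, linkage: "3.1"}}

  # oligomannose quench: marks the glycan terminally unprocessable
  - enzyme: OMquench
    match: {role: root}
    guards: {glycan_class: oligomannose}
    action: {quench: true}
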