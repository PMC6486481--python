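# Complex-glycan-rich 4-cisterna scenario (HEK293T-like regime: a fourth
# cisterna supports full antenna elaboration, galactosylation, sialylation
# and fucosylation).  Rates are ground-truth values chosen for this package
# and frozen here.
name: complex-4c
model:
  n_cisternae: 4
  residence_times: [10.0, 10.0, 10.0, 10.0]
  input_distribution: {Man8: 0.80, Man9: 0.15, Man9Glc: 0.05}
  rates:
    MAN1: {1: 2.0, 2: 0.5}
    ENDOM: {1: 1.0}
    OMquench: {1: 0.05, 2: 0.03}
    MGAT1: {2: 1.5}
    MAN2: {2: 1.5, 3: 0.3}
    FUT8: {2: 0.3, 3: 0.2}
    MGAT2: {3: 1.2}
    MGAT4: {3: 0.3}
    MGAT5: {3: 0.3}
    GalT: {3: 1.0, 4: 1.0}
    antFUT: {3: 0.1, 4: 0.05}
    SiaT3: {4: 0.8}
    SiaT6: {4: 0.4}
n_glycans: 10000
n_replicates: 3
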