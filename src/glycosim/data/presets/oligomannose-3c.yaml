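# Oligomannose-dominated 3-cisterna scenario (HeLa-like regime: a whole-cell
# profile dominated >90% by oligomannose species).  Strong oligomannose
# quench and alpha-1,2 trimming, weak antenna initiation.
# Rates are ground-truth values chosen for this package and frozen here.
name: oligomannose-3c
model:
  n_cisternae: 3
  residence_times: [10.0, 10.0, 10.0]
  input_distribution: {Man8: 0.80, Man9: 0.15, Man9Glc: 0.05}
  rates:
    MAN1: {1: 1.5, 2: 0.3, 3: 0.05}
    ENDOM: {1: 1.0}
    OMquench: {1: 0.2, 2: 0.15, 3: 0.1}
    MGAT1: {2: 0.3}
    MAN2: {2: 0.5}
    MGAT2: {3: 0.3}
    GalT: {3: 0.5}
    SiaT3: {3: 0.3}
    SiaT6: {3: 0.15}
    FUT8: {2: 0.1}
n_glycans: 10000
n_replicates: 3
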