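# Reduced fitting scenario: 3 cisternae, 5 enzymes (15 rate parameters).
# Used for parameter-recovery studies at desk scale.  Ground-truth rates are
# frozen here; the priors encode localization beliefs (log-normal in the
# cisterna where the enzyme predominantly resides, exponential decay
# elsewhere) and are deliberately centered near, but not at, the ground
# truth.
name: fit-demo-3c
model:
  n_cisternae: 3
  residence_times: [10.0, 10.0, 10.0]
  input_distribution: {Man8: 0.85, Man9: 0.15}
  rates:
    MAN1: {1: 1.2, 2: 0.3, 3: 0.05}
    MGAT1: {1: 0.05, 2: 0.8, 3: 0.1}
    MAN2: {1: 0.05, 2: 0.7, 3: 0.15}
    GalT: {1: 0.02, 2: 0.2, 3: 1.0}
    OMquench: {1: 0.15, 2: 0.1, 3: 0.05}
n_glycans: 10000
n_replicates: 3
priors:
  "MAN1@1": {dist: lognormal, mu: 0.0, sigma: 0.5}       # median 1.0
  "MAN1@2": {dist: exponential, lam: 5.0}                # mean 0.2
  "MAN1@3": {dist: exponential, lam: 5.0}
  "MGAT1@1": {dist: exponential, lam: 5.0}
  "MGAT1@2": {dist: lognormal, mu: -0.511, sigma: 0.5}   # median 0.6
  "MGAT1@3": {dist: exponential, lam: 5.0}
  "MAN2@1": {dist: exponential, lam: 5.0}
  "MAN2@2": {dist: lognormal, mu: -0.693, sigma: 0.5}    # median 0.5
  "MAN2@3": {dist: exponential, lam: 5.0}
  "GalT@1": {dist: exponential, lam: 5.0}
  "GalT@2": {dist: exponential, lam: 5.0}
  "GalT@3": {dist: lognormal, mu: -0.223, sigma: 0.5}    # median 0.8
  "OMquench@1": {dist: lognormal, mu: -2.303, sigma: 0.6} # median 0.1
  "OMquench@2": {dist: exponential, lam: 10.0}           # mean 0.1
  "OMquench@3": {dist: exponential, lam: 10.0}
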