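# Default synthetic cohort: 6000 genes, 120 samples, five subtype-marker
# modules (A-E) plus a liver-contamination module (F) active in the LIV group
# and in 35% of samples of all subtypes. Module A carries a risk hazard
# (+0.7 log-hazard per activation unit), module E a protective one (-0.7).
n_genes: 6000
n_samples: 120
subtype_proportions:
  LMS1: 0.25
  LMS2: 0.20
  LMS3: 0.175
  LMS4: 0.175
  LMS5: 0.15
  LIV: 0.05
modules:
  - label: A
    n_genes: 200
    levels: {LMS1: 1.2}
  - label: B
    n_genes: 200
    levels: {LMS2: 1.2}
  - label: C
    n_genes: 250
    levels: {LMS3: 1.2}
  - label: D
    n_genes: 200
    levels: {LMS4: 1.2}
  - label: E
    n_genes: 250
    levels: {LMS5: 1.2}
  - label: F
    n_genes: 150
    levels: {LIV: 1.2}
contamination_module: F
contamination_fraction: 0.35
contamination_level: 0.8
noise_sd: 0.25
intra_patient_sd: 0.05
lesions_per_patient: {1: 0.6, 2: 0.25, 3: 0.15}
survival_betas: {A: 0.7, E: -0.7}
censor_fraction: 0.3
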