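# Demo pipeline run: small synthetic survey through all stages.
out_dir: results/demo_run
seed: 2021
subtypes: [PV, VM, SOM, PO, RBP4, NXPH4]
n_per_subtype: 30
nodal_threshold: 5.0
cap_percent: 99.0
glm_reference: PV
jitter_sd: 0.0
sites_per_axon: [2, 3]
psf_sigma: 0.1
profile_noise_sd: 0.05
n_longitudinal: 150
remodeling:
  gain_at_zero: 20.0
  loss_at_full: 10.0
  noise_sd: 10.0
  pivot: 50.0
stages: [simulate, coverage, diameter, glm, longitudinal]
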