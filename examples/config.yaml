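# A desk-scale synthetic study: 19 subjects x 4 scans, 24-node connectome,
# planted 6-node clique coupled to the first thought dimension.
seed: 7
output_dir: wandernet_out
simulate:
  n_subjects: 19
  n_nodes: 24
  beta: 0.25
mfa:
  n_components: 3
  n_boot: 10000
nbs:
  threshold: 3.0
  n_perm: 2000
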