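# Example config for `eegfwd sweep --config examples/05_sweep_config.yaml`.
# Down-scaled version of the isotropic three-layer validation study; the
# full study uses n_realizations: 50 and all six eccentricities.
model: three_layer_iso
methods: [fem, hybrid]
eccentricities: [50, 90]
orientations: [radial]
n_realizations: 3
seed: 0
mesh_seed: 1
# output_dir: results/sweep   # uncomment to write raw + summary CSVs
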