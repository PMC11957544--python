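# Sparse neuron-marker counting (ball scales 2-5, step 1); no watershed
# split needed for well-separated somata, but kept for touching cases.
name: neurons
seed: 0
stages:
  - op: gaussian_smooth
    params: {sigma: 1.0}
  - op: ballness
    params: {stddev_min: 2, stddev_max: 5, stddev_step: 1, polarity: bright}
  - op: binarize
    params: {threshold: auto}
  - op: remove_small_spots
    params: {min_voxels: 20, connectivity: 26}
  - op: watershed
    params: {h: 1.0, connectivity: 6}
  - op: count
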