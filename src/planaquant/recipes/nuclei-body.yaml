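# Nuclei counting, trunk parameter set (ball scales 1-3, step 1).
name: nuclei-body
seed: 0
stages:
  - op: gaussian_smooth
    params: {sigma: 1.0}
  - op: ballness
    params: {stddev_min: 1, stddev_max: 3, stddev_step: 1, polarity: bright}
  - op: binarize
    params: {threshold: auto}
  - op: remove_small_spots
    params: {min_voxels: 10, connectivity: 26}
  - op: watershed
    params: {h: 1.0, connectivity: 6}
  - op: count
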