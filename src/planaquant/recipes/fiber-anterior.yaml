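# Anterior-pole muscle fiber tracing: unsharp masking, single-scale rod
# enhancement, cylinder correlation 18 / 2.8 / 3 at 5 degree sampling.
name: fiber-anterior
seed: 0
stages:
  - op: unsharp_mask
    params: {sigma: 2.0, amount: 1.0}
  - op: rodness
    params: {stddev_min: 1, stddev_max: 1, stddev_step: 1, polarity: bright}
  - op: cylinder_correlate
    params: {length: 18, outer_radius: 2.8, mask_radius: 3, angular_step: 5}
  - op: trace
    params: {seed_threshold: 0.5, min_length: 18}
  - op: classify
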