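"""Count nuclei in a synthetic stained volume, including touching pairs.

Builds a 128³ phantom of 80 Gaussian-profile nuclei (20% placed as
deliberately touching pairs at 1.5x-radius separation, SNR 10), runs the
counting pipeline — Gaussian smoothing, multiscale Hessian ball
enhancement, Otsu thresholding, small-spot removal, and marker-based
watershed — and compares the census against the generator's ground truth.
"""

import numpy as np

import planaquant as pq

grid, truth = pq.make_nuclei_phantom(
    n=80, shape=(128, 128, 128), touching_fraction=0.2, snr=10.0, seed=7
)
out = pq.count_nuclei(grid, scales=pq.ScaleRange(1, 3, 1))

print(f"planted nuclei:     {truth['n']}")
print(f"segmented instances: {out['count']}")
print(f"watershed markers:   {out['n_markers']}")

# did the marker-based watershed split the designated touching pairs?
spacing = np.asarray(grid.spacing)
split = 0
for i, j in truth["touching_pairs"]:
    ci = tuple(np.rint(np.array(truth["centroids_um"][i]) / spacing).astype(int))
    cj = tuple(np.rint(np.array(truth["centroids_um"][j]) / spacing).astype(int))
    split += int(out["labels"].data[ci] != out["labels"].data[cj])
print(f"touching pairs split: {split}/{len(truth['touching_pairs'])}")
print()
print(out["table"].head(5).to_string(index=False))
print("...")
print(
    "Each row is one segmented nucleus: voxel count, volume in µm³, and\n"
    "its centroid. A count matching the planted number means the\n"
    "enhancement+watershed chain neither merged touching nuclei nor\n"
    "fragmented single ones."
)
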