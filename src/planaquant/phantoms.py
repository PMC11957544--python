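"""Seeded synthetic phantoms with exact ground truth.

These stand in for the real stained volumes the pipeline was designed
for: PI-like dense nuclei fields, sparse neuron-marker fields, body-wall
fiber bundles of known orientation class, and capsule/sphere/cube body
shapes with closed-form volume and surface area.  Every generator is a
pure function of its parameters and seed, and returns the rendered
:class:`~planaquant.grid.VoxelGrid` together with a JSON-able truth
payload.

Noise model: intensities are scaled to photon counts, Poisson-sampled,
and Gaussian read noise is added so that the signal-to-noise ratio —
defined as (object peak − background mean) / background sd — hits the
requested value exactly.
"""

from __future__ import annotations

import numpy as np

from .fibers import _canonical_hemisphere
from .grid import VoxelGrid


def _apply_noise(img: np.ndarray, snr: float, rng: np.random.Generator,
                 peak_photons: float = 200.0, background: float = 20.0) -> np.ndarray:
    """Poisson + Gaussian noise calibrated to the target SNR (see module docs)."""
    counts = img * peak_photons + background
    noisy = rng.poisson(counts).astype(np.float32)
    target_var = (peak_photons / snr) ** 2
    extra = target_var - background  # Poisson already contributes var=background
    if extra > 0:
        noisy += rng.normal(0.0, np.sqrt(extra), size=img.shape).astype(np.float32)
    return noisy


def _add_blob(img: np.ndarray, center: np.ndarray, sigma: float, amplitude: float = 1.0) -> None:
    """Accumulate a Gaussian intensity blob (max-composited) in place."""
    r = int(np.ceil(3 * sigma))
    lo = np.maximum(np.floor(center).astype(int) - r, 0)
    hi = np.minimum(np.floor(center).astype(int) + r + 1, img.shape)
    if np.any(hi <= lo):
        return
    zz, yy, xx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    patch = amplitude * np.exp(-d2 / (2 * sigma**2))
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    np.maximum(img[sl], patch, out=img[sl])


def make_nuclei_phantom(
    n: int = 500,
    shape: tuple[int, int, int] = (256, 256, 256),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    radius_range: tuple[float, float] = (2.5, 4.0),
    touching_fraction: float = 0.0,
    snr: float = 10.0,
    seed: int = 0,
    margin_gap: float = 2.0,
    max_attempts: int = 200,
) -> tuple[VoxelGrid, dict]:
    """Dense nuclei field: Gaussian-profile spheres, optional touching pairs.

    Non-pair nuclei are placed with pairwise surface gaps > 0 (at least
    ``margin_gap`` µm); each designated touching pair shares a radius and
    sits at center distance 1.5× that radius.  Truth lists centroids
    (µm), radii, and pair memberships.  Density infeasible after
    ``max_attempts`` rejections per object raises ``RuntimeError``.
    """
    if not 0 <= touching_fraction <= 1:
        raise ValueError("touching_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    spacing = tuple(float(s) for s in spacing)
    if len(set(spacing)) != 1:
        raise NotImplementedError("phantom rendering assumes isotropic spacing")
    n_pairs = int(round(n * touching_fraction / 2))
    n_single = n - 2 * n_pairs
    extent = np.asarray(shape) * np.asarray(spacing)

    centers: list[np.ndarray] = []
    radii: list[float] = []
    pairs: list[tuple[int, int]] = []

    def fits(c: np.ndarray, r: float, skip: int | None = None) -> bool:
        for j, (c2, r2) in enumerate(zip(centers, radii)):
            if j == skip:
                continue
            if np.linalg.norm(c - c2) < r + r2 + margin_gap:
                return False
        return True

    def place(r: float, partner: tuple[np.ndarray, float] | None = None) -> np.ndarray:
        for _ in range(max_attempts):
            if partner is None:
                c = rng.uniform(r + margin_gap, extent - r - margin_gap)
            else:
                pc, dist = partner
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                c = pc + dist * u
                if np.any(c < r) or np.any(c > extent - r):
                    continue
            if fits(c, r, skip=len(centers) - 1 if partner is not None else None):
                return c
        raise RuntimeError("phantom density infeasible: rejection sampling exhausted")

    for _ in range(n_single):
        r = rng.uniform(*radius_range)
        centers.append(place(r))
        radii.append(r)
    for _ in range(n_pairs):
        r = rng.uniform(*radius_range)
        c1 = place(r)
        centers.append(c1)
        radii.append(r)
        c2 = place(r, partner=(c1, 1.5 * r))
        i, j = len(centers) - 1, len(centers)
        centers.append(c2)
        radii.append(r)
        pairs.append((i, j))

    img = np.zeros(shape, dtype=np.float32)
    vox = float(spacing[0])
    for c, r in zip(centers, radii):
        _add_blob(img, np.asarray(c) / vox, sigma=(r / 2.0) / vox)
    noisy = _apply_noise(img, snr, rng)
    truth = {
        "n": n,
        "centroids_um": [list(map(float, c)) for c in centers],
        "radii_um": [float(r) for r in radii],
        "touching_pairs": [list(p) for p in pairs],
        "snr": snr,
        "seed": seed,
        "clean_mass": float(img.sum()),
    }
    return VoxelGrid(noisy, spacing=spacing), truth


def _segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between 3D segments [p1,q1] and [p2,q2]."""
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    b, c = d1 @ d2, d1 @ r
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0, 1) if denom > 1e-12 else 0.0
    t = np.clip((b * s + f) / e, 0, 1) if e > 1e-12 else 0.0
    s = np.clip((b * t - c) / a, 0, 1) if a > 1e-12 else 0.0
    return float(np.linalg.norm(p1 + s * d1 - (p2 + t * d2)))


def _render_segment(img: np.ndarray, p: np.ndarray, q: np.ndarray, radius: float,
                    edge_width: float = 1.0) -> None:
    """Max-composite an anti-aliased solid cylinder between points p, q (voxels)."""
    lo = np.maximum(np.floor(np.minimum(p, q)).astype(int) - int(np.ceil(radius + 2)), 0)
    hi = np.minimum(np.ceil(np.maximum(p, q)).astype(int) + int(np.ceil(radius + 2)) + 1, img.shape)
    zz, yy, xx = np.meshgrid(*[np.arange(l, h, dtype=np.float32) for l, h in zip(lo, hi)], indexing="ij")
    d = q - p
    L = np.linalg.norm(d)
    u = d / L
    rel = np.stack([zz - p[0], yy - p[1], xx - p[2]], axis=-1)
    t_ax = rel @ u
    rho = np.sqrt(np.maximum((rel**2).sum(-1) - t_ax**2, 0.0))
    radial = np.clip((radius + edge_width / 2 - rho) / edge_width, 0.0, 1.0)
    axial = np.clip((np.minimum(t_ax, L - t_ax) + edge_width / 2) / edge_width, 0.0, 1.0)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    np.maximum(img[sl], (radial * axial).astype(np.float32), out=img[sl])


# default body frame in (z, y, x): AP along x, ML along y, DV along z
DEFAULT_BODY_FRAME = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])


def _class_orientation(fiber_class: str, frame: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit axis safely inside the angular bin of a fiber class."""
    ap, ml, dv = frame
    if fiber_class == "dorsoventral":
        theta = np.radians(rng.uniform(0, 25))
        psi = rng.uniform(0, 2 * np.pi)
        u = np.cos(theta) * dv + np.sin(theta) * (np.cos(psi) * ap + np.sin(psi) * ml)
    else:
        phi_deg = {"longitudinal": (0, 25), "diagonal": (35, 55), "circular": (65, 90)}[fiber_class]
        phi = np.radians(rng.uniform(*phi_deg))
        tilt = np.radians(rng.uniform(0, 15))  # out-of-plane tilt, well clear of the DV bin
        sgn = rng.choice([-1.0, 1.0])
        u = np.cos(tilt) * (np.cos(phi) * ap + sgn * np.sin(phi) * ml) + np.sin(tilt) * dv
    return _canonical_hemisphere(u[None])[0]


def make_fiber_phantom(
    fibers: list[tuple[str, float, float]] | None = None,
    shape: tuple[int, int, int] = (192, 192, 192),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    body_frame: np.ndarray = DEFAULT_BODY_FRAME,
    snr: float = 5.0,
    seed: int = 0,
    min_separation: float = 6.0,
    background: float = 0.0,
    edge_margin: float = 14.0,
    max_attempts: int = 500,
) -> tuple[VoxelGrid, dict]:
    """Bundle of straight fibers with known orientation classes.

    ``fibers`` is a list of ``(class, length_um, radius_um)``; default is
    50 fibers drawn over the four body-wall classes with lengths
    60–120 µm and radius matching the standard cylinder template.
    Cylinders are rendered with anti-aliased edges; no two fiber axes
    come closer than ``min_separation`` (defaults to twice the standard
    mask radius), and whole fibers stay ``edge_margin`` voxels clear of
    the volume faces (the matched filter's support half-size, so every
    fiber lies in the detector's valid interior).  ``snr=inf`` (or
    ``None``) renders noise-free.
    """
    rng = np.random.default_rng(seed)
    frame = np.asarray(body_frame, dtype=float)
    if fibers is None:
        classes = ["circular", "diagonal", "longitudinal", "dorsoventral"]
        # radius matches the standard template's outer radius
        fibers = [(classes[i % 4], float(rng.uniform(60, 120)), 2.8) for i in range(50)]
    extent = np.asarray(shape, dtype=float)
    placed = []  # (p, q, class, radius)
    lo_lim = max(edge_margin, 2.0)
    for fclass, length, radius in fibers:
        for attempt in range(max_attempts):
            u = _class_orientation(fclass, frame, rng)
            c = rng.uniform(lo_lim, extent - lo_lim)
            p, q = c - u * length / 2, c + u * length / 2
            if np.any(p < lo_lim) or np.any(p > extent - lo_lim):
                continue
            if np.any(q < lo_lim) or np.any(q > extent - lo_lim):
                continue
            if all(_segment_distance(p, q, pp, qq) >= min_separation for pp, qq, *_ in placed):
                placed.append((p, q, fclass, radius, u))
                break
        else:
            raise RuntimeError("fiber packing infeasible")
    img = np.full(shape, background, dtype=np.float32)
    for p, q, fclass, radius, u in placed:
        _render_segment(img, p, q, radius)
    clean_mass = float(img.sum())
    if snr is not None and np.isfinite(snr):
        img = _apply_noise(img, snr, rng)
    truth = {
        "fibers": [
            {
                "class": fclass,
                "endpoints_um": [list(map(float, p * np.asarray(spacing))),
                                 list(map(float, q * np.asarray(spacing)))],
                "length_um": float(np.linalg.norm((q - p) * np.asarray(spacing))),
                "radius_um": float(radius),
                "orientation": list(map(float, u)),
            }
            for p, q, fclass, radius, u in placed
        ],
        "body_frame": frame.tolist(),
        "snr": None if snr is None or not np.isfinite(snr) else float(snr),
        "seed": seed,
        "clean_mass": clean_mass,
    }
    return VoxelGrid(img, spacing=spacing), truth


def make_body_phantom(
    shape_kind: str = "capsule",
    dims: dict | None = None,
    fill: str = "solid",
    shape: tuple[int, int, int] | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    nuclei_spacing: float = 6.0,
) -> tuple[VoxelGrid, dict]:
    """Simple body shapes with closed-form volume and surface area.

    ``dims``: sphere ``{"radius"}``, cube ``{"side"}``, capsule
    ``{"radius", "height"}`` (cylinder height, hemispherical caps; total
    length = height + 2·radius), all µm.  ``fill='solid'`` renders the
    binary shape at intensity 1; ``fill='nuclei'`` scatters Gaussian
    nuclei dots on a jittered lattice inside the shape, emulating a
    PI-stained body for the mask-construction pipeline.
    """
    rng = np.random.default_rng(seed)
    dims = dims or {"radius": 20.0, "height": 60.0}
    if shape_kind == "sphere":
        r = float(dims["radius"])
        half_extent = np.array([r, r, r])
        truth_v = 4.0 / 3.0 * np.pi * r**3
        truth_sa = 4.0 * np.pi * r**2
        length = 2 * r
    elif shape_kind == "cube":
        a = float(dims["side"])
        half_extent = np.array([a / 2] * 3)
        truth_v, truth_sa, length = a**3, 6 * a**2, a
    elif shape_kind == "capsule":
        r, h = float(dims["radius"]), float(dims["height"])
        half_extent = np.array([r, r, h / 2 + r])  # capsule axis along x
        truth_v = np.pi * r**2 * h + 4.0 / 3.0 * np.pi * r**3
        truth_sa = 2 * np.pi * r * h + 4 * np.pi * r**2
        length = h + 2 * r
    else:
        raise ValueError(f"unknown shape {shape_kind!r}")

    margin = 8.0
    if shape is None:
        shape = tuple(int(np.ceil(2 * (e + margin))) for e in half_extent)
    center = (np.asarray(shape) - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(n, dtype=np.float32) for n in shape], indexing="ij")
    rel = np.stack([zz - center[0], yy - center[1], xx - center[2]], axis=-1)
    if shape_kind == "sphere":
        mask = (rel**2).sum(-1) <= r**2
    elif shape_kind == "cube":
        mask = np.all(np.abs(rel) <= a / 2, axis=-1)
    else:
        ax = np.clip(np.abs(rel[..., 2]) - h / 2, 0, None)
        mask = rel[..., 0] ** 2 + rel[..., 1] ** 2 + ax**2 <= r**2

    if fill == "solid":
        img = mask.astype(np.float32)
    elif fill == "nuclei":
        img = np.zeros(shape, dtype=np.float32)
        grid_pts = np.stack(
            np.meshgrid(*[np.arange(2.0, n - 2.0, nuclei_spacing) for n in shape], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        grid_pts = grid_pts + rng.uniform(-1.5, 1.5, size=grid_pts.shape)
        inside = mask[tuple(np.clip(np.rint(grid_pts).astype(int), 0, np.asarray(shape) - 1).T)]
        for c in grid_pts[inside]:
            _add_blob(img, c, sigma=1.5)
    else:
        raise ValueError(f"unknown fill {fill!r}")
    truth = {
        "shape_kind": shape_kind,
        "volume_um3": float(truth_v),
        "surface_area_um2": float(truth_sa),
        "length_um": float(length),
        "mask_voxels": int(mask.sum()),
        "seed": seed,
    }
    grid = VoxelGrid(img, spacing=spacing)
    return grid, {**truth, "mask": mask}


def make_allometry_table(
    n_samples: int = 99,
    slopes: tuple[float, float] = (0.10, 0.05),
    breakpoint: float | None = 5.0e5,
    intercept: float = 0.0,
    cell_range: tuple[float, float] = (5.0e4, 2.0e6),
    brain_fraction: float = 0.3,
    noise_cv: float = 0.05,
    seed: int = 0,
):
    """Synthetic (cell, neuron, brain-neuron) counts on a two-segment line.

    Neurons follow a continuous piecewise-linear function of cell count
    (slope ``slopes[0]`` below the breakpoint, ``slopes[1]`` above;
    ``breakpoint=None`` gives a single line), brain neurons a fixed
    fraction of neurons, both with multiplicative lognormal noise of
    coefficient of variation ``noise_cv``.  Defaults mirror a homeostatic
    cohort: ~100 animals, a ~10% neuron fraction among smaller animals
    flattening beyond a cell-count threshold.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    lo, hi = cell_range
    if breakpoint is not None and not lo < breakpoint < hi:
        raise ValueError("breakpoint must lie inside the sampled cell-count range")
    cells = np.exp(rng.uniform(np.log(lo), np.log(hi), n_samples))
    cells.sort()
    if breakpoint is None:
        neurons = intercept + slopes[0] * cells
    else:
        neurons = np.where(
            cells <= breakpoint,
            intercept + slopes[0] * cells,
            intercept + slopes[0] * breakpoint + slopes[1] * (cells - breakpoint),
        )
    sigma = np.sqrt(np.log(1 + noise_cv**2))
    if noise_cv > 0:
        neurons = neurons * np.exp(rng.normal(0, sigma, n_samples) - sigma**2 / 2)
    brain = brain_fraction * neurons
    if noise_cv > 0:
        brain = brain * np.exp(rng.normal(0, sigma, n_samples) - sigma**2 / 2)
    table = pd.DataFrame(
        {"cells": cells, "neurons": neurons, "brain_neurons": brain}
    )
    truth = {
        "slopes": list(slopes),
        "breakpoint": breakpoint,
        "intercept": intercept,
        "brain_fraction": brain_fraction,
        "noise_cv": noise_cv,
        "seed": seed,
    }
    return table, truth
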