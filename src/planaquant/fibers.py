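"""Muscle-fiber detection and tracing by cylinder correlation.

The detector slides a solid-cylinder template over the volume at a
quasi-uniform set of orientations, computing at every voxel the
zero-normalized cross-correlation (ZNCC) with the local neighbourhood,
and keeps per voxel the best correlation and the orientation attaining
it.  Correlation-line tracing then follows the orientation field from
the strongest unclaimed peaks outward in both directions, yielding
polyline traces with physical length and mean orientation, which are
binned into the anatomical fiber classes of the body wall (circular,
diagonal, longitudinal, dorsoventral) and counted per census region.

The anterior-pole recipe parameters (cylinder length 18, outer radius
2.8, mask radius 3, angular sampling 5°) are accepted verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft

from .grid import RegionBox, VoxelGrid

FIBER_CLASSES = ("circular", "diagonal", "longitudinal", "dorsoventral", "unclassified")


@dataclass(frozen=True)
class CylinderTemplate:
    """Solid-cylinder matching template (all dimensions in voxels).

    ``mask_radius`` bounds the background-exclusion zone; voxels between
    ``outer_radius`` and ``mask_radius`` form the (possibly thin)
    background annulus, voxels outside the mask are ignored entirely.
    """

    length: float = 18.0
    outer_radius: float = 2.8
    mask_radius: float = 3.0
    angular_step: float = 5.0

    def __post_init__(self) -> None:
        if not self.length > 2 * self.outer_radius:
            raise ValueError("cylinder length must exceed its diameter")
        if not 0 < self.angular_step <= 90:
            raise ValueError("angular_step must be in (0, 90] degrees")
        if self.mask_radius < self.outer_radius - 1e-9:
            raise ValueError("mask_radius must be >= outer_radius")


@dataclass
class CorrelationField:
    """Per-voxel best ZNCC and best template orientation.

    ``axes`` is the sampled orientation set (unit vectors, z/y/x
    components, antipodally identified); ``best_index`` indexes into it.
    """

    correlation: np.ndarray
    best_index: np.ndarray
    axes: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def axis_at(self, voxel: tuple[int, int, int]) -> np.ndarray:
        return self.axes[self.best_index[voxel]]


@dataclass
class FiberTrace:
    """One traced fiber: ordered 3D points (µm, z/y/x), derived quantities."""

    points: np.ndarray
    orientation: np.ndarray  # unit axis, antipodally identified
    fiber_class: str = "unclassified"
    trace_id: int = 0

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def midpoint(self) -> np.ndarray:
        return self.points[len(self.points) // 2]


@dataclass
class FiberSet:
    """A collection of traces plus the parameters that produced them."""

    fibers: list[FiberTrace]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fibers)

    def __iter__(self):
        return iter(self.fibers)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f in self.fibers:
            oz, oy, ox = f.orientation
            mz, my, mx = f.midpoint
            rows.append(
                {
                    "id": f.trace_id,
                    "length_um": f.length,
                    "orient_z": oz,
                    "orient_y": oy,
                    "orient_x": ox,
                    "class": f.fiber_class,
                    "mid_z_um": mz,
                    "mid_y_um": my,
                    "mid_x_um": mx,
                    "n_points": len(f.points),
                }
            )
        cols = ["id", "length_um", "orient_z", "orient_y", "orient_x", "class",
                "mid_z_um", "mid_y_um", "mid_x_um", "n_points"]
        return pd.DataFrame(rows, columns=cols)

    def to_spatial_graph(self) -> dict:
        """Node/edge JSON-able spatial graph (one chain per fiber)."""
        nodes, edges = [], []
        for f in self.fibers:
            start = len(nodes)
            nodes.extend({"id": start + i, "xyz_um": p.tolist()} for i, p in enumerate(f.points))
            edges.extend(
                {"source": start + i, "target": start + i + 1, "fiber": f.trace_id}
                for i in range(len(f.points) - 1)
            )
        return {"nodes": nodes, "edges": edges, "params": self.params}

    def save_spatial_graph(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_spatial_graph(), fh)


# ---------------------------------------------------------------------------
# orientation sampling


def _canonical_hemisphere(v: np.ndarray) -> np.ndarray:
    """Map unit vectors to the canonical hemisphere (antipodal identification)."""
    v = np.array(v, dtype=float)
    flip = (v[..., 0] < 0) | ((v[..., 0] == 0) & (v[..., 1] < 0)) | (
        (v[..., 0] == 0) & (v[..., 1] == 0) & (v[..., 2] < 0)
    )
    v[flip] *= -1
    return v


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1 - z**2, 0, 1))
    return np.stack([z, r * np.sin(phi), r * np.cos(phi)], axis=1)


def _line_angles_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise undirected angles (deg) between unit-vector sets (n,3),(m,3)."""
    c = np.clip(np.abs(a @ b.T), 0, 1)
    return np.degrees(np.arccos(c))


def make_orientation_set(angular_step: float) -> np.ndarray:
    """Quasi-uniform axis set covering the hemisphere to within ``angular_step``.

    Deterministic: the three coordinate axes first, then golden-spiral
    hemisphere points, grown until every axis of a fixed dense probe set
    lies within ``angular_step`` degrees of a sample.  Antipodal pairs
    are excluded by construction.
    """
    if not 0 < angular_step <= 90:
        raise ValueError("angular_step must be in (0, 90] degrees")
    axes = np.eye(3)
    probe = _canonical_hemisphere(_fibonacci_hemisphere(4096))
    n = max(4, int(0.55 * (180.0 / angular_step) ** 2))
    while True:
        samples = np.concatenate([axes, _canonical_hemisphere(_fibonacci_hemisphere(n))])
        if _line_angles_deg(probe, samples).min(axis=1).max() <= angular_step * 0.98:
            # dedupe near-identical axes, preserving order
            keep = np.ones(len(samples), dtype=bool)
            ang = _line_angles_deg(samples, samples)
            for i in range(len(samples)):
                if keep[i]:
                    dup = (ang[i] < 1e-6) & (np.arange(len(samples)) > i)
                    keep[dup] = False
            return samples[keep]
        n = int(n * 1.3) + 1


# ---------------------------------------------------------------------------
# template rendering and correlation


def render_cylinder(
    template: CylinderTemplate, axis: np.ndarray, edge_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Anti-aliased template and binary mask arrays for one orientation.

    Returns ``(t, m)`` cubes: ``t`` is the interior coverage in [0, 1]
    (linear edge ramp of ``edge_width`` voxels), ``m`` the boolean mask
    out to ``mask_radius``.  Both share an odd cube shape centred on the
    cylinder midpoint.
    """
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    half = int(np.ceil(template.length / 2 + template.mask_radius + 1))
    g = np.arange(-half, half + 1, dtype=np.float32)
    zz, yy, xx = np.meshgrid(g, g, g, indexing="ij")
    t_ax = zz * u[0] + yy * u[1] + xx * u[2]
    rho2 = np.maximum(zz**2 + yy**2 + xx**2 - t_ax**2, 0.0)
    rho = np.sqrt(rho2)
    half_len = template.length / 2.0
    radial = np.clip((template.outer_radius + edge_width / 2 - rho) / edge_width, 0.0, 1.0)
    axial = np.clip((half_len + edge_width / 2 - np.abs(t_ax)) / edge_width, 0.0, 1.0)
    t = (radial * axial).astype(np.float32)
    m = (rho <= template.mask_radius) & (np.abs(t_ax) <= half_len)
    return t, m


def cylinder_correlate(
    grid: VoxelGrid,
    template: CylinderTemplate | None = None,
    axes: np.ndarray | None = None,
) -> CorrelationField:
    """Orientation-swept masked ZNCC against a solid-cylinder template.

    For each sampled orientation the template (zero-meaned and
    unit-normed within its cylindrical mask) is correlated with the
    image; the local image mean and variance inside the rotated mask
    normalize the score to [-1, 1].  Per voxel the maximum over
    orientations and its argmax orientation are kept.  Voxels whose
    masked neighbourhood has (near-)zero variance get correlation 0.
    """
    template = template or CylinderTemplate()
    if axes is None:
        axes = make_orientation_set(template.angular_step)
    axes = np.asarray(axes, dtype=float)
    img = grid.data.astype(np.float32, copy=False)
    if min(img.shape) < template.length:
        raise ValueError("template longer than the smallest grid extent")
    img2 = img * img
    best = np.full(img.shape, -np.inf, dtype=np.float32)
    best_idx = np.zeros(img.shape, dtype=np.int32)
    max_img2 = max(float(img2.max()), 1e-30)

    # all templates share one cube size; cache the image FFTs at the
    # padded shape and reuse them across the whole orientation sweep
    half = int(np.ceil(template.length / 2 + template.mask_radius + 1))
    ksize = 2 * half + 1
    fshape = [fft.next_fast_len(n + ksize - 1) for n in img.shape]
    FI = fft.rfftn(img, fshape)
    FI2 = fft.rfftn(img2, fshape)
    lo = (ksize - 1) // 2  # offset of the 'same' window in the full convolution
    crop_sl = tuple(slice(lo, lo + n) for n in img.shape)

    def _corr_with(Fimg, kernel):
        full = fft.irfftn(Fimg * fft.rfftn(kernel[::-1, ::-1, ::-1], fshape), fshape)
        return full[crop_sl]

    for k, u in enumerate(axes):
        t, m = render_cylinder(template, u)
        mw = m.astype(np.float32)
        n_m = float(mw.sum())
        tm = (t - (t * mw).sum() / n_m) * mw
        norm = float(np.sqrt((tm * tm).sum()))
        if norm == 0:
            continue
        tm /= norm
        num = _corr_with(FI, tm)
        s1 = _corr_with(FI, mw)
        s2 = _corr_with(FI2, mw)
        var = np.maximum(s2 - s1 * s1 / n_m, 0.0)
        # variance floor scaled to the float32 cancellation magnitude of
        # s2 - s1^2/n: windows this flat are constant by convention
        eps = np.float32(1e-5 * n_m * max_img2)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(var > eps, num / np.sqrt(var), 0.0).astype(np.float32)
        upd = corr > best
        best[upd] = corr[upd]
        best_idx[upd] = k
    np.clip(best, -1.0, 1.0, out=best)
    # the masked window is only fully inside the data away from the
    # borders; zero-padded partial windows fake structure, so the border
    # margin is reported as correlation 0 (matching the direct oracle)
    interior = np.zeros(img.shape, dtype=bool)
    interior[half:-half or None, half:-half or None, half:-half or None] = True
    best[~interior] = 0.0
    return CorrelationField(best, best_idx, axes, spacing=grid.spacing)


def zncc_at(
    grid: VoxelGrid, template: CylinderTemplate, axis: np.ndarray, voxel: tuple[int, int, int]
) -> float:
    """Direct (non-FFT) masked ZNCC of one orientation at one voxel.

    Explicit gather-and-dot evaluation, useful as a spot check of the
    convolution path; returns 0 outside the valid interior or where the
    masked neighbourhood variance vanishes.
    """
    t, m = render_cylinder(template, axis)
    half = t.shape[0] // 2
    z, y, x = voxel
    sl = tuple(slice(c - half, c + half + 1) for c in (z, y, x))
    if any(s.start < 0 or s.stop > n for s, n in zip(sl, grid.shape)):
        return 0.0
    patch = grid.data[sl].astype(np.float64)
    mw = m.astype(np.float64)
    n_m = mw.sum()
    tm = (t - (t * mw).sum() / n_m) * mw
    norm = np.sqrt((tm * tm).sum())
    if norm == 0:
        return 0.0
    num = float((patch * tm).sum() / norm)
    var = float((patch * patch * mw).sum() - (patch * mw).sum() ** 2 / n_m)
    if var <= 1e-6 * max(float((patch * patch).max()), 1.0):
        return 0.0
    return num / np.sqrt(var)


# ---------------------------------------------------------------------------
# tracing


def _local_maxima(corr: np.ndarray, threshold: float) -> np.ndarray:
    from scipy.ndimage import maximum_filter

    peaks = (corr >= threshold) & (corr >= maximum_filter(corr, size=3))
    return np.argwhere(peaks)


def trace_correlation_lines(
    fieldv: CorrelationField,
    seed_threshold: float = 0.6,
    continue_threshold: float | None = None,
    step_size: float = 1.0,
    min_length: float = 10.0,
    turn_limit: float = 30.0,
    claim_radius: float = 2.0,
    momentum: float = 0.5,
    recenter: bool = True,
) -> FiberSet:
    """Extract fiber polylines from a correlation/orientation field.

    Seeds are local correlation maxima above ``seed_threshold``, visited
    in descending correlation order.  From each seed the tracer steps
    bidirectionally along the local best orientation (re-read at every
    step, sign-aligned with the direction of travel, per-step turn capped
    at ``turn_limit`` degrees), stopping when the correlation falls below
    ``continue_threshold`` (default ``0.6 * seed_threshold``), the turn
    limit trips, the volume edge is reached, or an already-claimed voxel
    is entered.  Claimed voxels (a ``claim_radius``-voxel tube around
    each accepted trace) can neither seed nor be traversed again, which
    resolves crossings greedily but deterministically.  Traces shorter
    than ``min_length`` µm are discarded (but still claim their voxels).

    Two refinements keep the walk on the ridge: the travel direction is
    an exponential blend (weight ``momentum`` on the previous direction)
    that damps the wobble of the quantized orientation samples, and with
    ``recenter`` each landing point snaps to the best-correlation voxel
    among its neighbours perpendicular to the travel direction, so
    accumulated drift does not walk the tracer off the fiber.
    """
    if continue_threshold is None:
        continue_threshold = 0.6 * seed_threshold
    if not (-1 <= continue_threshold <= 1 and -1 <= seed_threshold <= 1):
        raise ValueError("thresholds must lie in [-1, 1]")
    if continue_threshold > seed_threshold:
        raise ValueError("continue_threshold must not exceed seed_threshold")
    corr = fieldv.correlation
    spacing = np.asarray(fieldv.spacing)
    shape = np.asarray(corr.shape)
    cos_turn = np.cos(np.radians(turn_limit))
    seeds = _local_maxima(corr, seed_threshold)
    if len(seeds) == 0:
        return FiberSet([], params=_trace_params(seed_threshold, continue_threshold, step_size,
                                                 min_length, turn_limit, claim_radius))
    order = np.argsort(-corr[tuple(seeds.T)], kind="stable")
    seeds = seeds[order]
    claimed = np.zeros(corr.shape, dtype=bool)

    # precompute claim-ball offsets
    r = int(np.ceil(claim_radius))
    og = np.arange(-r, r + 1)
    oz, oy, ox = np.meshgrid(og, og, og, indexing="ij")
    ball = np.stack([oz, oy, ox], axis=-1)[oz**2 + oy**2 + ox**2 <= claim_radius**2]

    neigh27 = np.array([(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)])

    fibers: list[FiberTrace] = []
    next_id = 1
    for seed in seeds:
        sv = tuple(int(c) for c in seed)
        if claimed[sv] or corr[sv] < seed_threshold:
            continue
        d0 = fieldv.axes[fieldv.best_index[sv]]
        halves = []
        for sign in (1.0, -1.0):
            pts = []
            p = seed.astype(float)
            d = sign * d0
            while True:
                q = p + step_size * d
                qi = np.rint(q).astype(int)
                if np.any(qi < 0) or np.any(qi >= shape):
                    break
                if recenter:
                    cand = qi + neigh27
                    ok = np.all((cand >= 0) & (cand < shape), axis=1)
                    cand = cand[ok]
                    cand = cand[np.abs((cand - q) @ d) <= 0.5]  # sideways only
                    if len(cand):
                        qi = cand[int(np.argmax(corr[tuple(cand.T)]))]
                qv = tuple(qi)
                if claimed[qv] or corr[qv] < continue_threshold:
                    break
                o = fieldv.axes[fieldv.best_index[qv]]
                if np.dot(o, d) < 0:
                    o = -o
                if np.dot(o, d) < cos_turn:
                    break
                blend = momentum * d + (1.0 - momentum) * o
                pts.append(qi.astype(float))
                p = qi.astype(float)
                d = blend / np.linalg.norm(blend)
                if len(pts) > 100000:  # safety valve
                    break
            halves.append(pts)
        chain = halves[1][::-1] + [seed.astype(float)] + halves[0]
        pts_vox = np.asarray(chain)
        # claim the traced tube regardless of acceptance
        vox = np.rint(pts_vox).astype(int)
        stamped = (vox[:, None, :] + ball[None, :, :]).reshape(-1, 3)
        ok = np.all((stamped >= 0) & (stamped < shape), axis=1)
        claimed[tuple(stamped[ok].T)] = True
        if len(pts_vox) < 2:
            continue
        pts_um = pts_vox * spacing
        length = float(np.linalg.norm(np.diff(pts_um, axis=0), axis=1).sum())
        if length < min_length:
            continue
        ext = pts_um[-1] - pts_um[0]
        nrm = np.linalg.norm(ext)
        orient = _canonical_hemisphere((ext / nrm)[None])[0] if nrm > 0 else d0
        fibers.append(FiberTrace(pts_um, orient, trace_id=next_id))
        next_id += 1
    return FiberSet(fibers, params=_trace_params(seed_threshold, continue_threshold, step_size,
                                                 min_length, turn_limit, claim_radius))


def _trace_params(seed_threshold, continue_threshold, step_size, min_length, turn_limit, claim_radius):
    return {
        "seed_threshold": seed_threshold,
        "continue_threshold": continue_threshold,
        "step_size": step_size,
        "min_length_um": min_length,
        "turn_limit_deg": turn_limit,
        "claim_radius_vox": claim_radius,
    }


# ---------------------------------------------------------------------------
# classification and censuses


def classify_orientation(fibers: FiberSet, body_frame: np.ndarray) -> FiberSet:
    """Assign anatomical classes from each fiber's mean orientation.

    ``body_frame`` rows are the AP (anterior-posterior), ML
    (medio-lateral) and DV (dorso-ventral) unit axes.  A fiber within
    30° of the DV axis is dorsoventral; otherwise its projection onto
    the AP–ML tangent plane is binned by the angle φ to AP:
    longitudinal (φ < 30°), diagonal (30° <= φ < 60°), circular
    (φ >= 60°).  Axes are undirected, so flipping AP changes nothing.
    """
    frame = np.asarray(body_frame, dtype=float)
    if frame.shape != (3, 3) or not np.allclose(frame @ frame.T, np.eye(3), atol=1e-6):
        raise ValueError("body_frame must be three orthonormal axes (AP, ML, DV rows)")
    ap, ml, dv = frame
    for f in fibers:
        u = f.orientation / np.linalg.norm(f.orientation)
        theta_dv = np.degrees(np.arccos(np.clip(abs(float(u @ dv)), 0, 1)))
        if theta_dv < 30.0:
            f.fiber_class = "dorsoventral"
            continue
        tang = u - (u @ dv) * dv
        tang /= np.linalg.norm(tang)
        phi = np.degrees(np.arccos(np.clip(abs(float(tang @ ap)), 0, 1)))
        f.fiber_class = "longitudinal" if phi < 30 else ("diagonal" if phi < 60 else "circular")
    return fibers


def principal_body_frame(mask: VoxelGrid) -> np.ndarray:
    """Body frame from a mask's inertia axes: longest = AP, shortest = DV."""
    coords = np.argwhere(mask.data.astype(bool)) * np.asarray(mask.spacing)
    centered = coords - coords.mean(axis=0)
    w, v = np.linalg.eigh(centered.T @ centered)
    return np.stack([v[:, 2], v[:, 1], v[:, 0]])  # AP, ML, DV


def fiber_region_stats(fibers: FiberSet, region: RegionBox) -> pd.DataFrame:
    """Per-class fiber counts and proportions in a physical census region.

    A fiber counts toward the region if its polyline midpoint lies
    inside.  Proportions sum to 1 over the classes present; with no
    fiber in the region they are reported as null.
    """
    mids = np.array([f.midpoint for f in fibers]).reshape(-1, 3)
    inside = region.contains(mids) if len(fibers) else np.zeros(0, dtype=bool)
    counts = {c: 0 for c in FIBER_CLASSES}
    for f, isin in zip(fibers, inside):
        if isin:
            counts[f.fiber_class] += 1
    total = sum(counts.values())
    rows = [
        {
            "region": region.name or "region",
            "class": c,
            "count": n,
            "proportion": (n / total) if total else None,
        }
        for c, n in counts.items()
    ]
    return pd.DataFrame(rows)
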