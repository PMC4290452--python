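"""Isotropic Fibre Tracking Analysis (IFTA).

Traces the 3D axis of a (possibly curved) microtubule bundle by sphere
stepping: starting from the centre of mass of the densest minus-end cluster,
a sphere of radius R_s is advanced through the bundle; at each step the next
axis point is the point on the sphere surface minimising the mean squared
distance to the positions where microtubules cross the sphere.  That
constrained minimiser has the closed form

    c + R_s * (q_bar - c) / |q_bar - c|

for crossing centroid q_bar — exact, deterministic, and verified against a
numerical optimiser in the tests.  Once the front advances, trace points
inside the sphere are masked so the front cannot move backwards.

The traced axis supports computational straightening: cross-sections are
extracted on planes perpendicular to the axis, with centres expressed in a
2D frame parallel-transported along the axis, from which nearest-neighbour
distances and packing angles quantify the square (midzone, ~40 nm, θ~90°)
versus hexagonal (polar, ~30 nm, θ~60°) organisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .traces import SpindleReconstruction

#: Default sphere-step for axis tracing of anaphase B spindles (nm).
DEFAULT_TRACE_STEP = 200.0
#: Default step for cross-section packing statistics (nm).
DEFAULT_SECTION_STEP = 100.0
#: Traces are assigned to a section only if they cross within this distance
#: of the axis point (nm); keeps unrelated astral structures out.
DEFAULT_CAPTURE_RADIUS = 500.0


class AxisTracingError(RuntimeError):
    """Raised when the spindle axis cannot be traced end to end."""

    def __init__(self, message, partial_path=None):
        super().__init__(message)
        self.partial_path = partial_path


@dataclass
class SpindleAxis:
    """Ordered axis polyline (nm) with its step R_s and contour length."""

    points: np.ndarray
    step: float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)

    @property
    def contour_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class CrossSection:
    """Microtubule centres in a plane perpendicular to the spindle axis.

    axial_position: nm along the axis contour; centres: (n, 2) in-plane nm
    coordinates; pole_labels: pole of origin per centre.
    """

    axial_position: float
    centres: np.ndarray
    pole_labels: np.ndarray

    def __post_init__(self):
        self.centres = np.asarray(self.centres, dtype=float).reshape(-1, 2)
        self.pole_labels = np.asarray(self.pole_labels)


def sphere_point_minimising_msd(centre: np.ndarray, radius: float, crossings: np.ndarray) -> np.ndarray:
    """Point on the sphere minimising mean squared distance to *crossings*.

    Closed form: the sphere point in the direction of the crossing centroid.
    """
    q_bar = np.mean(np.asarray(crossings, dtype=float).reshape(-1, 3), axis=0)
    d = q_bar - centre
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise AxisTracingError("crossing centroid coincides with the sphere centre")
    return centre + radius * d / norm


def _minus_end_cluster(spindle: SpindleReconstruction, pole: str, r_s: float) -> np.ndarray:
    """Centre of mass of the densest minus-end cluster of *pole*.

    The cluster is seeded at the minus end with the most neighbours within
    R_s and contains that end plus those neighbours.
    """
    ends = np.array([t.minus_end_point for t in spindle.traces_for_pole(pole)])
    if len(ends) == 0:
        raise AxisTracingError(f"no minus ends for pole {pole!r}")
    d = np.linalg.norm(ends[:, None, :] - ends[None, :, :], axis=-1)
    within = d <= r_s
    counts = within.sum(axis=1)
    best = int(np.argmax(counts))
    return ends[within[best]].mean(axis=0)


def _segment_sphere_crossings(points, mask, centre, radius):
    """Exact intersection points of a polyline with a sphere surface.

    Only segments whose inside endpoint is unmasked count (masked points are
    behind the advancing front); touching the surface counts as a crossing.
    """
    d = np.linalg.norm(points - centre, axis=1)
    inside = d <= radius
    out = []
    for k in range(len(points) - 1):
        if inside[k] == inside[k + 1]:
            continue
        i_in, i_out = (k, k + 1) if inside[k] else (k + 1, k)
        if mask[i_in]:
            continue
        p, q = points[k], points[k + 1]
        v = q - p
        a = v @ v
        b = 2.0 * (p - centre) @ v
        c = (p - centre) @ (p - centre) - radius * radius
        disc = b * b - 4 * a * c
        if disc < 0:
            continue
        sq = np.sqrt(disc)
        for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
            if 0.0 <= t <= 1.0:
                out.append(p + t * v)
                break
    return out


def _trace_one_direction(spindle, r_s, seed_pole, target_pole):
    start = _minus_end_cluster(spindle, seed_pole, r_s)
    target = _minus_end_cluster(spindle, target_pole, r_s)
    masks = [np.zeros(len(t.points), dtype=bool) for t in spindle.traces]
    path = [start]
    current = start
    max_steps = int(20 * (np.linalg.norm(target - start) / r_s + 10))
    for _ in range(max_steps):
        crossings = []
        for t, m in zip(spindle.traces, masks):
            crossings.extend(_segment_sphere_crossings(t.points, m, current, r_s))
        # advance the front: points inside the current sphere are consumed
        for t, m in zip(spindle.traces, masks):
            m |= np.linalg.norm(t.points - current, axis=1) <= r_s
        if np.linalg.norm(current - target) <= r_s:
            path.append(target)
            return np.asarray(path), True
        if not crossings:
            return np.asarray(path), False
        current = sphere_point_minimising_msd(current, r_s, np.asarray(crossings))
        path.append(current)
    return np.asarray(path), False


def trace_axis(spindle: SpindleReconstruction, step: float = DEFAULT_TRACE_STEP) -> SpindleAxis:
    """Trace the spindle axis by sphere stepping at radius *step* (R_s).

    Both poles are attempted as seed (the richer minus-end cluster alone is
    ambiguous for symmetric bundles); the longer completed trace is kept.
    """
    poles = sorted(spindle.pole_labels())
    if len(poles) != 2:
        raise AxisTracingError(f"need exactly two pole labels, got {poles}")
    for p in poles:
        if len(spindle.traces_for_pole(p)) < 2:
            raise AxisTracingError(f"pole {p!r} has fewer than 2 microtubules")
    results = []
    for seed, tgt in ((poles[0], poles[1]), (poles[1], poles[0])):
        try:
            path, completed = _trace_one_direction(spindle, step, seed, tgt)
        except AxisTracingError:
            continue
        results.append((completed, path))
    completed = [r for r in results if r[0]]
    if not completed:
        best = max(results, key=lambda r: len(r[1]))[1] if results else None
        raise AxisTracingError("axis tracing did not reach the opposite pole", partial_path=best)
    path = max(
        (p for ok, p in completed),
        key=lambda p: float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum()),
    )
    return SpindleAxis(points=path, step=step)


def resample_axis(axis: SpindleAxis, step: float) -> SpindleAxis:
    """Resample the axis polyline at uniform arc-length *step* (nm)."""
    pts = axis.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    total = s[-1]
    n = max(1, int(np.floor(total / step)))
    targets = np.arange(0, n + 1) * step
    targets[-1] = min(targets[-1], total)
    new = np.column_stack([np.interp(targets, s, pts[:, i]) for i in range(3)])
    return SpindleAxis(points=new, step=step)


def _transported_frames(axis_points):
    """Parallel-transported orthonormal frames (e1, e2) along the axis."""
    tangents = np.diff(axis_points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    frames = []
    t0 = tangents[0]
    helper = np.array([0.0, 0.0, 1.0])
    if abs(t0 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(t0, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t0, e1)
    frames.append((e1, e2))
    for i in range(1, len(tangents)):
        a, b = tangents[i - 1], tangents[i]
        v = np.cross(a, b)
        s = np.linalg.norm(v)
        c = float(a @ b)
        if s < 1e-12:
            frames.append(frames[-1])
            continue
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))
        e1, e2 = frames[-1]
        frames.append((rot @ e1, rot @ e2))
    return tangents, frames


def cross_sections(
    spindle: SpindleReconstruction,
    axis: SpindleAxis,
    step: float | None = None,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS,
) -> list[CrossSection]:
    """Extract straightened cross-sections along the axis.

    One section per consecutive axis-point pair: the plane through the pair
    midpoint, perpendicular to the local axis direction.  Each trace
    contributes the plane crossing nearest the axis if it lies within
    *capture_radius*.  Centres are 2D coordinates in the parallel-transported
    frame, i.e. the computationally straightened spindle.
    """
    if step is not None and abs(step - axis.step) > 1e-9:
        axis = resample_axis(axis, step)
    pts = axis.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = seg > 1e-9
    if not np.all(keep):
        pts = np.vstack([pts[0], pts[1:][keep]])
        seg = seg[keep]
    tangents, frames = _transported_frames(pts)
    s_cum = np.concatenate(([0.0], np.cumsum(seg)))
    sections = []
    for i in range(len(pts) - 1):
        mid = 0.5 * (pts[i] + pts[i + 1])
        n = tangents[i]
        e1, e2 = frames[i]
        centres, labels = [], []
        for t in spindle.traces:
            side = (t.points - mid) @ n
            sign_change = np.flatnonzero(np.sign(side[:-1]) * np.sign(side[1:]) < 0)
            exact = np.flatnonzero(side == 0.0)
            cand = []
            for k in sign_change:
                frac = side[k] / (side[k] - side[k + 1])
                cand.append(t.points[k] + frac * (t.points[k + 1] - t.points[k]))
            for k in exact:
                cand.append(t.points[k])
            if not cand:
                continue
            cand = np.asarray(cand)
            dist = np.linalg.norm(cand - mid, axis=1)
            j = int(np.argmin(dist))
            if dist[j] <= capture_radius:
                r = cand[j] - mid
                centres.append((r @ e1, r @ e2))
                labels.append(t.pole)
        sections.append(
            CrossSection(
                axial_position=float(0.5 * (s_cum[i] + s_cum[i + 1])),
                centres=np.asarray(centres, dtype=float).reshape(-1, 2),
                pole_labels=np.asarray(labels),
            )
        )
    return sections


def nn_distances(section: CrossSection) -> np.ndarray:
    """Per-centre distance to its nearest other centre (nm); empty if < 2."""
    c = section.centres
    if len(c) < 2:
        return np.empty(0)
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def _modal_nn(section: CrossSection) -> float:
    d = nn_distances(section)
    if len(d) == 0:
        return np.nan
    vals, counts = np.unique(np.round(d), return_counts=True)
    return float(vals[np.argmax(counts)])


def packing_angles(section: CrossSection, neighbour_cutoff: float | None = None) -> np.ndarray:
    """Vertex angles (degrees) subtended by neighbour pairs at each centre.

    Neighbours are centres within *neighbour_cutoff* (default 1.25x the modal
    nearest-neighbour distance).  Angles are reported in [0°, 120°]; a square
    lattice yields 90°, a hexagonal lattice 60°.
    """
    c = section.centres
    if len(c) < 3:
        return np.empty(0)
    if neighbour_cutoff is None:
        neighbour_cutoff = 1.25 * _modal_nn(section)
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    angles = []
    for i in range(len(c)):
        nb = np.flatnonzero(d[i] <= neighbour_cutoff)
        if len(nb) < 2:
            continue
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                u = c[nb[a]] - c[i]
                v = c[nb[b]] - c[i]
                cosang = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
                ang = np.degrees(np.arccos(cosang))
                if ang <= 120.0 + 1e-9:
                    angles.append(ang)
    return np.asarray(angles)


def classify_midzone(sections: list[CrossSection]) -> tuple[float, float]:
    """Maximal contiguous axial interval whose sections contain >= 2 centres
    from each pole (the region of antiparallel microtubule overlap).

    Returns (start, end) in nm along the contour; (nan, nan) if no section
    qualifies.  The interval extends half a section step past the outermost
    qualifying sections.
    """
    if not sections:
        return (np.nan, np.nan)
    ok = []
    for s in sections:
        labels, counts = np.unique(s.pole_labels, return_counts=True)
        ok.append(len(labels) == 2 and counts.min() >= 2)
    ok = np.asarray(ok)
    if not ok.any():
        return (np.nan, np.nan)
    # longest run of True
    best_len, best_start = 0, 0
    run_len, run_start = 0, 0
    for i, v in enumerate(ok):
        if v:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    first, last = best_start, best_start + best_len - 1
    pos = np.array([s.axial_position for s in sections])
    step = np.median(np.diff(pos)) if len(pos) > 1 else 0.0
    return (float(pos[first] - step / 2), float(pos[last] + step / 2))


def midzone_sections(sections: list[CrossSection]) -> list[CrossSection]:
    """Sections inside the classified midzone interval."""
    lo, hi = classify_midzone(sections)
    if np.isnan(lo):
        return []
    return [s for s in sections if lo <= s.axial_position <= hi]


def polar_sections(sections: list[CrossSection]) -> list[CrossSection]:
    """Sections outside the classified midzone interval (with >= 2 centres)."""
    lo, hi = classify_midzone(sections)
    if np.isnan(lo):
        return [s for s in sections if len(s.centres) >= 2]
    return [
        s for s in sections
        if (s.axial_position < lo or s.axial_position > hi) and len(s.centres) >= 2
    ]


def compare_regions(values_polar, values_midzone):
    """Two-sample Kolmogorov–Smirnov test between region statistics.

    Returns (statistic, p_value).
    """
    values_polar = np.asarray(values_polar, dtype=float)
    values_midzone = np.asarray(values_midzone, dtype=float)
    if len(values_polar) < 2 or len(values_midzone) < 2:
        raise ValueError("need at least 2 values per region for a KS test")
    res = stats.ks_2samp(values_polar, values_midzone)
    return float(res.statistic), float(res.pvalue)
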