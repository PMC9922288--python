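"""Temporal smoothing, volume/flow curves, and scalar flow metrics.

Vertex trajectories are smoothed with least-squares cubic B-splines (15
interior knots by default) over the periodically extended cycle.  Chamber
volumes are evaluated on a 5 ms grid via the divergence theorem and
differentiated to flow rates; transmitral E/A metrics and LAA outflow
metrics are read off the curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline, make_lsq_spline

from .mesh_core import (OrificePlane, Region, RegionLabels, SurfaceMesh,
                        cap_boundary_loops, cap_topology, clip_by_plane,
                        enclosed_volume, extract_by_labels, loop_centroids,
                        surface_area)

__all__ = [
    "SplineMotion",
    "VolumeCurve",
    "FlowCurve",
    "FlowMetrics",
    "fit_motion_splines",
    "volume_curve",
    "mitral_flow_curve",
    "laa_flow_curve",
    "laa_area_curve",
    "ostium_plane_from_labels",
    "flow_metrics",
]


@dataclass
class SplineMotion:
    """Per-vertex, per-coordinate cubic B-spline motion over one cycle."""

    spline: BSpline                    # vector-valued: (t,) -> (n, 3)
    cycle_length: float
    max_fit_deviation: float           # diagnostic: max |spline - samples| (mm)

    def sample(self, t) -> np.ndarray:
        """Positions at time(s) t in [0, cycle_length]; scalar t gives
        (n, 3), array t gives (len(t), n, 3)."""
        t = np.mod(np.asarray(t, dtype=float), self.cycle_length + 1e-15)
        t = np.clip(t, 0.0, self.cycle_length)
        return self.spline(t)

    def export_times(self, dt: float = 0.0005) -> np.ndarray:
        n = int(round(self.cycle_length / dt))
        return np.arange(n + 1) * dt


def fit_motion_splines(seq, n_knots: int = 15) -> SplineMotion:
    """Least-squares cubic B-spline per vertex coordinate.

    The samples are extended periodically (frame 0 repeated at t = T) before
    fitting; ``n_knots`` counts interior knots.
    """
    n_frames = seq.n_frames
    if n_frames < 8:
        raise ValueError("need at least 8 frames to fit motion splines")
    # cubic fit needs n_knots + 4 coefficients <= n_frames + 1 samples
    if n_knots + 4 > n_frames + 1:
        raise ValueError(
            f"{n_knots} interior knots need {n_knots + 4} coefficients but only "
            f"{n_frames + 1} samples are available")
    T = seq.cycle_length
    t_samples = np.concatenate([seq.frame_times_s, [T]])
    y = np.concatenate([seq.positions, seq.positions[:1]], axis=0)
    y_flat = y.reshape(n_frames + 1, -1)

    interior = np.linspace(0.0, T, n_knots + 2)[1:-1]
    knots = np.concatenate([[0.0] * 4, interior, [T] * 4])
    spl = make_lsq_spline(t_samples, y_flat, knots, k=3)

    fitted = spl(t_samples)
    deviation = float(np.max(np.abs(fitted - y_flat)))

    n = seq.positions.shape[1]
    coeffs = spl.c.reshape(-1, n, 3)
    vector_spl = BSpline(spl.t, coeffs, 3, extrapolate=False)
    return SplineMotion(spline=vector_spl, cycle_length=T,
                        max_fit_deviation=deviation)


@dataclass
class VolumeCurve:
    times: np.ndarray        # seconds, uniform grid
    volumes: np.ndarray      # ml

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if len(self.times) != len(self.volumes):
            raise ValueError("times and volumes length mismatch")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class FlowCurve:
    """Flow rate in ml/s on the volume-curve grid.

    ``flow`` is the physiologically signed channel (inflow / emptying
    positive, clamped at zero outside the orifice's flow phase for the MV);
    ``raw_dvdt`` retains the uninterpreted volume derivative.
    """

    times: np.ndarray
    flow: np.ndarray
    raw_dvdt: np.ndarray | None = None


@dataclass
class FlowMetrics:
    e_peak: float            # ml/s
    a_peak: float            # ml/s
    e_time: float            # s
    a_time: float            # s
    peak_time_span: float    # s
    stroke_volume: float     # ml
    ef_af_ratio: float
    laa_peak_outflow: float  # ml/s
    laa_peak_outflow_time: float  # s
    laa_area_factor: float

    def as_dict(self) -> dict[str, float]:
        return {
            "e_peak_ml_per_s": self.e_peak,
            "a_peak_ml_per_s": self.a_peak,
            "e_time_s": self.e_time,
            "a_time_s": self.a_time,
            "peak_time_span_s": self.peak_time_span,
            "stroke_volume_ml": self.stroke_volume,
            "ef_af_ratio": self.ef_af_ratio,
            "laa_peak_outflow_ml_per_s": self.laa_peak_outflow,
            "laa_peak_outflow_time_s": self.laa_peak_outflow_time,
            "laa_area_factor": self.laa_area_factor,
        }


# ---------------------------------------------------------------------------
# volume / flow curves


def _grid(cycle_length: float, dt: float) -> np.ndarray:
    n = int(round(cycle_length / dt))
    if abs(n * dt - cycle_length) > 1e-9 * max(1.0, cycle_length):
        n = int(np.floor(cycle_length / dt))
    return np.arange(n + 1) * dt


class _RegionVolumeSampler:
    """Extracts a region submesh once and re-caps it per time sample."""

    def __init__(self, mesh: SurfaceMesh, labels: RegionLabels,
                 allowed: set[Region]):
        self.sub, self.vertex_map = extract_by_labels(mesh, labels, allowed)
        if self.sub.n_faces == 0:
            raise ValueError("region produces an empty submesh")
        self.cap_faces, self.loops = cap_topology(self.sub)
        self.faces = (np.vstack([self.sub.faces, self.cap_faces])
                      if len(self.cap_faces) else self.sub.faces)

    def volume(self, full_positions: np.ndarray) -> float:
        v = full_positions[self.vertex_map]
        if self.loops:
            v = np.vstack([v, loop_centroids(v, self.loops)])
        closed = SurfaceMesh(v, self.faces)
        return enclosed_volume(closed)


_REGION_SETS = {
    Region.LV: {Region.LV},
    Region.LA: {Region.LA, Region.LAA_OSTIUM, Region.BOUNDARY_RING},
    Region.LAA: {Region.LAA, Region.LAA_OSTIUM},
}


def volume_curve(motion: SplineMotion, mesh: SurfaceMesh, labels: RegionLabels,
                 region: Region, dt: float = 0.005) -> VolumeCurve:
    """Region volume every ``dt`` seconds from the smoothed motion."""
    region = Region(region)
    sampler = _RegionVolumeSampler(mesh, labels, _REGION_SETS[region])
    times = _grid(motion.cycle_length, dt)
    volumes = np.empty(len(times))
    for i, t in enumerate(times):
        try:
            volumes[i] = sampler.volume(motion.sample(float(t)))
        except ValueError as exc:
            raise ValueError(f"capping failed at t = {t:.4f} s: {exc}") from exc
    return VolumeCurve(times=times, volumes=volumes)


def _wrapped_central_difference(values: np.ndarray, dt: float) -> np.ndarray:
    """Central differences on a periodic grid whose last sample repeats the
    first (t = 0 and t = T are the same cycle phase)."""
    n = len(values) - 1
    dv = np.empty_like(values)
    dv[1:n] = (values[2:] - values[:n - 1]) / (2 * dt)
    dv[0] = (values[1] - values[n - 1]) / (2 * dt)
    dv[n] = dv[0]
    return dv


def mitral_flow_curve(lv_volume: VolumeCurve) -> FlowCurve:
    """Transmitral flow from the LV volume curve.

    The raw channel is dV_LV/dt; mitral inflow is its positive part (LV
    volume rises during diastolic filling), ejection-phase samples are
    reported as zero.
    """
    raw = _wrapped_central_difference(lv_volume.volumes, lv_volume.dt)
    return FlowCurve(times=lv_volume.times, flow=np.maximum(raw, 0.0),
                     raw_dvdt=raw)


def ostium_plane_from_labels(mesh: SurfaceMesh, labels: RegionLabels) -> OrificePlane:
    """Least-squares plane through the LAA ostium ring at frame 0, with the
    normal oriented from the LAA toward the LA."""
    ring = labels.indices_of(Region.LAA_OSTIUM)
    if len(ring) < 3:
        raise ValueError("ostium ring needs at least 3 vertices")
    pts = mesh.vertices[ring]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    laa_centroid = mesh.vertices[labels.indices_of(Region.LAA)].mean(axis=0)
    if (laa_centroid - centroid) @ normal > 0:  # normal must point away from LAA
        normal = -normal
    return OrificePlane(point=centroid, unit_normal=normal)


def laa_flow_curve(motion: SplineMotion, mesh: SurfaceMesh, labels: RegionLabels,
                   plane: OrificePlane, dt: float = 0.005,
                   ring_tolerance_fraction: float = 0.05) -> FlowCurve:
    """LAA orifice flow: clip the closed surface at the static ostium plane
    every ``dt`` and differentiate; emptying (outflow into the LA) positive."""
    ring = labels.indices_of(Region.LAA_OSTIUM)
    ring_dist = np.abs(plane.signed_distance(mesh.vertices[ring]))
    tol = ring_tolerance_fraction * mesh.bbox_diagonal()
    if ring_dist.max(initial=0.0) > tol:
        raise ValueError(
            "ostium ring is not on the orifice plane at frame 0 "
            f"(max distance {ring_dist.max():.3g} mm > {tol:.3g} mm); the "
            "plane does not separate LAA from LA")

    times = _grid(motion.cycle_length, dt)
    volumes = np.empty(len(times))
    for i, t in enumerate(times):
        frame = mesh.with_vertices(motion.sample(float(t)))
        closed = cap_boundary_loops(frame)
        laa_part = clip_by_plane(closed, plane, keep="negative")
        volumes[i] = enclosed_volume(laa_part) if laa_part.n_faces else 0.0
    raw = _wrapped_central_difference(volumes, float(times[1] - times[0]))
    return FlowCurve(times=times, flow=-raw, raw_dvdt=raw)


def laa_area_curve(seq) -> np.ndarray:
    """Per-frame LAA surface area (mm^2) from the tracked frames."""
    sub, vmap = extract_by_labels(seq.mesh, seq.labels,
                                  {Region.LAA, Region.LAA_OSTIUM})
    return np.array([surface_area(sub.with_vertices(p[vmap]))
                     for p in seq.positions])


# ---------------------------------------------------------------------------
# metrics


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local maxima of a 1-D array."""
    idx = []
    n = len(y)
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[j]:
                j += 1
            if j + 1 < n and y[j + 1] < y[j]:
                idx.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.asarray(idx, dtype=np.int64)


def flow_metrics(mv: FlowCurve, laa: FlowCurve | None = None,
                 areas: np.ndarray | None = None,
                 min_peak_separation_fraction: float = 0.05,
                 peak_height_fraction: float = 0.05,
                 diastole_tolerance_fraction: float = 0.10) -> FlowMetrics:
    """Scalar flow indices from the MV and LAA flow curves.

    Diastole is the contiguous inflow interval containing the global MV
    maximum (small negative excursions below ``diastole_tolerance_fraction``
    of the peak are tolerated so diastasis does not split the interval).
    The E peak is the first local maximum in diastole and the A peak the
    last; they must be distinct and separated by at least
    ``min_peak_separation_fraction`` of the cycle.
    """
    q = np.asarray(mv.flow, dtype=float)
    raw = q if mv.raw_dvdt is None else np.asarray(mv.raw_dvdt, dtype=float)
    times = np.asarray(mv.times, dtype=float)
    n = len(q) - 1                      # last sample repeats phase 0
    period = times[n]
    dt = times[1] - times[0]
    qmax = q.max()
    if qmax <= 0:
        raise ValueError("no positive mitral inflow found")

    # circular bookkeeping: rotate so the global max sits mid-array
    imax = int(np.argmax(q[:n]))
    shift = imax - n // 2
    q_rot = np.roll(q[:n], -shift)
    raw_rot = np.roll(raw[:n], -shift)

    tol = diastole_tolerance_fraction * qmax
    center = n // 2
    lo = center
    while lo > 0 and raw_rot[lo - 1] > -tol:
        lo -= 1
    hi = center
    while hi < n - 1 and raw_rot[hi + 1] > -tol:
        hi += 1
    if hi - lo >= n - 1:
        raise ValueError("could not delimit diastole: inflow never stops")

    window = q_rot[lo:hi + 1]
    peaks = _local_maxima(window)
    peaks = peaks[window[peaks] >= peak_height_fraction * qmax]
    if len(peaks) < 2:
        raise ValueError("E/A not separable: fewer than two distinct "
                         "diastolic maxima")
    e_i, a_i = int(peaks[0]), int(peaks[-1])
    if (a_i - e_i) * dt < min_peak_separation_fraction * period:
        raise ValueError("E/A not separable: peaks too close")
    if window[e_i:a_i + 1].min() >= min(window[e_i], window[a_i]):
        raise ValueError("E/A not separable: no local minimum between peaks")

    def unrot_time(i_window: int) -> float:
        return float(np.mod((lo + i_window + shift) * dt, period))

    e_time, a_time = unrot_time(e_i), unrot_time(a_i)
    e_peak, a_peak = float(window[e_i]), float(window[a_i])
    peak_time_span = (a_i - e_i) * dt

    # net filling volume over diastole, read off the cumulative integral of
    # the raw derivative: its range inside the window is exactly the volume
    # gained between the local ESV and EDV, and zero-mean diastasis noise
    # cancels instead of being rectified upward
    from scipy.integrate import cumulative_trapezoid
    cum = cumulative_trapezoid(raw_rot[lo:hi + 1], dx=dt, initial=0.0)
    stroke_volume = float(cum.max() - cum.min())

    laa_peak = laa_peak_time = float("nan")
    if laa is not None:
        laa_flow = np.asarray(laa.flow, dtype=float)
        k = int(np.argmax(laa_flow[:n]))
        laa_peak = float(laa_flow[k])
        laa_peak_time = float(laa.times[k])

    area_factor = float("nan")
    if areas is not None:
        areas = np.asarray(areas, dtype=float)
        if areas.min() <= 0:
            raise ValueError("non-positive LAA area")
        area_factor = float(areas.max() / areas.min())

    return FlowMetrics(
        e_peak=e_peak, a_peak=a_peak, e_time=e_time, a_time=a_time,
        peak_time_span=float(peak_time_span), stroke_volume=stroke_volume,
        ef_af_ratio=e_peak / a_peak, laa_peak_outflow=laa_peak,
        laa_peak_outflow_time=laa_peak_time, laa_area_factor=area_factor,
    )
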