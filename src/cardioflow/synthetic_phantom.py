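"""Deforming left-heart phantom with analytic ground truth.

Geometry (frame 0 = end diastole):

* LV: lower half-ellipsoid (z <= 0), semi-axes (r0, r0, c_lv), sized so the
  enclosed half-ellipsoid volume equals the end-diastolic volume.  It
  deforms by a pure axis scaling (sr, sr, sz) about the origin with
  sr = sz = s(t)^(1/3) and s(t) = V_LV(t)/EDV, so the analytic volume is
  exact at every time.
* LA: upper half-ellipsoid (z >= 0) sharing the equatorial ring with the LV
  (the open mitral/aortic plane).  A polar hole stands in for the
  pulmonary-vein cut: its rim is the frozen boundary ring.  The lower LA
  blends smoothly into the LV's radial scaling and is static above the
  blend zone, so the boundary ring and the LAA ostium never move.
* LAA: a cone pouch grafted onto a circular ostium ring on the static upper
  LA wall.  It contracts by a tapered isotropic scaling about the ostium
  (taper keeps the base attached), driven by a prescribed volume curve
  V_LAA(t); the per-time scale factor is recovered by root finding on the
  exact 1-D volume integral of the deformed profile.

Volume dynamics are sums of smooth compact-support (bump) pulses: an
ejection pulse empties the LV in systole and E-/A-pulses refill it, so the
true stroke volume, peak flows and peak times are known in closed form.

All targets are generated on an independent parameter grid (different
resolution and azimuthal offset from the source) so nearest-neighbor
correspondences are never index-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .mesh_core import Region, RegionLabels, SurfaceMesh

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomData",
    "generate_phantom_cycle",
    "phantom_truth_at",
]


# ---------------------------------------------------------------------------
# smooth compact-support pulses

_BUMP_PEAK = float(np.exp(-1.0))


def _bump_raw(x):
    """exp(-1/(1-x^2)) on (-1, 1), zero outside; C-infinity everywhere."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    inside = np.abs(x) < 1.0
    xi = x[inside]
    out[inside] = np.exp(-1.0 / (1.0 - xi * xi))
    return out


_BUMP_AREA = quad(lambda x: float(_bump_raw(x)), -1, 1, epsabs=1e-14)[0]

# normalized CDF of the bump on a dense grid (smooth integrand: Simpson on a
# fine grid is accurate to ~1e-12, and the endpoints are exact by
# normalization)
_CDF_X = np.linspace(-1.0, 1.0, 8193)
from scipy.integrate import cumulative_simpson as _cumsimp  # noqa: E402

_CDF_Y = _cumsimp(_bump_raw(_CDF_X), x=_CDF_X, initial=0.0)
_CDF_Y /= _CDF_Y[-1]


def _bump_cdf(x):
    return np.interp(np.asarray(x, dtype=float), _CDF_X, _CDF_Y, left=0.0, right=1.0)


def _bump_unit_area(x, width):
    """Unit-area pulse with half-width ``width`` centered at 0."""
    return _bump_raw(np.asarray(x) / width) / (width * _BUMP_AREA)


def _bump_unit_peak(x):
    """Bump scaled to peak value 1 at x = 0."""
    return _bump_raw(x) / _BUMP_PEAK


def _smootherstep(u):
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    return u ** 3 * (u * (6.0 * u - 15.0) + 10.0)


def _smootherstep_d(u):
    u = np.asarray(u, dtype=float)
    inside = (u > 0) & (u < 1)
    out = np.zeros_like(u)
    ui = u[inside]
    out[inside] = 30.0 * ui ** 2 * (ui - 1.0) ** 2
    return out


# ---------------------------------------------------------------------------
# spec


@dataclass
class PhantomSpec:
    """Parameters of the synthetic left-heart cycle (times in %RR unless
    noted)."""

    cycle_length: float = 1.0          # s
    n_frames: int = 20
    lv_edv: float = 120.0              # ml
    lv_esv: float = 50.0               # ml
    e_fraction: float = 0.7
    a_fraction: float = 0.3
    e_time: float = 55.0               # %RR
    a_time: float = 85.0               # %RR
    ejection_time: float = 20.0        # %RR
    pulse_width: float = 10.0          # half-width of E/A pulses, %RR
    ejection_width: float = 15.0       # half-width of ejection pulse, %RR
    laa_vmax: float = 8.0              # ml
    laa_vmin: float = 3.0              # ml
    laa_contraction_time: float = 90.0  # %RR
    # The contraction pulse is asymmetric.  The emptying flank (which
    # defines the measured peak outflow) is wide enough that 20 frames plus
    # 15-knot splines resolve the peak — narrower flanks lose >10% of it to
    # temporal sampling alone.  The refill flank is fast and confined to the
    # cycle end, so the chained registration meets it right next to the
    # pristine 0 %RR source instead of deep inside the backward chain.
    laa_contraction_width: float = 25.0  # emptying half-width, %RR
    laa_refill_width: float = 25.0       # refill half-width, %RR
    mesh_resolution: float = 4.0       # mm, source triangle edge target
    laa_resolution: float = 1.7        # mm, finer LAA triangles
    target_resolution_factor: float = 0.85
    target_jitter_sd: float = 0.0      # mm
    seed: int = 0

    # geometry shape factors
    lv_height_factor: float = 1.5      # c_lv / r0
    la_height_factor: float = 0.95     # c_la / r0
    laa_aspect: float = 4.0            # pouch length / ostium radius
    laa_elevation_deg: float = 45.0    # ostium center latitude on the LA
    laa_azimuth_deg: float = 180.0     # away from the grid seam
    pv_hole_deg: float = 13.0          # polar-hole half-angle (boundary ring)
    la_blend_top: float = 0.32         # blend zone top as fraction of c_la
    laa_taper_fraction: float = 0.35   # base taper extent of the LAA scaling

    def __post_init__(self) -> None:
        if not (self.lv_edv > self.lv_esv > 0):
            raise ValueError("need lv_edv > lv_esv > 0")
        if abs(self.e_fraction + self.a_fraction - 1.0) > 1e-12:
            raise ValueError("e_fraction + a_fraction must equal 1")
        if not (self.laa_vmax > self.laa_vmin > 0):
            raise ValueError("need laa_vmax > laa_vmin > 0")
        if self.n_frames < 8 or self.n_frames % 2:
            raise ValueError("n_frames must be even and >= 8")
        for c, w, name in [(self.ejection_time, self.ejection_width, "ejection"),
                           (self.e_time, self.pulse_width, "E"),
                           (self.a_time, self.pulse_width, "A")]:
            if c - w < 0 or c + w > 100:
                raise ValueError(f"infeasible spec: {name} pulse support "
                                 "crosses the cycle boundary")

    # derived geometry (mm)
    @property
    def r0(self) -> float:
        edv_mm3 = self.lv_edv * 1000.0
        return (edv_mm3 * 3.0 / (2.0 * np.pi * self.lv_height_factor)) ** (1.0 / 3.0)

    @property
    def c_lv(self) -> float:
        return self.lv_height_factor * self.r0

    @property
    def c_la(self) -> float:
        return self.la_height_factor * self.r0

    @property
    def laa_r_ost(self) -> float:
        # cone profile r(u) = R (1 - u): V = (1/3) pi R^2 L
        vmax_mm3 = self.laa_vmax * 1000.0
        return (3.0 * vmax_mm3 / (np.pi * self.laa_aspect)) ** (1.0 / 3.0)

    @property
    def laa_length(self) -> float:
        return self.laa_aspect * self.laa_r_ost

    @property
    def stroke_volume(self) -> float:
        return self.lv_edv - self.lv_esv


# ---------------------------------------------------------------------------
# analytic volume dynamics


def _lv_volume(spec: PhantomSpec, t) -> np.ndarray:
    """Closed-form V_LV(t) in ml; V(0) = EDV, periodic with the cycle."""
    T = spec.cycle_length
    tt = np.mod(np.asarray(t, dtype=float), T)
    sv = spec.stroke_volume

    def cdf(center_pct, width_pct):
        c = center_pct / 100.0 * T
        w = width_pct / 100.0 * T
        return _bump_cdf((tt - c) / w)

    v = (spec.lv_edv
         - sv * cdf(spec.ejection_time, spec.ejection_width)
         + sv * spec.e_fraction * cdf(spec.e_time, spec.pulse_width)
         + sv * spec.a_fraction * cdf(spec.a_time, spec.pulse_width))
    return v


def _lv_dvdt(spec: PhantomSpec, t) -> np.ndarray:
    """Closed-form dV_LV/dt in ml/s."""
    T = spec.cycle_length
    tt = np.mod(np.asarray(t, dtype=float), T)
    sv = spec.stroke_volume

    def pulse(center_pct, width_pct):
        c = center_pct / 100.0 * T
        w = width_pct / 100.0 * T
        return _bump_unit_area(tt - c, w)

    return (-sv * pulse(spec.ejection_time, spec.ejection_width)
            + sv * spec.e_fraction * pulse(spec.e_time, spec.pulse_width)
            + sv * spec.a_fraction * pulse(spec.a_time, spec.pulse_width))


def _laa_pulse_x(spec: PhantomSpec, t) -> np.ndarray:
    """Scaled pulse coordinate of the asymmetric contraction bump: the
    emptying flank (before the minimum) uses the contraction half-width,
    the refill flank the (shorter) refill half-width.  Evaluated
    periodically; C1 at the minimum."""
    T = spec.cycle_length
    tt = np.mod(np.asarray(t, dtype=float), T)
    c = spec.laa_contraction_time / 100.0 * T
    w_e = spec.laa_contraction_width / 100.0 * T
    w_r = spec.laa_refill_width / 100.0 * T
    x = np.full_like(tt, np.inf)
    for k in (-1.0, 0.0, 1.0):
        d = tt - c + k * T
        xk = np.where(d < 0, d / w_e, d / w_r)
        x = np.where(np.abs(xk) < np.abs(x), xk, x)
    return x


def _laa_volume(spec: PhantomSpec, t) -> np.ndarray:
    """Prescribed V_LAA(t) in ml; vmax at rest, vmin at the contraction
    minimum."""
    b = _bump_unit_peak(_laa_pulse_x(spec, t))
    return spec.laa_vmax - (spec.laa_vmax - spec.laa_vmin) * b


def _laa_dvdt(spec: PhantomSpec, t) -> np.ndarray:
    T = spec.cycle_length
    x = _laa_pulse_x(spec, t)
    w_e = spec.laa_contraction_width / 100.0 * T
    w_r = spec.laa_refill_width / 100.0 * T
    w = np.where(x < 0, w_e, w_r)
    out = np.zeros_like(x)
    inside = np.abs(x) < 1.0
    xi = x[inside]
    # d/dx exp(1 - 1/(1-x^2)) = -2x/(1-x^2)^2 * exp(1 - 1/(1-x^2))
    out[inside] = (-(spec.laa_vmax - spec.laa_vmin) / w[inside]
                   * (-2.0 * xi / (1.0 - xi * xi) ** 2)
                   * np.exp(1.0 - 1.0 / (1.0 - xi * xi)))
    return out


# ---------------------------------------------------------------------------
# LAA cone profile and its exact deformed volume / area


class _LaaShape:
    """Blunt pouch of length L and base radius R deformed by a tapered
    scaling.

    The profile is a cone r(u) = R (1 - u) (u = 0 base, u = 1 tip).  A
    point at axial fraction u scales by f(u, k) = 1 + (k - 1) * h(u) in
    both the axial and radial direction, with h a smootherstep ramp over
    the taper zone (h(0) = 0 keeps the base ring fixed).  Volume and
    lateral area of the deformed smooth pouch are 1-D integrals over u,
    evaluated with fixed-order Gauss-Legendre.
    """

    @staticmethod
    def profile(u):
        return 1.0 - np.asarray(u, dtype=float)

    @staticmethod
    def profile_d(u):
        return np.full_like(np.asarray(u, dtype=float), -1.0)

    def __init__(self, R: float, L: float, taper: float):
        self.R, self.L, self.taper = R, L, taper
        gl_x, gl_w = np.polynomial.legendre.leggauss(96)
        self._u = 0.5 * (gl_x + 1.0)
        self._w = 0.5 * gl_w
        # the axial map stays monotone only while 1 + (k-1)(h + u h') > 0
        hmax = float(np.max(self._h(self._u) + self._u * self._h_d(self._u)))
        self.k_floor = max(0.02, 1.0 - 0.98 / hmax)

    def _h(self, u):
        return _smootherstep(np.asarray(u) / self.taper)

    def _h_d(self, u):
        return _smootherstep_d(np.asarray(u) / self.taper) / self.taper

    def scale(self, u, k: float):
        return 1.0 + (k - 1.0) * self._h(u)

    def volume_mm3(self, k: float) -> float:
        """pi * int r'(u)^2 d(xi') with xi' = L*u*f, r' = R*p(u)*f."""
        u, w = self._u, self._w
        f = self.scale(u, k)
        fd = (k - 1.0) * self._h_d(u)
        r2 = (self.R * self.profile(u) * f) ** 2
        dxi = self.L * (f + u * fd)
        return float(np.pi * np.sum(w * r2 * dxi))

    def lateral_area_mm2(self, k: float) -> float:
        u, w = self._u, self._w
        f = self.scale(u, k)
        fd = (k - 1.0) * self._h_d(u)
        r = self.R * self.profile(u) * f
        drdu = self.R * (self.profile_d(u) * f + self.profile(u) * fd)
        dxidu = self.L * (f + u * fd)
        return float(2.0 * np.pi * np.sum(w * r * np.sqrt(drdu ** 2 + dxidu ** 2)))

    def scale_for_volume(self, v_mm3: float) -> float:
        v0 = self.volume_mm3(1.0)
        if abs(v_mm3 - v0) < 1e-9 * v0:
            return 1.0
        if v_mm3 < self.volume_mm3(self.k_floor):
            raise ValueError(
                "infeasible spec: requested LAA volume below the smallest "
                "reachable by the contraction map; raise laa_vmin or the "
                "taper fraction")
        return float(brentq(lambda k: self.volume_mm3(k) - v_mm3,
                            self.k_floor, 2.0, xtol=1e-13))


# ---------------------------------------------------------------------------
# truth container


@dataclass
class PhantomTruth:
    """Analytic ground truth of one phantom cycle."""

    spec: PhantomSpec
    frame_times: np.ndarray            # s
    v_lv: np.ndarray                   # ml per frame
    v_laa: np.ndarray                  # ml per frame
    a_laa: np.ndarray                  # mm^2 per frame (smooth cone, lateral)
    e_peak: float = 0.0                # ml/s
    a_peak: float = 0.0
    e_time: float = 0.0                # s
    a_time: float = 0.0
    stroke_volume: float = 0.0         # ml
    ef_af_ratio: float = 0.0
    laa_peak_outflow: float = 0.0      # ml/s
    laa_peak_outflow_time: float = 0.0
    laa_area_factor: float = 0.0
    _shape: _LaaShape = field(default=None, repr=False)

    def lv_volume(self, t):
        return _lv_volume(self.spec, t)

    def laa_volume(self, t):
        return _laa_volume(self.spec, t)

    def mv_flow(self, t):
        return np.maximum(_lv_dvdt(self.spec, t), 0.0)

    def laa_outflow(self, t):
        return -_laa_dvdt(self.spec, t)

    def laa_area(self, t):
        v = np.atleast_1d(_laa_volume(self.spec, t)) * 1000.0
        return np.array([self._shape.lateral_area_mm2(self._shape.scale_for_volume(vi))
                         for vi in v])


def phantom_truth_at(spec: PhantomSpec, t):
    """(V_LV, V_LAA, A_LAA, Q_MV, Q_LAA) at time(s) t, all closed-form
    (area via exact 1-D quadrature of the smooth profile)."""
    shape = _LaaShape(spec.laa_r_ost, spec.laa_length, spec.laa_taper_fraction)
    v_laa = np.atleast_1d(_laa_volume(spec, t))
    a_laa = np.array([shape.lateral_area_mm2(shape.scale_for_volume(v * 1000.0))
                      for v in v_laa])
    return (_lv_volume(spec, t), _laa_volume(spec, t), a_laa,
            np.maximum(_lv_dvdt(spec, t), 0.0), -_laa_dvdt(spec, t))


def _make_truth(spec: PhantomSpec, shape: _LaaShape) -> PhantomTruth:
    T = spec.cycle_length
    frame_t = np.arange(spec.n_frames) / spec.n_frames * T
    v_laa_frames = _laa_volume(spec, frame_t)
    a_laa_frames = np.array([
        shape.lateral_area_mm2(shape.scale_for_volume(v * 1000.0))
        for v in v_laa_frames])

    # scalar truth metrics from the closed-form curves on a fine grid
    tg = np.linspace(0, T, 40001)
    q_mv = np.maximum(_lv_dvdt(spec, tg), 0.0)
    q_laa = -_laa_dvdt(spec, tg)
    a_range_vol = _laa_volume(spec, tg)
    a_range = np.array([spec.laa_vmax, a_range_vol.min()])
    k_ext = [shape.scale_for_volume(v * 1000.0) for v in a_range]
    areas_ext = [shape.lateral_area_mm2(k) for k in k_ext]

    e_peak = spec.stroke_volume * spec.e_fraction / (
        spec.pulse_width / 100.0 * T * _BUMP_AREA) * _BUMP_PEAK
    a_peak = spec.stroke_volume * spec.a_fraction / (
        spec.pulse_width / 100.0 * T * _BUMP_AREA) * _BUMP_PEAK
    k_laa = int(np.argmax(q_laa))
    return PhantomTruth(
        spec=spec, frame_times=frame_t,
        v_lv=_lv_volume(spec, frame_t), v_laa=v_laa_frames, a_laa=a_laa_frames,
        e_peak=e_peak, a_peak=a_peak,
        e_time=spec.e_time / 100.0 * T, a_time=spec.a_time / 100.0 * T,
        stroke_volume=spec.stroke_volume, ef_af_ratio=e_peak / a_peak,
        laa_peak_outflow=float(q_laa[k_laa]), laa_peak_outflow_time=float(tg[k_laa]),
        laa_area_factor=float(max(areas_ext) / min(areas_ext)),
        _shape=shape,
    )


# ---------------------------------------------------------------------------
# mesh generation


class _PhantomGeometry:
    """Parametric generator for the phantom surface at any cycle time."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.shape = _LaaShape(spec.laa_r_ost, spec.laa_length,
                               spec.laa_taper_fraction)
        s = spec
        # ostium frame on the (static) upper LA wall
        el = np.deg2rad(s.laa_elevation_deg)
        az = np.deg2rad(s.laa_azimuth_deg)
        p = np.array([s.r0 * np.cos(el) * np.cos(az),
                      s.r0 * np.cos(el) * np.sin(az),
                      s.c_la * np.sin(el)])
        normal = np.array([p[0] / s.r0 ** 2, p[1] / s.r0 ** 2, p[2] / s.c_la ** 2])
        self.ost_normal = normal / np.linalg.norm(normal)
        self.ost_center = p
        ref = np.array([0.0, 0.0, 1.0])
        u = np.cross(ref, self.ost_normal)
        u /= np.linalg.norm(u)
        self.ost_u = u
        self.ost_v = np.cross(self.ost_normal, u)

    # time-dependent scale factors -----------------------------------------
    def lv_scale(self, t: float) -> float:
        return float(_lv_volume(self.spec, t) / self.spec.lv_edv) ** (1.0 / 3.0)

    def laa_scale(self, t: float) -> float:
        return self.shape.scale_for_volume(float(_laa_volume(self.spec, t)) * 1000.0)

    def la_radial_factor(self, z: np.ndarray, t: float) -> np.ndarray:
        """Blend from the LV's radial scale at the equator to 1 (static)
        above the blend zone."""
        sr = self.lv_scale(t)
        zeta = np.clip(np.asarray(z) / (self.spec.la_blend_top * self.spec.c_la),
                       0.0, 1.0)
        return 1.0 + (sr - 1.0) * (1.0 - _smootherstep(zeta))

    # parametric surfaces ---------------------------------------------------
    def lv_point(self, elev: np.ndarray, az: np.ndarray, t: float) -> np.ndarray:
        """Lower half-ellipsoid; elev in [0, pi/2] measured downward."""
        s, sp = self.lv_scale(t), self.spec
        x = sp.r0 * np.cos(elev) * np.cos(az)
        y = sp.r0 * np.cos(elev) * np.sin(az)
        z = -sp.c_lv * np.sin(elev)
        return np.stack([s * x, s * y, s * z], axis=-1)

    def la_point(self, elev: np.ndarray, az: np.ndarray, t: float) -> np.ndarray:
        sp = self.spec
        x = sp.r0 * np.cos(elev) * np.cos(az)
        y = sp.r0 * np.cos(elev) * np.sin(az)
        z = sp.c_la * np.sin(elev)
        f = self.la_radial_factor(z, t)
        return np.stack([f * x, f * y, z], axis=-1)

    def laa_point(self, u: np.ndarray, angle: np.ndarray, t: float) -> np.ndarray:
        """Deformed cone; u in [0, 1) axial fraction, angle around the
        ostium axis."""
        sp = self.spec
        k = self.laa_scale(t)
        f = self.shape.scale(u, k)
        xi = sp.laa_length * np.asarray(u) * f
        r = sp.laa_r_ost * self.shape.profile(u) * f
        d = (np.cos(angle)[..., None] * self.ost_u
             + np.sin(angle)[..., None] * self.ost_v)
        return (self.ost_center + xi[..., None] * self.ost_normal
                + r[..., None] * d)


def _build_phantom_mesh(geom: _PhantomGeometry, t: float, resolution: float,
                        az_offset: float = 0.0, part: str = "full"):
    """Assemble the phantom surface at time ``t``.

    ``part`` selects "full" (LV + LA + LAA), "chambers" (no LAA) or "laa"
    (cone only, open at the ostium).  Returns ``(SurfaceMesh, labels_array)``
    with per-vertex :class:`Region` codes.
    """
    sp = geom.spec
    n_az = max(16, int(round(2 * np.pi * sp.r0 / resolution)))
    az = np.linspace(0, 2 * np.pi, n_az, endpoint=False) + az_offset
    pv_hole = np.deg2rad(90.0 - sp.pv_hole_deg)

    verts: list[np.ndarray] = []
    labels: list[int] = []
    faces: list[list[int]] = []
    # per-vertex surface parameters, so source vertices can be re-evaluated
    # analytically at any cycle time (kind: 0 = LV, 1 = LA, 2 = LAA)
    par_kind: list[int] = []
    par_a: list[float] = []
    par_b: list[float] = []

    def add_ring(points: np.ndarray, label: Region, kind: int,
                 pa, pb) -> list[int]:
        idx = list(range(len(verts), len(verts) + len(points)))
        verts.extend(points)
        labels.extend([int(label)] * len(points))
        par_kind.extend([kind] * len(points))
        par_a.extend(np.broadcast_to(pa, (len(points),)).tolist())
        par_b.extend(np.broadcast_to(pb, (len(points),)).tolist())
        return idx

    def stitch(lower: list[int], upper: list[int]) -> None:
        from .primitives import _stitch_rows
        faces.extend(_stitch_rows(lower, upper))

    ring_cache: dict[str, list[int]] = {}

    if part in ("full", "chambers"):
        # LV: apex (elev pi/2, downward) up to the equator
        n_lv = max(4, int(round((np.pi / 2) * sp.c_lv / resolution)))
        lv_elev = np.linspace(np.pi / 2, 0.0, n_lv + 1)
        prev = add_ring(geom.lv_point(np.pi / 2, 0.0, t)[None, :], Region.LV,
                        0, np.pi / 2, 0.0)
        for e in lv_elev[1:-1]:
            ring = add_ring(geom.lv_point(np.full(n_az, e), az, t), Region.LV,
                            0, e, az)
            stitch(prev, ring)
            prev = ring
        equator = add_ring(geom.lv_point(np.zeros(n_az), az, t), Region.LV,
                           0, 0.0, az)
        stitch(prev, equator)
        ring_cache["equator"] = equator

        # LA: equator up to the pulmonary-vein hole rim
        n_la = max(4, int(round((pv_hole) * sp.c_la / resolution)))
        la_elev = np.linspace(0.0, pv_hole, n_la + 1)
        prev = equator
        for j, e in enumerate(la_elev[1:]):
            is_rim = j == n_la - 1
            label = Region.BOUNDARY_RING if is_rim else Region.LA
            ring = add_ring(geom.la_point(np.full(n_az, e), az, t), label,
                            1, e, az)
            stitch(prev, ring)
            prev = ring

    # the LAA is meshed finer than the chambers; scale its resolution by
    # the same factor as the chamber resolution (targets vs source)
    laa_res = sp.laa_resolution * (resolution / sp.mesh_resolution)
    n_ost = max(16, int(round(2 * np.pi * sp.laa_r_ost / laa_res)))
    ost_angle = np.linspace(0, 2 * np.pi, n_ost, endpoint=False)

    if part == "chambers":
        # the ostium ring without the cone: the chamber target mirrors the
        # manual cut of the LAA at its ostium, leaving the ring open
        ring_cache["ostium"] = add_ring(
            geom.laa_point(np.zeros(n_ost), ost_angle, t), Region.LAA_OSTIUM,
            2, 0.0, ost_angle)

    if part in ("full", "laa"):
        n_ax = max(6, int(round(sp.laa_length / laa_res)))
        u_rows = np.linspace(0.0, 1.0, n_ax + 1)
        prev = add_ring(geom.laa_point(np.zeros(n_ost), ost_angle, t),
                        Region.LAA_OSTIUM, 2, 0.0, ost_angle)
        ring_cache["ostium"] = prev
        for u in u_rows[1:-1]:
            ring = add_ring(geom.laa_point(np.full(n_ost, u), ost_angle, t),
                            Region.LAA, 2, u, ost_angle)
            stitch(prev, ring)
            prev = ring
        tip = add_ring(geom.laa_point(np.array([1.0]),
                                      np.array([0.0]), t)[:1], Region.LAA,
                       2, 1.0, 0.0)
        stitch(prev, tip)

    if part in ("full", "chambers"):
        # carve the ostium disk out of the LA wall: remove LA faces whose
        # projected footprint falls inside the ostium circle, then bridge
        # the resulting hole rim to the ostium ring (which stays open for
        # the chambers part, where the LAA cone is absent).
        _carve_and_bridge(geom, t, verts, labels, faces, ring_cache["ostium"])

    mesh = SurfaceMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))
    params = (np.asarray(par_kind, dtype=np.int64), np.asarray(par_a),
              np.asarray(par_b))
    return mesh, np.asarray(labels, dtype=np.int64), params


def _carve_and_bridge(geom: _PhantomGeometry, t: float, verts, labels, faces,
                      ostium_ring: list[int] | None) -> None:
    """Open a hole in the LA wall under the LAA and stitch it to the ostium
    ring, keeping the surface closed (except PV hole) and oriented.  With
    ``ostium_ring=None`` the hole is carved but left open."""
    V = np.asarray(verts)
    c, n = geom.ost_center, geom.ost_normal
    r_ost = geom.spec.laa_r_ost
    la_like = np.isin(np.asarray(labels), [int(Region.LA)])
    # vertices whose projection along the ostium axis is inside the circle
    rel = V - c
    ax = rel @ n
    radial = np.linalg.norm(rel - np.outer(ax, n), axis=1)
    # the hole is carved strictly larger than the ostium circle so the rim is
    # radially outside it: the bridge collar then never folds over itself
    inside = la_like & (radial < 1.15 * r_ost) & (np.abs(ax) < 2.0 * r_ost)
    if not inside.any():
        raise ValueError(
            "phantom infeasible: mesh too coarse to carve the LAA ostium "
            "(no LA vertex under the ostium disk); lower mesh_resolution")
    inside_idx = set(np.flatnonzero(inside).tolist())

    kept_faces = []
    hole_edges = []
    for f in faces:
        if any(v in inside_idx for v in f):
            for kk in range(3):
                a, b = f[kk], f[(kk + 1) % 3]
                if a not in inside_idx and b not in inside_idx:
                    hole_edges.append((a, b))
            continue
        kept_faces.append(f)

    # rim = directed edges of removed faces whose endpoints both survive and
    # whose reverse bounds no removed face (i.e. the kept/removed interface)
    edge_set = set(hole_edges)
    rim_edges = [(a, b) for a, b in edge_set if (b, a) not in edge_set]
    if len(rim_edges) < 3:
        raise ValueError("phantom infeasible: ostium hole rim degenerate; "
                         "adjust mesh_resolution")
    rim = sorted({v for e in rim_edges for v in e})

    faces[:] = kept_faces
    if ostium_ring is not None:
        _bridge_rings(np.asarray(verts), faces, rim, ostium_ring, c, n,
                      geom.ost_u, geom.ost_v)


def _bridge_rings(V: np.ndarray, faces: list, rim: list[int],
                  ostium: list[int], center: np.ndarray, outward: np.ndarray,
                  u: np.ndarray, v: np.ndarray) -> None:
    """Triangulate the annulus between the (outer) hole rim and the (inner)
    ostium ring by zipping both rings in angular order about the ostium
    axis.  With both rings counter-clockwise about the outward axis and the
    rim strictly outside the ring, the zipper winding is consistently
    outward by construction."""

    def ang(i: int) -> float:
        rel = V[i] - center
        return float(np.arctan2(rel @ v, rel @ u))

    rim_s = sorted(rim, key=ang)
    ost_s = sorted(ostium, key=ang)
    rim_a = [ang(i) for i in rim_s]
    ost_a = [ang(i) for i in ost_s]
    nr, no = len(rim_s), len(ost_s)

    i = j = 0
    for _ in range(nr + no):
        r_cur, o_cur = rim_s[i % nr], ost_s[j % no]
        ai_next = rim_a[(i + 1) % nr] + 2 * np.pi * ((i + 1) // nr)
        aj_next = ost_a[(j + 1) % no] + 2 * np.pi * ((j + 1) // no)
        if j >= no or (i < nr and ai_next <= aj_next):
            tri = [r_cur, rim_s[(i + 1) % nr], o_cur]
            i += 1
        else:
            tri = [r_cur, ost_s[(j + 1) % no], o_cur]
            j += 1
        if len(set(tri)) == 3:
            faces.append(tri)


# ---------------------------------------------------------------------------
# public generator


@dataclass
class PhantomData:
    source: SurfaceMesh
    labels: RegionLabels
    targets_full: list[SurfaceMesh]
    targets_laa: list[SurfaceMesh]
    targets_chambers: list[SurfaceMesh]
    truth: PhantomTruth
    spec: PhantomSpec
    _geom: "_PhantomGeometry" = field(default=None, repr=False)
    _source_params: tuple = field(default=None, repr=False)

    def source_positions_at(self, t: float) -> np.ndarray:
        """Analytic positions of every source vertex at cycle time ``t`` —
        the exact trajectory the tracking pipeline tries to recover."""
        kind, pa, pb = self._source_params
        out = np.empty((len(kind), 3))
        for k, fn in ((0, self._geom.lv_point), (1, self._geom.la_point),
                      (2, self._geom.laa_point)):
            m = kind == k
            if m.any():
                out[m] = fn(pa[m], pb[m], float(t))
        return out


def generate_phantom_cycle(spec: PhantomSpec | None = None) -> PhantomData:
    """Source mesh + labels, per-frame targets, and analytic truth."""
    if spec is None:
        spec = PhantomSpec()
    geom = _PhantomGeometry(spec)
    src_mesh, src_labels, src_params = _build_phantom_mesh(
        geom, 0.0, spec.mesh_resolution)

    rng = np.random.default_rng(spec.seed)
    res_t = spec.mesh_resolution * spec.target_resolution_factor
    frame_t = np.arange(spec.n_frames) / spec.n_frames * spec.cycle_length
    n_az = max(16, int(round(2 * np.pi * spec.r0 / res_t)))
    az_off = 0.5 * (2 * np.pi / n_az)

    targets_full, targets_laa, targets_chambers = [], [], []
    for t in frame_t:
        full, _, _ = _build_phantom_mesh(geom, float(t), res_t,
                                         az_offset=az_off, part="full")
        laa, _, _ = _build_phantom_mesh(geom, float(t), res_t,
                                        az_offset=az_off, part="laa")
        cham, _, _ = _build_phantom_mesh(geom, float(t), res_t,
                                         az_offset=az_off, part="chambers")
        if spec.target_jitter_sd > 0:
            for m in (full, laa, cham):
                m.vertices += rng.normal(0.0, spec.target_jitter_sd,
                                         m.vertices.shape)
        targets_full.append(full)
        targets_laa.append(laa)
        targets_chambers.append(cham)

    truth = _make_truth(spec, geom.shape)
    return PhantomData(
        source=src_mesh, labels=RegionLabels(src_labels),
        targets_full=targets_full, targets_laa=targets_laa,
        targets_chambers=targets_chambers, truth=truth, spec=spec,
        _geom=geom, _source_params=src_params,
    )
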