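"""Cycle-wise tracking: normalization, chamber + LAA passes, chained frames.

Each frame is tracked in two passes.  Pass 1 registers the chamber surface
(LA + LV, including the ostium ring) with the open boundary rings frozen at
their frame-0 positions.  Pass 2 registers the LAA with the ostium motion
prescribed from pass 1 and the bi-directional term enabled.  Frames are
chained forward (0 -> 5 -> ... -> 50 %RR) and backward (0 -> 95 -> ... ->
50 %RR); the mid-cycle frame is the mean of both chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import Region, RegionLabels, SurfaceMesh, extract_by_labels
from .nicp import RegistrationConfig, make_stiffness_schedule, register_surfaces

__all__ = [
    "NormalizationTransform",
    "TrackedSequence",
    "TrackingConfigs",
    "normalize_to_unit_cube",
    "track_frame",
    "track_cycle",
]


@dataclass
class NormalizationTransform:
    """Isotropic scale + translation mapping world mm into the unit cube."""

    scale: float
    offset: np.ndarray  # world-space minimum corner

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.offset) * self.scale

    def invert(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) / self.scale + self.offset


def normalize_to_unit_cube(meshes) -> tuple[list[SurfaceMesh], NormalizationTransform]:
    """Scale one or more meshes jointly into [0, 1]^3 (longest axis spans
    [0, 1]); the shared transform is returned and exactly invertible."""
    if isinstance(meshes, SurfaceMesh):
        meshes = [meshes]
    meshes = list(meshes)
    if not meshes:
        raise ValueError("no meshes to normalize")
    lo = np.min([m.vertices.min(axis=0) for m in meshes], axis=0)
    hi = np.max([m.vertices.max(axis=0) for m in meshes], axis=0)
    extent = float(np.max(hi - lo))
    if extent <= 0:
        raise ValueError("degenerate geometry: zero extent")
    t = NormalizationTransform(scale=1.0 / extent, offset=lo)
    return [m.with_vertices(t.apply(m.vertices)) for m in meshes], t


@dataclass
class TrackedSequence:
    """Fixed-topology vertex trajectories over the cardiac cycle."""

    mesh: SurfaceMesh                  # topology + frame-0 vertices
    labels: RegionLabels
    positions: np.ndarray              # (n_frames, n, 3) mm
    frame_times_pct: np.ndarray        # %RR
    cycle_length: float                # seconds

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def frame_times_s(self) -> np.ndarray:
        return self.frame_times_pct / 100.0 * self.cycle_length

    def frame_mesh(self, i: int) -> SurfaceMesh:
        return self.mesh.with_vertices(self.positions[i])


@dataclass
class TrackingConfigs:
    """Registration configs for the two passes."""

    chambers: RegistrationConfig = field(default_factory=lambda: RegistrationConfig(
        alpha_schedule=make_stiffness_schedule("chambers"),
        prune_border_targets=True))
    laa: RegistrationConfig = field(default_factory=lambda: RegistrationConfig(
        alpha_schedule=make_stiffness_schedule("laa"), lambda_bidir=0.5))

    @classmethod
    def fast(cls) -> "TrackingConfigs":
        """Reduced schedules (25 chamber / 10 LAA steps) for CI-scale runs."""
        return cls(
            chambers=RegistrationConfig(
                alpha_schedule=make_stiffness_schedule("chambers", n_steps=25),
                prune_border_targets=True),
            laa=RegistrationConfig(
                alpha_schedule=make_stiffness_schedule("laa", n_steps=10),
                lambda_bidir=0.5),
        )


_CHAMBER_LABELS = {Region.LV, Region.LA, Region.BOUNDARY_RING, Region.LAA_OSTIUM}
_LAA_LABELS = {Region.LAA, Region.LAA_OSTIUM}


def _submesh_landmark_indices(parent_indices: np.ndarray,
                              labels: RegionLabels, region: Region) -> np.ndarray:
    mask = labels.vertex_region[parent_indices] == int(region)
    return np.flatnonzero(mask)


def track_frame(mesh: SurfaceMesh, current_positions: np.ndarray,
                frame0_positions: np.ndarray, labels: RegionLabels,
                target_full: SurfaceMesh, target_laa: SurfaceMesh,
                configs: TrackingConfigs) -> np.ndarray:
    """Track one frame transition; all coordinates in normalized space.

    Returns the merged (n, 3) next-frame positions.
    """
    if target_laa is None:
        raise ValueError("missing LAA target surface for this frame")

    # pass 1: chambers, boundary rings frozen at frame-0 positions
    chamber_sub, chamber_idx = extract_by_labels(mesh, labels, _CHAMBER_LABELS)
    chamber_src = chamber_sub.with_vertices(current_positions[chamber_idx])
    ring_local = _submesh_landmark_indices(chamber_idx, labels, Region.BOUNDARY_RING)
    landmarks1 = (ring_local, frame0_positions[chamber_idx][ring_local])
    res1 = register_surfaces(chamber_src, target_full, landmarks1, configs.chambers)

    merged = current_positions.copy()
    merged[chamber_idx] = res1.positions

    # pass 2: LAA, ostium prescribed from pass 1, bi-directional term on
    laa_sub, laa_idx = extract_by_labels(mesh, labels, _LAA_LABELS)
    laa_src = laa_sub.with_vertices(merged[laa_idx])
    ostium_local = _submesh_landmark_indices(laa_idx, labels, Region.LAA_OSTIUM)
    landmarks2 = (ostium_local, merged[laa_idx][ostium_local])
    res2 = register_surfaces(laa_src, target_laa, landmarks2, configs.laa)

    # ostium positions are prescribed, not re-solved: copy only LAA vertices
    laa_only = labels.vertex_region[laa_idx] == int(Region.LAA)
    merged[laa_idx[laa_only]] = res2.positions[laa_only]
    return merged


def track_cycle(source: SurfaceMesh, labels: RegionLabels,
                targets_full: list[SurfaceMesh], targets_laa: list[SurfaceMesh],
                configs: TrackingConfigs | None = None,
                targets_chambers: list[SurfaceMesh] | None = None,
                cycle_length: float = 1.0,
                n_frames: int = 20) -> TrackedSequence:
    """Track the full cycle with forward and backward chains.

    ``targets_full[i]`` / ``targets_laa[i]`` are the surfaces at frame i
    (i * 100 / n_frames %RR); frame 0 corresponds to the source.  When
    ``targets_chambers`` is given, pass 1 registers against those (LAA
    already removed from the target) instead of the full surfaces.
    """
    if configs is None:
        configs = TrackingConfigs()
    if len(targets_full) != n_frames or len(targets_laa) != n_frames:
        raise ValueError(
            f"expected {n_frames} target frames, got {len(targets_full)} full "
            f"and {len(targets_laa)} LAA")
    missing = [i for i, t in enumerate(targets_laa) if t is None]
    if missing:
        raise ValueError(f"missing LAA target for frame(s) {missing}")
    if targets_chambers is not None and len(targets_chambers) != n_frames:
        raise ValueError("targets_chambers frame count mismatch")

    pass1_targets = targets_chambers if targets_chambers is not None else targets_full

    all_meshes = [source] + list(pass1_targets) + list(targets_laa)
    normed, tf = normalize_to_unit_cube(all_meshes)
    src_n = normed[0]
    tgt1_n = normed[1:1 + n_frames]
    tgt_laa_n = normed[1 + n_frames:]

    frame0 = src_n.vertices.copy()
    positions = np.zeros((n_frames, source.n_vertices, 3))
    positions[0] = frame0
    half = n_frames // 2

    # forward chain: 0 -> 1 -> ... -> half
    cur = frame0.copy()
    for i in range(1, half + 1):
        cur = track_frame(src_n, cur, frame0, labels, tgt1_n[i], tgt_laa_n[i],
                          configs)
        positions[i] = cur
    forward_mid = positions[half].copy()

    # backward chain: 0 -> n-1 -> ... -> half
    cur = frame0.copy()
    for i in range(n_frames - 1, half - 1, -1):
        cur = track_frame(src_n, cur, frame0, labels, tgt1_n[i], tgt_laa_n[i],
                          configs)
        if i != half:
            positions[i] = cur
    backward_mid = cur

    positions[half] = 0.5 * (forward_mid + backward_mid)

    # back to world mm; frame 0 is the source bit-exactly
    world = np.array([tf.invert(p) for p in positions])
    world[0] = source.vertices
    return TrackedSequence(
        mesh=source,
        labels=labels,
        positions=world,
        frame_times_pct=np.arange(n_frames) * (100.0 / n_frames),
        cycle_length=cycle_length,
    )
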