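"""Deterministic tensor-deflection (TEND) streamline tractography.

Tracking is seeded at every voxel whose FA strictly exceeds the seed
threshold (default 0.3) and launched bidirectionally along ±e1 of the
seed voxel.  At each step the incoming unit direction v_in is deflected
by the full local tensor,

    v_out ∝ D · v_in        (sign chosen so v_out·v_in ≥ 0),

which bends trajectories smoothly toward the local fibre axis instead of
snapping to e1.  A half-track stops when the local FA drops below the
stop threshold (default 0.2), when the turn between successive step
directions exceeds the curvature limit (default 60°), when the position
leaves the grid, or after ``max_steps`` steps.  Everything is
deterministic: no random number is drawn anywhere.

The generalised TEND update

    v_out ∝ f·e1 + (1−f)·((1−g)·v_in + g·normalize(D·v_in))

is exposed through the config weights ``f`` and ``g``; the defaults
f = 0, g = 1 give the pure deflection rule.

Tensor lookup is nearest-voxel: world coordinates map through the inverse
affine and round to the nearest integer index (half-open cells
[i−0.5, i+0.5) around integer voxel centres), matching the per-voxel
phrasing of the FA stop rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor import TensorField

__all__ = [
    "TrackingConfig",
    "Streamline",
    "Tractogram",
    "select_seeds",
    "propagate",
    "track_whole_volume",
]

TERMINATION_REASONS = ("low_fa", "curvature", "out_of_bounds", "max_steps")


@dataclass(frozen=True)
class TrackingConfig:
    seed_fa_threshold: float = 0.3
    stop_fa_threshold: float = 0.2
    max_angle_deg: float = 60.0
    step_size_mm: float | None = None  # None -> half the smallest voxel dim
    max_steps: int = 2000
    seeds_per_voxel: int = 1
    tend_f: float = 0.0
    tend_g: float = 1.0

    def __post_init__(self):
        if not self.stop_fa_threshold < self.seed_fa_threshold:
            raise ValueError("stop_fa_threshold must be < seed_fa_threshold")
        if not 0 < self.max_angle_deg < 180:
            raise ValueError("max_angle_deg must lie in (0, 180)")
        if self.step_size_mm is not None and self.step_size_mm <= 0:
            raise ValueError("step_size_mm must be positive")
        if self.max_steps < 1 or self.seeds_per_voxel < 1:
            raise ValueError("max_steps and seeds_per_voxel must be >= 1")

    def resolve_step_size(self, field: TensorField) -> float:
        if self.step_size_mm is not None:
            return float(self.step_size_mm)
        voxdims = np.linalg.norm(field.affine[:3, :3], axis=0)
        return float(voxdims.min() / 2.0)


@dataclass
class Streamline:
    """Ordered polyline in world mm with per-direction termination reasons.

    ``termination_reasons`` is (reason at the first point, reason at the
    last point): the polyline starts at the end reached by the −e1
    half-track and finishes at the end reached by the +e1 half-track.
    """

    points: np.ndarray
    seed_voxel: tuple[int, int, int]
    termination_reasons: tuple[str, str]

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self):
        return self.points.shape[0]


@dataclass
class Tractogram:
    streamlines: list[Streamline]
    affine: np.ndarray
    grid_shape: tuple[int, int, int]
    n_seeds: int = 0

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)

    def __len__(self):
        return len(self.streamlines)

    def termination_histogram(self) -> dict[str, int]:
        hist = {r: 0 for r in TERMINATION_REASONS}
        for s in self.streamlines:
            for r in s.termination_reasons:
                hist[r] += 1
        return hist


def select_seeds(field: TensorField, config: TrackingConfig) -> np.ndarray:
    """Voxel indices with FA strictly above the seed threshold.

    Returns an (N·seeds_per_voxel, 3) integer array; each qualifying
    voxel contributes ``seeds_per_voxel`` seeds at its centre.
    """
    mask = (field.fa_map > config.seed_fa_threshold) & field.valid
    vox = np.argwhere(mask)
    if config.seeds_per_voxel > 1:
        vox = np.repeat(vox, config.seeds_per_voxel, axis=0)
    return vox


def _world_to_voxel_idx(inv_affine: np.ndarray, point: np.ndarray) -> np.ndarray:
    v = inv_affine[:3, :3] @ point + inv_affine[:3, 3]
    return np.round(v).astype(int)


def _in_grid(idx: np.ndarray, shape) -> bool:
    return bool(np.all(idx >= 0) and np.all(idx < np.asarray(shape)))


def _deflect(D: np.ndarray, e1: np.ndarray, v_in: np.ndarray,
             f: float, g: float) -> np.ndarray | None:
    dv = D @ v_in
    n = np.linalg.norm(dv)
    if n < 1e-30:
        return None
    dv = dv / n
    if dv @ v_in < 0:
        dv = -dv
    e1s = e1 if e1 @ v_in >= 0 else -e1
    v = f * e1s + (1.0 - f) * ((1.0 - g) * v_in + g * dv)
    n = np.linalg.norm(v)
    if n < 1e-30:
        return None
    return v / n


def _half_track(field: TensorField, start: np.ndarray, v0: np.ndarray,
                config: TrackingConfig, step: float, cos_max: float):
    """Propagate one direction; returns (points after start, reason)."""
    inv = field.inverse_affine
    shape = field.grid_shape
    pts = []
    current = start
    v_in = v0
    for _ in range(config.max_steps):
        idx = _world_to_voxel_idx(inv, current)
        D = field.D[tuple(idx)]
        e1 = field.e1[tuple(idx)]
        v_out = _deflect(D, e1, v_in, config.tend_f, config.tend_g)
        if v_out is None:
            return pts, "low_fa"  # zero tensor treated as low FA
        if v_out @ v_in < cos_max:
            return pts, "curvature"
        nxt = current + step * v_out
        nidx = _world_to_voxel_idx(inv, nxt)
        if not _in_grid(nidx, shape):
            return pts, "out_of_bounds"
        if not field.valid[tuple(nidx)] or field.fa_map[tuple(nidx)] < config.stop_fa_threshold:
            return pts, "low_fa"
        pts.append(nxt)
        current = nxt
        v_in = v_out
    return pts, "max_steps"


def propagate(field: TensorField, seed_voxel, config: TrackingConfig) -> Streamline | None:
    """Bidirectional streamline from one seed voxel centre.

    Launches along +e1 and −e1 of the seed voxel and concatenates the
    reversed −e1 half with the +e1 half.  The curvature rule applies
    within each half only: the two halves depart at 180° by design, so
    the junction is exempt.  Returns None if neither half can take a
    single step (degenerate boundary seed).
    """
    seed_voxel = tuple(int(i) for i in seed_voxel)
    if not _in_grid(np.asarray(seed_voxel), field.grid_shape):
        raise ValueError(f"seed voxel {seed_voxel} outside grid")
    step = config.resolve_step_size(field)
    cos_max = float(np.cos(np.deg2rad(config.max_angle_deg)))
    start = field.affine[:3, :3] @ np.asarray(seed_voxel, float) + field.affine[:3, 3]
    e1 = field.e1[seed_voxel]
    if np.linalg.norm(e1) < 1e-30:
        return None
    fwd_pts, fwd_reason = _half_track(field, start, e1, config, step, cos_max)
    bwd_pts, bwd_reason = _half_track(field, start, -e1, config, step, cos_max)
    pts = bwd_pts[::-1] + [start] + fwd_pts
    if len(pts) < 2:
        return None
    return Streamline(
        points=np.asarray(pts),
        seed_voxel=seed_voxel,
        termination_reasons=(bwd_reason, fwd_reason),
    )


def track_whole_volume(field: TensorField, config: TrackingConfig | None = None) -> Tractogram:
    """Track from every suprathreshold seed; deterministic.

    One streamline per seed; seeds whose streamline degenerates to a
    single point are counted in ``n_seeds`` but contribute no streamline.
    """
    if config is None:
        config = TrackingConfig()
    seeds = select_seeds(field, config)
    streamlines = []
    for seed in seeds:
        s = propagate(field, seed, config)
        if s is not None:
            streamlines.append(s)
    return Tractogram(
        streamlines=streamlines,
        affine=field.affine,
        grid_shape=tuple(field.grid_shape),
        n_seeds=len(seeds),
    )
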