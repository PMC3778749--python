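"""Synthetic test surfaces: DWI bundle phantoms and network cohorts.

Two kinds of synthetic data feed the pipeline end to end without any
download:

* **Bundle phantoms** — voxel grids containing a single fibre bundle
  (straight, arc, sharp bend, or two crossing bundles) with known
  per-voxel tensors.  The DWI signal follows the single-tensor forward
  model S_k = s0·exp(−b_k·g_kᵀ D g_k); optional Rician noise is applied
  as |S + ε_re + i·ε_im| with per-channel sd = s0/snr.  Label volumes
  mark the bundle end-caps as regions 1 and 2 (3 and 4 for the second
  bundle of a crossing), so tractography and network construction have a
  ground truth.

* **Network cohorts** — two groups of symmetric R×R connectivity
  matrices sharing one random edge skeleton, with a chosen number of
  edges carrying a planted standardized mean shift (Cohen's d) in
  group 2: fibre density and FA are lowered, MD raised, emulating the
  degenerative direction of white-matter pathology.  Fibre densities are
  normalised per subject so present-edge densities sum to 1 (they are
  fractions of a fibre total).

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .gradients import GradientTable
from .network import CohortDataset, ConnectivityNetwork
from .parcellation import LabelVolume
from .tensor import DWIVolume, TensorField, fa_of

__all__ = [
    "BundlePhantomSpec",
    "CohortSpec",
    "make_bundle_phantom",
    "make_cohort",
    "make_dwi_cohort",
    "straight_bundle_spec",
    "arc_bundle_spec",
    "sharp_bend_spec",
    "crossing_spec",
]

GEOMETRIES = ("straight", "arc", "sharp_bend", "crossing")

# generic white-matter-like bundle tensor (mm²/s): FA ≈ 0.80
INSIDE_EIGS = (1.7e-3, 0.3e-3, 0.3e-3)
# stick-like bundle used for the sharp bend: the pure deflection rule can
# turn at most 90° − 2·atan(sqrt(λ2/λ1)) in one step, so only a very
# anisotropic tensor lets a single step exceed the 60° curvature limit
STICK_EIGS = (1.7e-3, 0.05e-3, 0.05e-3)
# nearly isotropic background: FA ≈ 0.08
OUTSIDE_EIGS = (0.8e-3, 0.7e-3, 0.7e-3)


@dataclass(frozen=True)
class BundlePhantomSpec:
    grid_shape: tuple[int, int, int] = (40, 20, 20)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    geometry: str = "straight"
    bundle_radius_vox: float = 3.0
    inside_eigenvalues: tuple[float, float, float] = INSIDE_EIGS
    outside_eigenvalues: tuple[float, float, float] = OUTSIDE_EIGS
    arc_angle_deg: float = 90.0
    s0: float = 1000.0
    snr: float | None = None
    seed: int = 0
    cap_length_vox: float = 2.0
    margin_vox: float = 2.0

    def __post_init__(self):
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        ins = np.asarray(self.inside_eigenvalues, float)
        out = np.asarray(self.outside_eigenvalues, float)
        if np.any(ins <= 0) or np.any(out <= 0):
            raise ValueError("eigenvalues must be positive")
        if np.any(np.diff(ins) > 0):
            raise ValueError("inside eigenvalues must be descending")
        if fa_of(ins) <= 0.3:
            raise ValueError("inside eigenvalues must give FA > 0.3 (seedable)")
        if fa_of(np.sort(out)[::-1]) >= 0.2:
            raise ValueError("outside eigenvalues must give FA < 0.2")
        if not 0 < self.arc_angle_deg <= 180:
            raise ValueError("arc_angle_deg must lie in (0, 180]")
        if self.s0 <= 0 or self.bundle_radius_vox <= 0:
            raise ValueError("s0 and bundle_radius_vox must be positive")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive or None")


def straight_bundle_spec(**kw) -> BundlePhantomSpec:
    return BundlePhantomSpec(geometry="straight", **kw)


def arc_bundle_spec(arc_angle_deg: float = 90.0, **kw) -> BundlePhantomSpec:
    kw.setdefault("grid_shape", (40, 40, 20))
    return BundlePhantomSpec(geometry="arc", arc_angle_deg=arc_angle_deg, **kw)


def sharp_bend_spec(arc_angle_deg: float = 75.0, **kw) -> BundlePhantomSpec:
    """Bend of 75° at mid-bundle with a stick-like tensor: the one-step
    deflection turn at the bend is ≈69° > 60°, so tracking must stop."""
    kw.setdefault("inside_eigenvalues", STICK_EIGS)
    kw.setdefault("grid_shape", (40, 30, 20))
    return BundlePhantomSpec(geometry="sharp_bend", arc_angle_deg=arc_angle_deg, **kw)


def crossing_spec(**kw) -> BundlePhantomSpec:
    kw.setdefault("grid_shape", (30, 30, 20))
    return BundlePhantomSpec(geometry="crossing", **kw)


def _centerline(spec: BundlePhantomSpec, sample_step: float = 0.25):
    """Sampled centerline(s) in voxel coordinates.

    Returns a list of (points (N,3), tangents (N,3)) per bundle.
    """
    nx, ny, nz = spec.grid_shape
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    # the tube (centerline ± radius) must fit inside the grid
    m = max(spec.margin_vox, spec.bundle_radius_vox + 0.5)
    if spec.geometry == "straight":
        xs = np.arange(m, nx - 1 - m + 1e-9, sample_step)
        pts = np.column_stack([xs, np.full_like(xs, cy), np.full_like(xs, cz)])
        tan = np.tile([1.0, 0.0, 0.0], (len(xs), 1))
        return [(pts, tan)]
    if spec.geometry == "arc":
        # circular arc in the x-y plane, starting at (m, y0) heading +x
        theta = np.deg2rad(spec.arc_angle_deg)
        length = nx - 1 - 2 * m
        radius = length / theta
        y0 = m + spec.bundle_radius_vox
        s = np.arange(0, length + 1e-9, sample_step)
        a = s / radius
        pts = np.column_stack(
            [m + radius * np.sin(a), y0 + radius * (1 - np.cos(a)),
             np.full_like(s, cz)]
        )
        tan = np.column_stack([np.cos(a), np.sin(a), np.zeros_like(a)])
        return [(pts, tan)]
    if spec.geometry == "sharp_bend":
        theta = np.deg2rad(spec.arc_angle_deg)
        d2 = np.array([np.cos(theta), np.sin(theta), 0.0])
        mid = np.array([(nx - 1) / 2.0, m + spec.bundle_radius_vox, cz])
        len1 = mid[0] - m
        s1 = np.arange(-len1, 0, sample_step)
        seg1 = mid + np.outer(s1, [1.0, 0.0, 0.0])
        # second leg runs until it would leave the padded grid
        lim = min(
            (nx - 1 - m - mid[0]) / d2[0] if d2[0] > 1e-12 else np.inf,
            (ny - 1 - m - mid[1]) / d2[1] if d2[1] > 1e-12 else np.inf,
        )
        s2 = np.arange(0, lim + 1e-9, sample_step)
        seg2 = mid + np.outer(s2, d2)
        pts = np.vstack([seg1, seg2])
        tan = np.vstack(
            [np.tile([1.0, 0.0, 0.0], (len(seg1), 1)), np.tile(d2, (len(seg2), 1))]
        )
        return [(pts, tan)]
    # crossing: one bundle along x, one along y
    xs = np.arange(m, nx - 1 - m + 1e-9, sample_step)
    b1 = (
        np.column_stack([xs, np.full_like(xs, cy), np.full_like(xs, cz)]),
        np.tile([1.0, 0.0, 0.0], (len(xs), 1)),
    )
    cx = (nx - 1) / 2.0
    ys = np.arange(m, ny - 1 - m + 1e-9, sample_step)
    b2 = (
        np.column_stack([np.full_like(ys, cx), ys, np.full_like(ys, cz)]),
        np.tile([0.0, 1.0, 0.0], (len(ys), 1)),
    )
    return [b1, b2]


def _tensor_along(tangent: np.ndarray, eigenvalues) -> np.ndarray:
    """Axially symmetric tensor with principal axis along ``tangent``."""
    e1 = tangent / np.linalg.norm(tangent)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R = np.column_stack([e1, e2, e3])
    return R @ np.diag(eigenvalues) @ R.T


def make_bundle_phantom(
    spec: BundlePhantomSpec, gradients: GradientTable
) -> tuple[DWIVolume, TensorField, LabelVolume]:
    """Forward-simulate DWI of a fibre-bundle phantom.

    Returns the (optionally Rician-noised) DWI volume, the noiseless
    ground-truth tensor field, and the end-cap label volume.
    """
    if gradients.dwi_mask.sum() < 6:
        raise ValueError("need at least 6 diffusion-weighted directions")
    nx, ny, nz = spec.grid_shape
    bundles = _centerline(spec)
    for pts, _ in bundles:
        if pts.shape[0] < 2:
            raise ValueError("bundle geometry does not fit inside the grid")
        lo = pts.min(axis=0) - spec.bundle_radius_vox
        hi = pts.max(axis=0) + spec.bundle_radius_vox
        if np.any(lo < -0.5) or np.any(hi > np.asarray(spec.grid_shape) - 0.5):
            raise ValueError("bundle geometry does not fit inside the grid")

    grid = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3).astype(float)

    D = np.empty((nx * ny * nz, 3, 3), dtype=float)
    D[:] = np.diag(spec.outside_eigenvalues)
    labels = np.zeros(nx * ny * nz, dtype=np.int32)
    region_offset = 0
    for pts, tan in bundles:
        # nearest centerline sample per voxel (chunked to bound memory)
        d2 = np.empty((grid.shape[0],), dtype=float)
        nearest = np.empty((grid.shape[0],), dtype=int)
        chunk = 4096
        for a in range(0, grid.shape[0], chunk):
            diff = grid[a:a + chunk, None, :] - pts[None, :, :]
            dist2 = np.einsum("ijk,ijk->ij", diff, diff)
            nearest[a:a + chunk] = np.argmin(dist2, axis=1)
            d2[a:a + chunk] = dist2[np.arange(dist2.shape[0]), nearest[a:a + chunk]]
        inside = d2 <= spec.bundle_radius_vox**2
        for v in np.nonzero(inside)[0]:
            D[v] = _tensor_along(tan[nearest[v]], spec.inside_eigenvalues)
        # arclength position of the nearest sample -> end caps
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(seglen)])
        s = arclen[nearest]
        cap1 = inside & (s <= spec.cap_length_vox)
        cap2 = inside & (s >= arclen[-1] - spec.cap_length_vox)
        labels[cap1] = region_offset + 1
        labels[cap2] = region_offset + 2
        region_offset += 2

    D = D.reshape(nx, ny, nz, 3, 3)
    labels = labels.reshape(nx, ny, nz)
    affine = np.diag(list(spec.voxel_size_mm) + [1.0])

    b = gradients.bvals
    g = gradients.bvecs
    # S_k = s0 * exp(-b_k g_k^T D g_k), exact for every voxel
    exponent = np.einsum("ki,xyzij,kj->xyzk", g, D, g) * b[None, None, None, :]
    signal = spec.s0 * np.exp(-exponent)
    if spec.snr is not None:
        rng = np.random.default_rng(spec.seed)
        sd = spec.s0 / spec.snr
        re = signal + rng.normal(0.0, sd, signal.shape)
        im = rng.normal(0.0, sd, signal.shape)
        signal = np.sqrt(re**2 + im**2)

    dwi = DWIVolume(signal, affine)
    truth = TensorField(D=D, affine=affine)
    label_vol = LabelVolume(labels, affine)
    return dwi, truth, label_vol


# ---------------------------------------------------------------------------
# cohort-level generator


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort of synthetic connectivity matrices.

    ``effect_size_d`` is the standardized mean shift (Cohen's d) planted
    on ``affected_edges`` randomly chosen present edges in group 2:
    density and FA drop by d·sd, MD rises by d·sd, then FA is clipped to
    [0, 1], MD to ≥ 0 and densities renormalised to sum to 1 per subject.
    """

    n_regions: int = 16
    n_per_group: tuple[int, int] = (20, 20)
    baseline_edge_probability: float = 0.9
    attribute_means: dict = field(
        default_factory=lambda: {"cd": 1.0, "fa": 0.45, "md": 0.8e-3}
    )
    attribute_sds: dict = field(
        default_factory=lambda: {"cd": 0.2, "fa": 0.05, "md": 0.08e-3}
    )
    # spread of the cohort-shared per-edge baseline profile around
    # attribute_means: real connectomes have strongly heterogeneous edge
    # strengths, and similarity-based classification relies on it
    edge_heterogeneity_sds: dict = field(
        default_factory=lambda: {"cd": 0.5, "fa": 0.08, "md": 0.15e-3}
    )
    affected_edges: int = 10
    effect_size_d: float = 2.0
    affected_attributes: tuple[str, ...] = ("cd", "fa", "md")
    seed: int = 0
    group_labels: tuple = (0, 1)

    def __post_init__(self):
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not 0 < self.baseline_edge_probability <= 1:
            raise ValueError("baseline_edge_probability must be in (0, 1]")
        if min(self.n_per_group) < 1:
            raise ValueError("each group needs at least one subject")
        if self.affected_edges < 0:
            raise ValueError("affected_edges must be non-negative")
        for attr in self.affected_attributes:
            if attr not in ("cd", "fa", "md"):
                raise ValueError(f"unknown attribute {attr!r}")
        for k in ("cd", "fa", "md"):
            if self.attribute_means[k] <= 0 or self.attribute_sds[k] <= 0:
                raise ValueError("attribute means and sds must be positive")


def make_cohort(spec: CohortSpec) -> CohortDataset:
    """Draw a cohort; deterministic given ``spec.seed``.

    All subjects share one edge skeleton so the feature layout is
    comparable across subjects; exactly ``spec.affected_edges`` of the
    present upper-triangle edges carry the planted group-2 shift, and
    their identities are returned on the dataset for recovery testing.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.n_regions
    iu = np.triu_indices(R, k=1)
    n_pairs = len(iu[0])
    present = rng.random(n_pairs) < spec.baseline_edge_probability
    if present.sum() == 0:  # guarantee a non-empty skeleton
        present[rng.integers(n_pairs)] = True
    present_idx = np.nonzero(present)[0]
    if spec.affected_edges > len(present_idx):
        raise ValueError(
            f"affected_edges={spec.affected_edges} exceeds the "
            f"{len(present_idx)} present edges"
        )
    planted = rng.choice(present_idx, size=spec.affected_edges, replace=False)
    planted = np.sort(planted)
    planted_mask = np.zeros(n_pairs, dtype=bool)
    planted_mask[planted] = True

    # degeneration-like signs: density and FA fall, MD rises
    shift_sign = {"cd": -1.0, "fa": -1.0, "md": +1.0}

    # cohort-shared per-edge baseline profile (heterogeneous edge strengths)
    baseline = {}
    for attr in ("cd", "fa", "md"):
        b = rng.normal(
            spec.attribute_means[attr], spec.edge_heterogeneity_sds[attr], n_pairs
        )
        baseline[attr] = np.clip(b, 0.1 * spec.attribute_means[attr], None)

    networks, labels = [], []
    for gi, (glabel, n_sub) in enumerate(zip(spec.group_labels, spec.n_per_group)):
        for _ in range(n_sub):
            vals = {}
            for attr in ("cd", "fa", "md"):
                mu = baseline[attr].copy()
                sd = spec.attribute_sds[attr]
                if gi == 1 and attr in spec.affected_attributes:
                    mu = mu + planted_mask * shift_sign[attr] * spec.effect_size_d * sd
                x = rng.normal(mu, sd)
                x[~present] = 0.0
                vals[attr] = x
            vals["cd"] = np.clip(vals["cd"], 1e-6, None) * present
            vals["cd"] = vals["cd"] / vals["cd"].sum()
            vals["fa"] = np.clip(vals["fa"], 0.0, 1.0) * present
            vals["md"] = np.clip(vals["md"], 0.0, None) * present

            def to_mat(v):
                m = np.zeros((R, R))
                m[iu] = v
                return m + m.T

            # synthetic counts consistent with the densities (n_all = 10000)
            n_all = 10000
            counts = np.round(to_mat(vals["cd"]) * n_all).astype(int)
            counts[to_mat(present.astype(float)) > 0] = np.maximum(
                counts[to_mat(present.astype(float)) > 0], 1
            )
            net = ConnectivityNetwork(
                counts=counts,
                density=to_mat(vals["cd"]),
                fa=to_mat(vals["fa"]),
                md=to_mat(vals["md"]),
                n_all=n_all,
                m=1,
            )
            networks.append(net)
            labels.append(glabel)
    planted_pairs = [(int(iu[0][e]), int(iu[1][e])) for e in planted]
    return CohortDataset(networks=networks, labels=labels, planted_edges=planted_pairs)


def make_dwi_cohort(
    n_per_group: tuple[int, int] = (6, 6),
    seed: int = 0,
    snr: float = 25.0,
    grid_shape: tuple[int, int, int] = (24, 12, 12),
    bundle_radius_vox: float = 2.5,
    group2_inside_eigenvalues: tuple[float, float, float] = (1.2e-3, 0.5e-3, 0.5e-3),
    group_labels: tuple = (0, 1),
):
    """DWI-level two-group cohort: group 2 bundles are degraded.

    Each subject is a straight-bundle phantom with Rician noise; group 2
    carries less anisotropic bundle tensors (FA ≈ 0.50 vs ≈ 0.80),
    emulating fibre degeneration.  Returns a list of dicts with keys
    ``spec``, ``group`` and per-subject ``seed`` — the phantom itself is
    generated lazily by :func:`make_bundle_phantom` so pipelines control
    the gradient table.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for gi, (glabel, n) in enumerate(zip(group_labels, n_per_group)):
        for _ in range(n):
            sub_seed = int(rng.integers(2**31 - 1))
            spec = BundlePhantomSpec(
                grid_shape=grid_shape,
                geometry="straight",
                bundle_radius_vox=bundle_radius_vox,
                snr=snr,
                seed=sub_seed,
            )
            if gi == 1:
                spec = replace(spec, inside_eigenvalues=group2_inside_eigenvalues)
            subjects.append({"spec": spec, "group": glabel, "seed": sub_seed})
    return subjects
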