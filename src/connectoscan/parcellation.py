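"""Atlas-based cortical parcellation in native space.

A probabilistic atlas (one probability map per region) is thresholded so
that a voxel belongs to a region only when its membership probability
exceeds a cutoff (default 35%), with ties and overlaps resolved by argmax
— this guarantees non-overlapping regions.  A given affine transform
(e.g. an estimated template-to-native registration) then carries the
integer labels onto the subject's native grid by nearest-neighbour
resampling.  Registration *estimation* is deliberately not part of this
package: transforms are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


__all__ = [
    "AffineTransform",
    "LabelVolume",
    "threshold_probabilistic_atlas",
    "resample_labels",
]


class TransformDirection(str, Enum):
    NATIVE_TO_TEMPLATE = "native_to_template"
    TEMPLATE_TO_NATIVE = "template_to_native"


@dataclass(frozen=True)
class AffineTransform:
    """A 4×4 affine with a declared direction of mapping."""

    matrix: np.ndarray
    direction: TransformDirection = TransformDirection.TEMPLATE_TO_NATIVE

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).reshape(4, 4)
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("affine transform is singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "direction", TransformDirection(self.direction))

    def inverse(self) -> "AffineTransform":
        other = (
            TransformDirection.NATIVE_TO_TEMPLATE
            if self.direction == TransformDirection.TEMPLATE_TO_NATIVE
            else TransformDirection.TEMPLATE_TO_NATIVE
        )
        return AffineTransform(np.linalg.inv(self.matrix), other)


@dataclass
class LabelVolume:
    """Integer region labels on a 3-D grid (0 = background, 1..R = regions)."""

    labels: np.ndarray
    affine: np.ndarray
    region_names: list[str] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("label volume must be integer valued")
            self.labels = np.round(self.labels).astype(np.int32)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        n = int(self.labels.max())
        if self.region_names is None:
            self.region_names = [f"region_{i}" for i in range(1, n + 1)]
        if len(self.region_names) < n:
            raise ValueError("fewer region names than region ids")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


def threshold_probabilistic_atlas(
    prob_atlas: np.ndarray,
    threshold_pct: float = 35.0,
    affine: np.ndarray | None = None,
    region_names: list[str] | None = None,
) -> LabelVolume:
    """Label each voxel with the most probable region above a threshold.

    Parameters
    ----------
    prob_atlas : (X, Y, Z, R) probability maps, either in percent [0, 100]
        or fractions [0, 1] (auto-detected from the data maximum).
    threshold_pct : inclusion threshold in percent; a voxel gets a label
        only if some region's probability strictly exceeds it.  Among
        suprathreshold regions the argmax wins; exact probability ties go
        to the lowest region index, so the labelling is deterministic and
        regions never overlap.
    """
    p = np.asarray(prob_atlas, dtype=float)
    if p.ndim != 4 or p.shape[3] == 0:
        raise ValueError("probabilistic atlas must be 4-D with R >= 1 maps")
    if p.max() <= 1.0:  # fractional probabilities
        p = p * 100.0
    above = p > threshold_pct
    # argmax takes the first (lowest-index) maximum: deterministic tie-break
    best = np.argmax(np.where(above, p, -np.inf), axis=-1)
    labels = np.where(above.any(axis=-1), best + 1, 0).astype(np.int32)
    if affine is None:
        affine = np.eye(4)
    return LabelVolume(labels, affine, region_names)


def resample_labels(
    atlas: LabelVolume,
    transform: AffineTransform,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray | None = None,
) -> LabelVolume:
    """Nearest-neighbour resample of integer labels onto a target grid.

    ``transform.matrix`` maps template voxel indices to target voxel
    indices; a native-to-template transform is inverted automatically.
    Nearest-neighbour interpolation guarantees the output label set is a
    subset of the input's.
    """
    if transform.direction == TransformDirection.NATIVE_TO_TEMPLATE:
        transform = transform.inverse()
    # for each target voxel find its source (template) voxel
    inv = np.linalg.inv(transform.matrix)
    ii, jj, kk = np.meshgrid(
        np.arange(target_shape[0]),
        np.arange(target_shape[1]),
        np.arange(target_shape[2]),
        indexing="ij",
    )
    tgt = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    src = inv @ tgt
    # nearest-neighbour: round to the closest source voxel centre;
    # anything landing outside the source grid becomes background
    idx = np.round(src[:3]).astype(int)
    inside = np.all(
        (idx >= 0) & (idx < np.asarray(atlas.labels.shape)[:, None]), axis=0
    )
    out = np.zeros(idx.shape[1], dtype=np.int32)
    out[inside] = atlas.labels[idx[0, inside], idx[1, inside], idx[2, inside]]
    out = out.reshape(target_shape)
    if target_affine is None:
        target_affine = atlas.affine
    return LabelVolume(out.astype(np.int32), target_affine, atlas.region_names)
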