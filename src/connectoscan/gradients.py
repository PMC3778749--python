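"""Diffusion gradient tables (b-values and unit gradient directions).

A :class:`GradientTable` describes the diffusion-weighting scheme of an
acquisition: one b-value (s/mm²) and one gradient direction per volume.
The default table emulates a clinical single-shell scheme with 15
noncollinear directions at b = 800 s/mm² plus one unweighted (b = 0)
volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GradientTable", "default_gradient_table"]

DEFAULT_B_VALUE = 800.0  # s/mm²
DEFAULT_N_DIRECTIONS = 15


@dataclass(frozen=True)
class GradientTable:
    """b-values (s/mm²) and gradient directions for a DWI acquisition.

    Parameters
    ----------
    bvals : (N,) array of non-negative b-values in s/mm².
    bvecs : (N, 3) array; unit vectors where the b-value is positive,
        zero vectors allowed for b = 0 entries.

    At least one b = 0 entry and at least six diffusion-weighted
    directions spanning 3-space (full-rank design matrix) are required
    so that the six unique tensor elements are identifiable.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals has {bvals.shape[0]} entries but bvecs has "
                f"{bvecs.shape[0]} rows"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        dw = bvals > 0
        if not np.any(bvals == 0):
            raise ValueError("gradient table needs at least one b = 0 entry")
        if dw.sum() < 6:
            raise ValueError("need at least 6 diffusion-weighted directions")
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must be unit norm")
        if np.linalg.matrix_rank(design_matrix(bvals[dw], bvecs[dw])) < 6:
            raise ValueError("gradient design matrix is rank deficient")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Stejskal–Tanner design matrix rows b·[gx², gy², gz², 2gxgy, 2gxgz, 2gygz].

    Solving ``-ln(S/S0) = B @ d`` for ``d = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)``
    fits the log-linearised single-tensor model.
    """
    g = np.asarray(bvecs, dtype=float)
    b = np.asarray(bvals, dtype=float)[:, None]
    return b * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the upper hemisphere."""
    i = np.arange(n) + 0.5
    # golden-angle spiral restricted to z >= 0
    z = i / n  # (0, 1]
    phi = np.pi * (1 + np.sqrt(5.0)) * i
    r = np.sqrt(1 - z**2)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def default_gradient_table(
    n_directions: int = DEFAULT_N_DIRECTIONS, b_value: float = DEFAULT_B_VALUE
) -> GradientTable:
    """Single-shell table: one b = 0 row plus ``n_directions`` noncollinear
    unit directions at ``b_value`` s/mm², approximately uniform over the
    hemisphere (antipodal directions are equivalent for diffusion).
    """
    dirs = _fibonacci_hemisphere(n_directions)
    bvals = np.concatenate([[0.0], np.full(n_directions, float(b_value))])
    bvecs = np.vstack([np.zeros(3), dirs])
    return GradientTable(bvals, bvecs)
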