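"""Voxel-wise diffusion tensor fitting and scalar maps (FA, MD, e1).

The single-tensor model describes the diffusion-weighted signal as

    S_k = S0 · exp(−b_k · g_kᵀ D g_k)

with D a symmetric positive-semidefinite 3×3 tensor per voxel.  Fitting is
by ordinary least squares on the log-linearised system
``−ln(S_k/S0) = b_k g_kᵀ D g_k``, which is exact for noiseless data and the
conventional estimator for single-shell clinical acquisitions.  From the
eigenvalues λ1 ≥ λ2 ≥ λ3 the scalar maps are

    FA = sqrt(1/2) · sqrt((λ1−λ2)² + (λ2−λ3)² + (λ3−λ1)²) / sqrt(λ1²+λ2²+λ3²)
    MD = (λ1 + λ2 + λ3) / 3

Voxels with non-positive signals are flagged invalid; negative eigenvalues
(noise) are clamped to zero before FA/MD and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientTable, design_matrix

__all__ = ["TensorField", "DWIVolume", "fit_tensor", "fa_of", "md_of"]

# index order of the 6 unique tensor elements (FSL lower-triangular dialect)
TENSOR_ELEMENT_ORDER = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class DWIVolume:
    """4-D diffusion-weighted image: data[x, y, z, gradient] plus geometry."""

    data: np.ndarray
    affine: np.ndarray
    voxel_size_mm: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D (x, y, z, gradient)")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if self.voxel_size_mm is None:
            self.voxel_size_mm = np.linalg.norm(self.affine[:3, :3], axis=0)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)

    @property
    def grid_shape(self):
        return self.data.shape[:3]


def _tensor_from_elements(d6: np.ndarray) -> np.ndarray:
    """(..., 6) element vectors -> (..., 3, 3) symmetric tensors."""
    d6 = np.asarray(d6, dtype=float)
    out = np.empty(d6.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = d6[..., 0]
    out[..., 1, 1] = d6[..., 1]
    out[..., 2, 2] = d6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 5]
    return out


def _elements_from_tensor(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    return np.stack(
        [D[..., 0, 0], D[..., 1, 1], D[..., 2, 2],
         D[..., 0, 1], D[..., 0, 2], D[..., 1, 2]],
        axis=-1,
    )


def fa_of(eigenvalues) -> float:
    """Fractional anisotropy of a set of tensor eigenvalues, in [0, 1].

    All-zero eigenvalues define FA = 0 (avoids NaN propagation into
    tracking masks).  Small negative eigenvalues (|λ| ≤ 1e-12·max) are
    tolerated and clamped; larger ones raise.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected 3 eigenvalues")
    tol = 1e-12 * max(1.0, float(np.max(np.abs(lam))) if lam.size else 1.0)
    if np.any(lam < -tol):
        raise ValueError("negative eigenvalue beyond tolerance")
    lam = np.clip(lam, 0.0, None)
    num = np.sqrt(
        (lam[..., 0] - lam[..., 1]) ** 2
        + (lam[..., 1] - lam[..., 2]) ** 2
        + (lam[..., 2] - lam[..., 0]) ** 2
    )
    den = np.sqrt(2.0 * np.sum(lam**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return fa if fa.ndim else float(fa)


def md_of(eigenvalues) -> float:
    """Mean diffusivity: arithmetic mean of the three eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected 3 eigenvalues")
    tol = 1e-12 * max(1.0, float(np.max(np.abs(lam))) if lam.size else 1.0)
    if np.any(lam < -tol):
        raise ValueError("negative eigenvalue beyond tolerance")
    lam = np.clip(lam, 0.0, None)
    md = np.mean(lam, axis=-1)
    return md if md.ndim else float(md)


@dataclass
class TensorField:
    """Per-voxel diffusion tensors with derived eigenstructure and maps.

    Attributes
    ----------
    D : (X, Y, Z, 3, 3) symmetric tensors in mm²/s.
    eigenvalues : (X, Y, Z, 3), descending.
    e1 : (X, Y, Z, 3) principal eigenvector (unit norm where valid).
    fa_map, md_map : (X, Y, Z) scalar maps.
    valid : boolean mask of voxels with a usable fit.
    affine : voxel-to-world (mm) 4×4.
    """

    D: np.ndarray
    affine: np.ndarray
    valid: np.ndarray = None
    eigenvalues: np.ndarray = field(default=None)
    e1: np.ndarray = field(default=None)
    fa_map: np.ndarray = field(default=None)
    md_map: np.ndarray = field(default=None)
    negative_eigenvalue: np.ndarray = field(default=None)

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape[-2:] != (3, 3):
            raise ValueError("D must have trailing shape (3, 3)")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if self.valid is None:
            self.valid = np.ones(self.D.shape[:-2], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.eigenvalues is None:
            self._decompose()

    def _decompose(self):
        # eigh returns ascending eigenvalues; flip to descending
        w, v = np.linalg.eigh(self.D)
        w = w[..., ::-1]
        v = v[..., :, ::-1]
        self.negative_eigenvalue = np.any(w < -1e-15, axis=-1) & self.valid
        w_cl = np.clip(w, 0.0, None)
        self.eigenvalues = w_cl
        self.e1 = np.ascontiguousarray(v[..., :, 0])
        num = np.sqrt(
            (w_cl[..., 0] - w_cl[..., 1]) ** 2
            + (w_cl[..., 1] - w_cl[..., 2]) ** 2
            + (w_cl[..., 2] - w_cl[..., 0]) ** 2
        )
        den = np.sqrt(2.0 * np.sum(w_cl**2, axis=-1))
        safe = den > 0
        fa = np.zeros_like(den)
        fa[safe] = num[safe] / den[safe]
        self.fa_map = np.where(self.valid, fa, 0.0)
        self.md_map = np.where(self.valid, np.mean(w_cl, axis=-1), 0.0)

    @property
    def grid_shape(self):
        return self.D.shape[:-2]

    @property
    def inverse_affine(self):
        return np.linalg.inv(self.affine)


def fit_tensor(
    dwi: DWIVolume,
    gradients: GradientTable,
    mask: np.ndarray | None = None,
) -> TensorField:
    """Fit the diffusion tensor per voxel by log-linear ordinary least squares.

    Multiple b = 0 volumes are averaged into a single S0.  Voxels outside
    ``mask`` or with any non-positive signal are flagged invalid and carry
    a zero tensor.

    Raises
    ------
    ValueError
        If the data/gradient lengths disagree or the design is rank
        deficient (guarded already by :class:`GradientTable`).
    """
    data = dwi.data
    if data.shape[3] != len(gradients):
        raise ValueError(
            f"DWI has {data.shape[3]} volumes but gradient table has "
            f"{len(gradients)} entries"
        )
    b0 = gradients.b0_mask
    dw = gradients.dwi_mask
    B = design_matrix(gradients.bvals[dw], gradients.bvecs[dw])
    # pinv is exact for the full-rank overdetermined OLS problem
    B_pinv = np.linalg.pinv(B)

    s0 = data[..., b0].mean(axis=-1)
    s = data[..., dw]

    valid = (s0 > 0) & np.all(s > 0, axis=-1)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)

    logratio = np.zeros_like(s)
    vs = valid
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio[vs] = -np.log(s[vs] / s0[vs, None])
    d6 = logratio @ B_pinv.T
    d6[~valid] = 0.0
    D = _tensor_from_elements(d6)
    return TensorField(D=D, affine=dwi.affine, valid=valid)
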