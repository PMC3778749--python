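"""Individual structural connectivity network (ISCN) construction.

A tractogram and a region-label volume combine into a per-subject
symmetric R×R network.  Two regions i, j are connected when at least
``m`` streamlines (m ∈ {1, 3, 5, …}) have one endpoint in each.  Each
connection carries three attributes:

* fibre density  cd_ij = n_ij / n_all, the fraction of the subject's
  streamlines joining the pair,
* FA_ij, the mean FA over the union of voxels visited by the
  connection's streamlines (each voxel counted once),
* MD_ij, the analogous mean MD.

Edges failing the m-fibre threshold carry exact 0 in every attribute, so
cohort feature vectors have fixed length and "no measured connection" is
a meaningful zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parcellation import LabelVolume
from .tensor import TensorField
from .tracking import Tractogram

__all__ = [
    "ConnectivityNetwork",
    "CohortDataset",
    "assign_endpoints",
    "build_network",
    "group_average",
]


def _check_symmetric_zero_diag(mat: np.ndarray, name: str):
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    if np.any(np.diag(mat) != 0):
        raise ValueError(f"{name} must have a zero diagonal")


@dataclass
class ConnectivityNetwork:
    """Symmetric R×R edge matrices for one subject.

    ``counts`` holds raw streamline tallies n_ij; ``density``/``fa``/``md``
    are zeroed wherever n_ij < m.  ``n_all`` is the subject's total
    streamline count (all launched fibres, including those that connect
    no region pair).
    """

    counts: np.ndarray
    density: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    n_all: int
    m: int = 1
    region_names: list[str] | None = None
    # unthresholded attribute matrices, kept so the connection rule can
    # be tightened without re-tracking
    raw_fa: np.ndarray = field(default=None, repr=False)
    raw_md: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        for name in ("counts", "density", "fa", "md"):
            _check_symmetric_zero_diag(np.asarray(getattr(self, name)), name)
        if self.m < 1:
            raise ValueError("connection threshold m must be >= 1")
        if self.raw_fa is None:
            self.raw_fa = self.fa.copy()
        if self.raw_md is None:
            self.raw_md = self.md.copy()

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]

    @property
    def degenerate(self) -> bool:
        return self.n_all == 0

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        raw_fa: np.ndarray,
        raw_md: np.ndarray,
        n_all: int,
        m: int = 1,
        region_names: list[str] | None = None,
    ) -> "ConnectivityNetwork":
        """Apply the m-fibre connection rule to raw count/attribute matrices."""
        counts = np.asarray(counts)
        present = counts >= m
        density = np.zeros(counts.shape, dtype=float)
        if n_all > 0:
            density[present] = counts[present] / float(n_all)
        fa = np.where(present, raw_fa, 0.0)
        md = np.where(present, raw_md, 0.0)
        return cls(
            counts=counts, density=density, fa=fa, md=md,
            n_all=int(n_all), m=int(m), region_names=region_names,
            raw_fa=np.asarray(raw_fa, float), raw_md=np.asarray(raw_md, float),
        )

    def rethreshold(self, m: int) -> "ConnectivityNetwork":
        """Same subject, stricter (or looser) connection definition."""
        return ConnectivityNetwork.from_counts(
            self.counts, self.raw_fa, self.raw_md, self.n_all, m,
            self.region_names,
        )

    def attribute(self, name: str) -> np.ndarray:
        if name not in ("cd", "fa", "md"):
            raise ValueError(f"unknown attribute {name!r}")
        return {"cd": self.density, "fa": self.fa, "md": self.md}[name]


@dataclass
class CohortDataset:
    """Networks with group labels, ready for edge-feature vectorization."""

    networks: list[ConnectivityNetwork]
    labels: list
    planted_edges: list[tuple[int, int]] | None = None

    def __post_init__(self):
        if len(self.networks) != len(self.labels):
            raise ValueError("one label per network required")
        if self.networks:
            r = self.networks[0].n_regions
            if any(n.n_regions != r for n in self.networks):
                raise ValueError("all networks must share n_regions")

    @property
    def n_regions(self) -> int:
        return self.networks[0].n_regions

    def __len__(self):
        return len(self.networks)


def _endpoint_voxel(inv_affine: np.ndarray, point: np.ndarray) -> tuple[int, ...]:
    v = inv_affine[:3, :3] @ point + inv_affine[:3, 3]
    return tuple(int(i) for i in np.round(v))


def assign_endpoints(tract: Tractogram, labels: LabelVolume) -> list[tuple[int, int] | None]:
    """Map each streamline to its (region_i, region_j) endpoint pair.

    Endpoints falling in background (label 0) or both in the same region
    yield ``None``.  Endpoint voxels are found by the same half-open
    rounding convention tracking uses.
    """
    if tuple(labels.labels.shape) != tuple(tract.grid_shape):
        raise ValueError(
            f"label grid {labels.labels.shape} does not match tractogram "
            f"grid {tract.grid_shape}"
        )
    inv = np.linalg.inv(labels.affine)
    shape = np.asarray(labels.labels.shape)
    pairs: list[tuple[int, int] | None] = []
    for s in tract.streamlines:
        ends = []
        for p in (s.points[0], s.points[-1]):
            idx = _endpoint_voxel(inv, p)
            if np.any(np.asarray(idx) < 0) or np.any(np.asarray(idx) >= shape):
                ends.append(0)
            else:
                ends.append(int(labels.labels[idx]))
        a, b = sorted(ends)
        pairs.append((a, b) if a != 0 and a != b else None)
    return pairs


def build_network(
    tract: Tractogram,
    labels: LabelVolume,
    tensor_field: TensorField,
    m: int = 1,
) -> ConnectivityNetwork:
    """Tally streamline endpoint pairs into an ISCN.

    n_ij counts streamlines with endpoints in regions i and j; n_all is
    the total number of streamlines in the tractogram.  FA_ij (MD_ij) is
    the mean FA (MD) over the deduplicated union of voxels visited by all
    of the edge's streamlines.  An empty tractogram yields an all-zero
    network with ``n_all = 0`` (flagged via ``degenerate``).
    """
    if m < 1:
        raise ValueError("connection threshold m must be >= 1")
    R = labels.n_regions
    counts = np.zeros((R, R), dtype=int)
    edge_voxels: dict[tuple[int, int], set] = {}
    pairs = assign_endpoints(tract, labels)
    inv = np.linalg.inv(labels.affine)
    for s, pair in zip(tract.streamlines, pairs):
        if pair is None:
            continue
        i, j = pair[0] - 1, pair[1] - 1
        counts[i, j] += 1
        counts[j, i] += 1
        vox = edge_voxels.setdefault((i, j), set())
        for p in s.points:
            vox.add(_endpoint_voxel(inv, p))
    raw_fa = np.zeros((R, R), dtype=float)
    raw_md = np.zeros((R, R), dtype=float)
    for (i, j), vox in edge_voxels.items():
        idx = tuple(np.asarray(list(vox)).T)
        raw_fa[i, j] = raw_fa[j, i] = float(np.mean(tensor_field.fa_map[idx]))
        raw_md[i, j] = raw_md[j, i] = float(np.mean(tensor_field.md_map[idx]))
    return ConnectivityNetwork.from_counts(
        counts, raw_fa, raw_md, n_all=len(tract), m=m,
        region_names=labels.region_names,
    )


def group_average(networks: list[ConnectivityNetwork]):
    """Entrywise mean of each attribute plus a never-connected mask.

    Returns a dict of (R, R) mean matrices for ``cd``/``fa``/``md`` and a
    boolean ``never_connected`` mask marking entries with no connection
    in any subject of the group.
    """
    if not networks:
        raise ValueError("need at least one network")
    R = networks[0].n_regions
    if any(n.n_regions != R for n in networks):
        raise ValueError("all networks must share n_regions and ordering")
    means = {
        attr: np.mean([n.attribute(attr) for n in networks], axis=0)
        for attr in ("cd", "fa", "md")
    }
    present = np.zeros((R, R), dtype=bool)
    for n in networks:
        present |= n.counts >= n.m
    never = ~present
    np.fill_diagonal(never, True)
    means["never_connected"] = never
    return means
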