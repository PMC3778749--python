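"""Readers and writers for the standard formats the pipeline touches.

NIfTI-1 volumes go through nibabel; gradient tables use the FSL
bval/bvec text dialect (one whitespace-delimited row of b-values; three
rows of direction components); affine transforms use the FLIRT 4×4 text
matrix; tractograms are written as TrackVis TRK or TCK via
nibabel.streamlines; networks and cohorts are plain CSV edge lists with
a JSON manifest.  Write-then-read round trips reproduce arrays to the
format's precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import TckFile, TrkFile
from nibabel.streamlines import Tractogram as NibTractogram

from .gradients import GradientTable
from .network import CohortDataset, ConnectivityNetwork
from .parcellation import LabelVolume
from .tensor import DWIVolume, TensorField
from .tracking import Streamline, Tractogram

__all__ = [
    "read_nifti", "write_nifti", "read_dwi", "write_dwi",
    "read_gradients", "write_gradients", "read_labels", "write_labels",
    "read_affine", "write_affine", "write_tensor_maps",
    "read_tractogram", "write_tractogram",
    "write_network", "read_network", "write_cohort", "read_cohort",
]


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_nifti(path, data: np.ndarray, affine: np.ndarray):
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def read_gradients(bval_path, bvec_path) -> GradientTable:
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.ndim != 2 or 3 not in bvecs.shape:
        raise ValueError(f"{bvec_path}: expected a 3×N or N×3 matrix")
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.shape[0]:
        raise ValueError(
            f"{bvec_path} has {bvecs.shape[0]} directions but {bval_path} "
            f"has {bvals.shape[0]} b-values"
        )
    return GradientTable(bvals, bvecs)


def write_gradients(table: GradientTable, bval_path, bvec_path):
    np.savetxt(str(bval_path), table.bvals[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), table.bvecs.T, fmt="%.17g")


def read_dwi(nii_path, bval_path, bvec_path) -> tuple[DWIVolume, GradientTable]:
    data, affine = read_nifti(nii_path)
    if data.ndim != 4:
        raise ValueError(f"{nii_path}: DWI must be 4-D")
    table = read_gradients(bval_path, bvec_path)
    if data.shape[3] != len(table):
        raise ValueError(
            f"{nii_path} has {data.shape[3]} volumes but the gradient "
            f"table has {len(table)} entries"
        )
    return DWIVolume(data, affine), table


def write_dwi(dwi: DWIVolume, table: GradientTable, nii_path, bval_path, bvec_path):
    write_nifti(nii_path, dwi.data, dwi.affine)
    write_gradients(table, bval_path, bvec_path)


def read_labels(path, names_path=None) -> LabelVolume:
    data, affine = read_nifti(path)
    names = None
    if names_path is not None:
        names = pd.read_csv(names_path, sep="\t")["name"].tolist()
    return LabelVolume(np.round(data).astype(np.int32), affine, names)


def write_labels(labels: LabelVolume, path, names_path=None):
    nib.save(
        nib.Nifti1Image(labels.labels.astype(np.int16), labels.affine), str(path)
    )
    if names_path is not None:
        pd.DataFrame(
            {"id": np.arange(1, labels.n_regions + 1), "name": labels.region_names}
        ).to_csv(names_path, sep="\t", index=False)


def read_affine(path) -> np.ndarray:
    m = np.loadtxt(str(path))
    if m.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4×4 matrix, got {m.shape}")
    return m


def write_affine(matrix: np.ndarray, path):
    np.savetxt(str(path), np.asarray(matrix).reshape(4, 4), fmt="%.17g")


def write_tensor_maps(field: TensorField, out_dir):
    """fa/md/e1 plus the 6-component tensor volume (FSL element order)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_nifti(out / "fa.nii.gz", field.fa_map, field.affine)
    write_nifti(out / "md.nii.gz", field.md_map, field.affine)
    write_nifti(out / "e1.nii.gz", field.e1, field.affine)
    D = field.D
    d6 = np.stack(
        [D[..., 0, 0], D[..., 0, 1], D[..., 0, 2],
         D[..., 1, 1], D[..., 1, 2], D[..., 2, 2]],
        axis=-1,
    )
    write_nifti(out / "tensor.nii.gz", d6, field.affine)
    write_nifti(out / "valid.nii.gz", field.valid.astype(np.uint8), field.affine)


def write_tractogram(tract: Tractogram, path, summary_path=None):
    """TRK or TCK (by extension) plus an optional JSON summary."""
    path = Path(path)
    nt = NibTractogram(
        [s.points.astype(np.float32) for s in tract.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    voxel_sizes = np.linalg.norm(tract.affine[:3, :3], axis=0)
    if path.suffix == ".trk":
        header = {
            "voxel_sizes": voxel_sizes.astype(np.float32),
            "dimensions": np.asarray(tract.grid_shape, dtype=np.int16),
            "voxel_to_rasmm": tract.affine.astype(np.float32),
            "voxel_order": "RAS",
        }
        TrkFile(nt, header=header).save(str(path))
    elif path.suffix == ".tck":
        TckFile(nt).save(str(path))
    else:
        raise ValueError(f"unsupported tractogram format: {path.suffix}")
    if summary_path is not None:
        summary = {
            "n_streamlines": len(tract),
            "n_seeds": tract.n_seeds,
            "termination_histogram": tract.termination_histogram(),
            "grid_shape": list(tract.grid_shape),
            "affine": tract.affine.tolist(),
        }
        Path(summary_path).write_text(json.dumps(summary, indent=2))


def read_tractogram(path, affine=None, grid_shape=None) -> Tractogram:
    path = Path(path)
    f = nib.streamlines.load(str(path))
    streamlines = [
        Streamline(
            points=np.asarray(s, dtype=float),
            seed_voxel=(-1, -1, -1),
            termination_reasons=("unknown", "unknown"),
        )
        for s in f.tractogram.streamlines
    ]
    if affine is None:
        if hasattr(f, "header") and "voxel_to_rasmm" in getattr(f, "header", {}):
            affine = np.asarray(f.header["voxel_to_rasmm"], dtype=float)
        else:
            affine = np.eye(4)
    if grid_shape is None:
        hdr = getattr(f, "header", {})
        grid_shape = tuple(int(i) for i in hdr.get("dimensions", (0, 0, 0)))
    return Tractogram(
        streamlines=streamlines, affine=affine, grid_shape=tuple(grid_shape),
        n_seeds=len(streamlines),
    )


def _edge_frame(net: ConnectivityNetwork) -> pd.DataFrame:
    iu = np.triu_indices(net.n_regions, k=1)
    df = pd.DataFrame(
        {
            "region_i": iu[0] + 1,
            "region_j": iu[1] + 1,
            "count": net.counts[iu],
            "cd": net.density[iu],
            "fa": net.fa[iu],
            "md": net.md[iu],
        }
    )
    return df[df["count"] > 0].reset_index(drop=True)


def write_network(net: ConnectivityNetwork, out_dir, subject_id="subject"):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _edge_frame(net).to_csv(out / f"{subject_id}_edges.csv", index=False)
    for attr in ("cd", "fa", "md"):
        pd.DataFrame(net.attribute(attr)).to_csv(
            out / f"{subject_id}_{attr}_matrix.csv", index=False, header=False
        )
    meta = {
        "subject_id": subject_id,
        "n_regions": net.n_regions,
        "n_all": net.n_all,
        "m": net.m,
    }
    (out / f"{subject_id}_meta.json").write_text(json.dumps(meta, indent=2))


def read_network(edge_csv, meta_json) -> ConnectivityNetwork:
    meta = json.loads(Path(meta_json).read_text())
    R = meta["n_regions"]
    counts = np.zeros((R, R), dtype=int)
    fa = np.zeros((R, R))
    md = np.zeros((R, R))
    df = pd.read_csv(edge_csv)
    for _, row in df.iterrows():
        i, j = int(row.region_i) - 1, int(row.region_j) - 1
        counts[i, j] = counts[j, i] = int(row["count"])
        fa[i, j] = fa[j, i] = row.fa
        md[i, j] = md[j, i] = row.md
    return ConnectivityNetwork.from_counts(
        counts, fa, md, n_all=meta["n_all"], m=meta["m"]
    )


def write_cohort(cohort: CohortDataset, out_dir, seed=None):
    """One edge-list CSV per subject plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_regions": cohort.n_regions,
        "seed": seed,
        "planted_edges": cohort.planted_edges,
        "subjects": [],
    }
    for k, (net, label) in enumerate(zip(cohort.networks, cohort.labels)):
        sid = f"sub-{k:03d}"
        _edge_frame(net).to_csv(out / f"{sid}_edges.csv", index=False)
        manifest["subjects"].append(
            {
                "id": sid,
                "group": label,
                "file": f"{sid}_edges.csv",
                "n_all": net.n_all,
                "m": net.m,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def read_cohort(cohort_dir) -> CohortDataset:
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    R = manifest["n_regions"]
    networks, labels = [], []
    for sub in manifest["subjects"]:
        df = pd.read_csv(cohort_dir / sub["file"])
        counts = np.zeros((R, R), dtype=int)
        fa = np.zeros((R, R))
        md = np.zeros((R, R))
        cd = np.zeros((R, R))
        for _, row in df.iterrows():
            i, j = int(row.region_i) - 1, int(row.region_j) - 1
            counts[i, j] = counts[j, i] = int(row["count"])
            cd[i, j] = cd[j, i] = row.cd
            fa[i, j] = fa[j, i] = row.fa
            md[i, j] = md[j, i] = row.md
        networks.append(
            ConnectivityNetwork(
                counts=counts, density=cd, fa=fa, md=md,
                n_all=sub["n_all"], m=sub["m"],
            )
        )
        labels.append(sub["group"])
    planted = manifest.get("planted_edges")
    if planted is not None:
        planted = [tuple(e) for e in planted]
    return CohortDataset(networks=networks, labels=labels, planted_edges=planted)
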