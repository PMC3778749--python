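"""End-to-end orchestration: DWI → tensors → tracking → networks → classification.

``run_pipeline`` executes the full analysis for a cohort of subjects,
persisting intermediate artifacts (tensor maps, tractogram, network edge
lists) per subject and the final accuracy grid, selection-frequency
matrix and config echo in the output directory.  Stages are resumable:
a subject whose network edge list already exists is not re-tracked.
Runs are deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .gradients import GradientTable, default_gradient_table
from .harness import ClassificationExperiment, ExperimentConfig, render_table
from .network import CohortDataset, build_network
from .phantoms import make_bundle_phantom, make_dwi_cohort
from .tensor import fit_tensor
from .tracking import TrackingConfig, track_whole_volume

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and subject id."""

    def __init__(self, stage, subject, original):
        self.stage = stage
        self.subject = subject
        super().__init__(f"stage {stage!r} failed for subject {subject!r}: {original}")


@dataclass
class RunConfig:
    """Everything a full run needs; serializable and echoed to outputs."""

    out_dir: str
    cohort_dir: str | None = None  # precomputed networks
    subjects: list | None = None   # DWI-level: dicts with dwi/bval/bvec/labels/group
    phantom_cohort: dict | None = None  # generate a DWI phantom cohort
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    connection_threshold: int = 1
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    seed: int = 0
    save_dwi: bool = False

    def to_dict(self):
        d = dataclasses.asdict(self)
        return d


def _echo_config(config: RunConfig, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    payload = config.to_dict()
    payload["code_version"] = __version__
    (out / "config_echo.yaml").write_text(
        yaml.safe_dump(payload, sort_keys=True)
    )


def _subject_network(sub_id, dwi, table, labels, config, sub_dir):
    """Tensor fit → tracking → network for one subject, with persistence."""
    edge_csv = sub_dir / f"{sub_id}_edges.csv"
    meta_json = sub_dir / f"{sub_id}_meta.json"
    if edge_csv.exists() and meta_json.exists():
        logger.info("subject %s: network exists, skipping recompute", sub_id)
        return cio.read_network(edge_csv, meta_json)
    try:
        field_ = fit_tensor(dwi, table)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("tensor_fit", sub_id, e) from e
    cio.write_tensor_maps(field_, sub_dir / "tensors")
    try:
        tract = track_whole_volume(field_, config.tracking)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("tracking", sub_id, e) from e
    cio.write_tractogram(
        tract, sub_dir / f"{sub_id}.trk", sub_dir / f"{sub_id}_track_summary.json"
    )
    try:
        net = build_network(tract, labels, field_, m=config.connection_threshold)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("network", sub_id, e) from e
    cio.write_network(net, sub_dir, subject_id=sub_id)
    return net


def run_pipeline(config: RunConfig):
    """Execute the pipeline and return the accuracy :class:`ResultGrid`."""
    out = Path(config.out_dir)
    _echo_config(config, out)
    log_file = out / "run.log"
    handler = logging.FileHandler(log_file)
    logging.getLogger("connectoscan").addHandler(handler)
    try:
        if config.cohort_dir is not None:
            cohort = cio.read_cohort(config.cohort_dir)
        else:
            if config.phantom_cohort is not None:
                spec_kw = dict(config.phantom_cohort)
                spec_kw.setdefault("seed", config.seed)
                subjects = make_dwi_cohort(**spec_kw)
                table = default_gradient_table()
                loaded = []
                for k, sub in enumerate(subjects):
                    dwi, _, labels = make_bundle_phantom(sub["spec"], table)
                    loaded.append(
                        {"id": f"sub-{k:03d}", "dwi": dwi, "table": table,
                         "labels": labels, "group": sub["group"]}
                    )
            elif config.subjects is not None:
                loaded = []
                for k, sub in enumerate(config.subjects):
                    sid = sub.get("id", f"sub-{k:03d}")
                    try:
                        dwi, table = cio.read_dwi(
                            sub["dwi"], sub["bval"], sub["bvec"]
                        )
                        labels = cio.read_labels(sub["labels"])
                    except KeyError as e:
                        raise PipelineError("parcellation", sid, f"missing input {e}")
                    except FileNotFoundError as e:
                        stage = "parcellation" if "label" in str(e) else "load_dwi"
                        raise PipelineError(stage, sid, e) from e
                    loaded.append(
                        {"id": sid, "dwi": dwi, "table": table,
                         "labels": labels, "group": sub["group"]}
                    )
            else:
                raise ValueError(
                    "config needs cohort_dir, subjects, or phantom_cohort"
                )
            networks, groups = [], []
            for sub in loaded:
                sub_dir = out / sub["id"]
                sub_dir.mkdir(parents=True, exist_ok=True)
                if config.save_dwi:
                    cio.write_dwi(
                        sub["dwi"], sub["table"], sub_dir / "dwi.nii.gz",
                        sub_dir / "dwi.bval", sub_dir / "dwi.bvec",
                    )
                net = _subject_network(
                    sub["id"], sub["dwi"], sub["table"], sub["labels"],
                    config, sub_dir,
                )
                networks.append(net)
                groups.append(sub["group"])
            cohort = CohortDataset(networks=networks, labels=groups)
            cio.write_cohort(cohort, out / "cohort", seed=config.seed)

        exp_cfg = dataclasses.replace(config.experiment, seed=config.seed)
        grid = ClassificationExperiment(cohort, exp_cfg).run()
        grid.to_dataframe().to_csv(out / "results.csv", index=False)
        (out / "results.txt").write_text(render_table(grid))
        sel_rows = []
        for (comp, attr), report in grid.selection.items():
            for (i, j), count in zip(report.feature_index, report.counts):
                if count > 0:
                    sel_rows.append(
                        {
                            "comparison": f"{comp[0]} vs {comp[1]}",
                            "attribute": attr,
                            "region_i": i + 1,
                            "region_j": j + 1,
                            "rounds_selected": int(count),
                            "highlighted": bool(count > report.round_threshold),
                        }
                    )
        import pandas as pd

        pd.DataFrame(sel_rows).to_csv(out / "selection_frequency.csv", index=False)
        (out / "seed.json").write_text(json.dumps({"seed": config.seed}))
        return grid
    finally:
        logging.getLogger("connectoscan").removeHandler(handler)
        handler.close()
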