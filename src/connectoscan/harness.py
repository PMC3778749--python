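"""Cross-validated classification of connectivity cohorts.

:class:`ClassificationExperiment` is the model-like object: it binds a
cohort and an :class:`ExperimentConfig` (comparisons, attributes,
classifiers, validation scheme, seed); ``run()`` executes the protocol
and returns a :class:`ResultGrid` results object.

The protocol is strictly nested: folds are stratified by class and
assigned by a seeded shuffle; within each validation round, feature
discretization, information-gain selection and classifier training see
only the training subjects, and each test subject is predicted exactly
once.  Pooled accuracy is total correct / total subjects, which makes
every reported accuracy an integer multiple of 1/n_subjects.  The whole
run is deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .classify import CLASSIFIERS
from .features import aggregate_selection, select_features, vectorize
from .network import CohortDataset

__all__ = [
    "ExperimentConfig",
    "ResultGrid",
    "ClassificationExperiment",
    "run_cv",
    "type_one_check",
    "render_table",
]

logger = logging.getLogger(__name__)

CLASSIFIER_DISPLAY = {"max_margin": "SVM", "knn": "k-NN", "nb": "Naive Bayes"}
ATTRIBUTE_DISPLAY = {"cd": "Fiber density", "fa": "FA", "md": "MD"}


@dataclass(frozen=True)
class ExperimentConfig:
    comparisons: tuple = None  # None -> all label pairs in the cohort
    attributes: tuple = ("cd", "fa", "md")
    classifiers: tuple = ("max_margin", "knn", "nb")
    validation: str = "kfold10"  # or "loo"
    n_folds: int = 10
    seed: int = 0
    selection: object = "all_positive"  # or an int top-n
    round_threshold: int = 5
    knn_k: int = 6
    svm_C: float = 1.0

    def __post_init__(self):
        if self.validation not in ("kfold10", "loo"):
            raise ValueError("validation must be 'kfold10' or 'loo'")
        if not self.attributes or not self.classifiers:
            raise ValueError("attributes and classifiers must be non-empty")
        for a in self.attributes:
            if a not in ("cd", "fa", "md"):
                raise ValueError(f"unknown attribute {a!r}")
        for c in self.classifiers:
            if c not in CLASSIFIERS:
                raise ValueError(f"unknown classifier {c!r}")


@dataclass
class ResultGrid:
    """Accuracies, fold assignments and selection reports of one run.

    ``cells`` maps (comparison, attribute, classifier) to a
    (correct, total) pair; ``selection`` maps (comparison, attribute) to
    a :class:`SelectionReport`.
    """

    cells: dict
    selection: dict
    fold_assignments: dict
    config: ExperimentConfig
    comparison_sizes: dict = field(default_factory=dict)

    def accuracy(self, comparison, attribute, classifier) -> float:
        correct, total = self.cells[(comparison, attribute, classifier)]
        return correct / total

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (comp, attr, clf), (correct, total) in self.cells.items():
            rows.append(
                {
                    "comparison": f"{comp[0]} vs {comp[1]}",
                    "attribute": attr,
                    "classifier": clf,
                    "correct": correct,
                    "total": total,
                    "accuracy": correct / total,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        return render_table(self)


def render_table(grid: ResultGrid) -> str:
    """Human-readable accuracy grid: one 3×3 block per comparison.

    Accuracies print as percentages to two decimals; rows are the edge
    attributes, columns the classifiers.
    """
    cfg = grid.config
    clfs = list(cfg.classifiers)
    lines = []
    header = f"{'':<16}" + "".join(
        f"{CLASSIFIER_DISPLAY.get(c, c):>14}" for c in clfs
    )
    comparisons = sorted({c for (c, _, _) in grid.cells})
    for comp in comparisons:
        lines.append(f"{comp[0]} vs. {comp[1]}")
        lines.append(header)
        for attr in cfg.attributes:
            row = f"{ATTRIBUTE_DISPLAY[attr]:<16}"
            for clf in clfs:
                correct, total = grid.cells[(comp, attr, clf)]
                row += f"{100.0 * correct / total:>13.2f}%"
            lines.append(row)
        lines.append("")
    return "\n".join(lines)


def _fold_indices(labels: np.ndarray, config: ExperimentConfig):
    """Stratified k-fold (seeded shuffle) or leave-one-out index pairs."""
    n = len(labels)
    if config.validation == "loo":
        return list(LeaveOneOut().split(np.zeros(n)))
    _, counts = np.unique(labels, return_counts=True)
    n_splits = min(config.n_folds, int(counts.min()))
    if n_splits < config.n_folds:
        logger.warning(
            "reducing folds from %d to %d (smallest class has %d members)",
            config.n_folds, n_splits, counts.min(),
        )
    if n_splits < 2:
        raise ValueError("need at least 2 subjects per class for k-fold")
    skf = StratifiedKFold(
        n_splits=n_splits, shuffle=True, random_state=config.seed % (2**31)
    )
    return list(skf.split(np.zeros(n), labels))


class ClassificationExperiment:
    """Binds a cohort to a validation protocol; ``run()`` yields results."""

    def __init__(self, cohort: CohortDataset, config: ExperimentConfig | None = None):
        self.cohort = cohort
        self.config = config or ExperimentConfig()

    def _comparisons(self):
        if self.config.comparisons is not None:
            return [tuple(c) for c in self.config.comparisons]
        classes = sorted(set(self.cohort.labels))
        return [
            (a, b) for i, a in enumerate(classes) for b in classes[i + 1:]
        ]

    def _make_classifier(self, name):
        if name == "max_margin":
            return CLASSIFIERS[name](C=self.config.svm_C)
        if name == "knn":
            return CLASSIFIERS[name](k=self.config.knn_k)
        return CLASSIFIERS[name]()

    def run(self) -> ResultGrid:
        cfg = self.config
        cells, selection, fold_assignments, sizes = {}, {}, {}, {}
        labels_all = np.asarray(self.cohort.labels)
        for comp in self._comparisons():
            rows = np.nonzero(np.isin(labels_all, comp))[0]
            sub_labels = labels_all[rows]
            for c in comp:
                if np.sum(sub_labels == c) < 2:
                    raise ValueError(f"class {c!r} has fewer than 2 subjects")
            folds = _fold_indices(sub_labels, cfg)
            fold_assignments[comp] = folds
            sizes[comp] = len(rows)
            for attr in cfg.attributes:
                fm_full = vectorize(self.cohort, attr).subset(rows)
                per_round_sel, per_round_gains = [], []
                correct = {clf: 0 for clf in cfg.classifiers}
                for train_idx, test_idx in folds:
                    train = fm_full.subset(train_idx)
                    sel, gains = select_features(train, cfg.selection)
                    per_round_gains.append(gains)
                    per_round_sel.append(sel)
                    if len(sel) == 0:
                        logger.warning(
                            "empty feature selection; falling back to all features"
                        )
                        cols = np.arange(fm_full.n_features)
                    else:
                        cols = sel
                    Xtr = train.values[:, cols]
                    ytr = train.labels
                    Xte = fm_full.values[test_idx][:, cols]
                    yte = fm_full.labels[test_idx]
                    for clf_name in cfg.classifiers:
                        model = self._make_classifier(clf_name).fit(Xtr, ytr)
                        pred = model.predict(Xte)
                        correct[clf_name] += int(np.sum(pred == yte))
                for clf_name in cfg.classifiers:
                    cells[(comp, attr, clf_name)] = (correct[clf_name], len(rows))
                selection[(comp, attr)] = aggregate_selection(
                    per_round_sel,
                    fm_full.feature_index,
                    round_threshold=cfg.round_threshold,
                    gains_per_round=per_round_gains,
                )
        return ResultGrid(
            cells=cells,
            selection=selection,
            fold_assignments=fold_assignments,
            config=cfg,
            comparison_sizes=sizes,
        )


def run_cv(cohort: CohortDataset, config: ExperimentConfig | None = None) -> ResultGrid:
    """Functional entry point: run the full validation protocol."""
    return ClassificationExperiment(cohort, config).run()


def type_one_check(
    cohort_factory,
    config: ExperimentConfig,
    n_repeats: int = 50,
    base_seed: int = 0,
):
    """Null-calibration check: accuracies on effect-free cohorts.

    ``cohort_factory(seed)`` must return a two-group cohort drawn with no
    planted effect (both groups from the identical distribution).  Runs
    the experiment once per repeat and returns a dict with per-repeat
    pooled accuracies per classifier, their means, and the 95% binomial
    interval around 0.5 for the total number of pooled predictions —
    under a valid (leak-free) protocol the means must fall inside it.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    accs = {clf: [] for clf in config.classifiers}
    n_predictions = 0  # pooled predictions per classifier across repeats
    for rep in range(n_repeats):
        seed = (base_seed + rep) % (2**31)
        cohort = cohort_factory(seed)
        if len(set(cohort.labels)) < 2:
            raise ValueError("null cohort must still contain two label groups")
        cfg = ExperimentConfig(**{**config.__dict__, "seed": seed})
        grid = ClassificationExperiment(cohort, cfg).run()
        rep_preds = {clf: 0 for clf in config.classifiers}
        rep_correct = {clf: 0 for clf in config.classifiers}
        for (comp, attr, clf), (correct, total) in grid.cells.items():
            rep_correct[clf] += correct
            rep_preds[clf] += total
        n_predictions += rep_preds[config.classifiers[0]]
        for clf in config.classifiers:
            accs[clf].append(rep_correct[clf] / rep_preds[clf])
    half = 1.96 * math.sqrt(0.25 / n_predictions)
    interval = (0.5 - half, 0.5 + half)
    return {
        "accuracies": {clf: np.asarray(v) for clf, v in accs.items()},
        "means": {clf: float(np.mean(v)) for clf, v in accs.items()},
        "binomial_interval_95": interval,
        "n_predictions": n_predictions,
    }
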