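"""Repeated stratified evaluation protocol with a permuted-label null.

The protocol, per repeat:

1. shuffle and split the cohort 80/20, stratified on the group label;
2. on the training+validation portion only, run a 10-fold stratified grid
   search (the minority class is SMOTE-balanced inside each fold's training
   portion, never in the held-out fold);
3. select the grid combination and fold with the highest validation accuracy;
4. construct a classifier with those optimal parameters (by default retrained
   on the full, balanced training+validation set) and evaluate it on the
   untouched test split: 2×2 confusion matrix, PPV, NPV, sensitivity,
   specificity, AUC and accuracy.

Repeating 1-4 many times yields per-metric distributions (mean ± SD).  The
matching null distribution permutes the training+validation labels, runs a
10-fold stratified cross-validation at fixed (optimal) parameters — no grid
search — selects the best-performing random fold model and evaluates it on
the test split with true labels.  Significance is the plain proportion of
null values at or above the correctly-trained mean.

Per-repeat randomness derives from the master seed via ``default_rng([seed,
stream, repeat])`` (stream 0 = correct pipeline, 1 = null), so any repeat is
reproducible in isolation.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datatypes import GMSlice, LabeledDataset, SubjectRecord
from .exceptions import ArchitectureError, ClassBalanceError, ConfigurationError
from .models import (
    CNNClassifier,
    CNNSpec,
    DAGClassifier,
    DAGSpec,
    TrainConfig,
    TrainedModel,
)
from .smote import SmoteConfig, balance

METRIC_NAMES = ("ppv", "npv", "sen", "spc", "auc", "acc")
SUBGROUP_NAMES = ("lesional", "non_lesional", "seizure_free", "non_seizure_free")


# --------------------------------------------------------------------------
# confusion matrix and metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts with TLE as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


def _safe_ratio(num: int, den: int):
    return (num / den) if den > 0 else float("nan")


@dataclass
class MetricsSummary:
    """PPV, NPV, SEN, SPC, AUC, ACC; undefined ratios are NaN and named."""

    ppv: float
    npv: float
    sen: float
    spc: float
    auc: float
    acc: float
    undefined: frozenset = frozenset()

    @classmethod
    def compute(
        cls,
        cm: ConfusionMatrix,
        y_true=None,
        scores=None,
    ) -> "MetricsSummary":
        if cm.total == 0:
            raise ValueError("empty confusion matrix")
        vals = {
            "acc": _safe_ratio(cm.tp + cm.tn, cm.total),
            "sen": _safe_ratio(cm.tp, cm.tp + cm.fn),
            "spc": _safe_ratio(cm.tn, cm.tn + cm.fp),
            "ppv": _safe_ratio(cm.tp, cm.tp + cm.fp),
            "npv": _safe_ratio(cm.tn, cm.tn + cm.fn),
        }
        auc = float("nan")
        if y_true is not None and scores is not None:
            y_true = np.asarray(y_true)
            if len(np.unique(y_true)) == 2:
                auc = float(roc_auc_score(y_true, np.asarray(scores)))
        vals["auc"] = auc
        undefined = frozenset(k for k, v in vals.items() if math.isnan(v))
        return cls(undefined=undefined, **vals)

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


class MetricDistribution:
    """Per-metric value lists over repeats with mean ± SD summaries.

    Undefined (NaN) entries are excluded from the mean/SD and counted.
    """

    def __init__(self) -> None:
        self.values: Dict[str, List[float]] = {m: [] for m in METRIC_NAMES}

    def add(self, summary: MetricsSummary) -> None:
        for m in METRIC_NAMES:
            self.values[m].append(getattr(summary, m))

    def __len__(self) -> int:
        return len(self.values["acc"])

    def mean(self, metric: str) -> float:
        vals = np.asarray(self.values[metric], dtype=float)
        return float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")

    def sd(self, metric: str) -> float:
        vals = np.asarray(self.values[metric], dtype=float)
        finite = vals[np.isfinite(vals)]
        if len(finite) < 2:
            return float("nan")
        return float(np.std(finite, ddof=1))

    def n_undefined(self, metric: str) -> int:
        return int(np.sum(~np.isfinite(np.asarray(self.values[metric], dtype=float))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metric": m,
                    "mean": self.mean(m),
                    "sd": self.sd(m),
                    "n": len(self.values[m]),
                    "n_undefined": self.n_undefined(m),
                }
                for m in METRIC_NAMES
            ]
        )


# --------------------------------------------------------------------------
# worked-example statistics
# --------------------------------------------------------------------------

def majority_baseline_accuracy(n_minority: int, n_majority: int) -> float:
    """Accuracy of always predicting the majority class."""
    total = n_minority + n_majority
    if total <= 0:
        raise ConfigurationError("total sample size must be positive")
    return n_majority / total


def pooled_t(mean1, sd1, n1, mean2, sd2, n2) -> float:
    """Magnitude of the pooled-variance two-sample t statistic."""
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ConfigurationError("standard deviations must be non-negative")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 0.0 if mean1 == mean2 else float("inf")
    return abs(mean2 - mean1) / se


def p_value(correct_mean: float, null_values: Sequence[float]) -> float:
    """Proportion of null values >= the correctly-trained mean (no correction)."""
    null_values = np.asarray(list(null_values), dtype=float)
    if null_values.size == 0:
        raise ValueError("null distribution is empty")
    return float(np.count_nonzero(null_values >= correct_mean) / null_values.size)


# --------------------------------------------------------------------------
# splitting and grid search
# --------------------------------------------------------------------------

def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def stratified_split(
    dataset: LabeledDataset, test_fraction: float = 0.2, rng=0
) -> Tuple[LabeledDataset, LabeledDataset]:
    """Stratified train+validation / test partition.

    Per-class test counts are ``floor(class_n * test_fraction)`` — the fixed
    rounding rule — so 95 patients / 202 controls at 0.2 give a 19 + 40 test
    set.  Partitions are disjoint and exhaustive; deterministic for a fixed
    rng state.
    """
    rng = _as_rng(rng)
    labels = dataset.labels
    counts = dataset.class_counts()
    if counts["HC"] < 5 or counts["TLE"] < 5:
        raise ConfigurationError(f"each class needs >= 5 samples, got {counts}")
    test_idx: List[int] = []
    train_idx: List[int] = []
    for label in (0, 1):
        cls_idx = np.flatnonzero(labels == label)
        n_test = int(math.floor(len(cls_idx) * test_fraction))
        if n_test == 0:
            raise ConfigurationError(
                f"test fraction {test_fraction} yields an empty test set for class {label}"
            )
        perm = rng.permutation(cls_idx)
        test_idx.extend(perm[:n_test].tolist())
        train_idx.extend(perm[n_test:].tolist())
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


@dataclass
class HyperGrid:
    """Candidate lists for the grid search (deterministic enumeration order:
    conv layers, then learning rate, epochs, validation frequency, plane)."""

    conv_layer_options: tuple = (CNNSpec.scaled().conv_layers,)
    learning_rates: tuple = (0.05,)
    epochs: tuple = (15,)
    validation_frequencies: tuple = (5,)
    plane_indices: tuple = (None,)
    batch_size: int = 16

    def __post_init__(self) -> None:
        for name in ("conv_layer_options", "learning_rates", "epochs",
                     "validation_frequencies", "plane_indices"):
            if len(getattr(self, name)) == 0:
                raise ConfigurationError(f"grid field {name} is empty")

    def combinations(self):
        for conv, lr, ep, vf, plane in itertools.product(
            self.conv_layer_options,
            self.learning_rates,
            self.epochs,
            self.validation_frequencies,
            self.plane_indices,
        ):
            yield conv, lr, ep, vf, plane

    def __len__(self) -> int:
        return (
            len(self.conv_layer_options)
            * len(self.learning_rates)
            * len(self.epochs)
            * len(self.validation_frequencies)
            * len(self.plane_indices)
        )


@dataclass
class OptimalParams:
    """The modelling parameters selected by the grid search."""

    spec: CNNSpec
    cfg: TrainConfig
    plane_index: Optional[int] = None


@dataclass
class GridSearchResult:
    optimal: OptimalParams
    winning_model: TrainedModel
    winning_fold: int
    fold_accuracies: List[float]
    skipped: List[Tuple[str, str]]
    smote_parent_ids: set
    best_accuracy: float


def _make_classifier(family: str, spec: CNNSpec, input_shape):
    if family == "dag":
        if not isinstance(spec, DAGSpec):
            spec = DAGSpec(conv_layers=spec.conv_layers, n_classes=spec.n_classes)
        return DAGClassifier(spec, input_shape)
    return CNNClassifier(spec, input_shape)


def _spec_for(family: str, conv_layers) -> CNNSpec:
    return DAGSpec(conv_layers=conv_layers) if family == "dag" else CNNSpec(conv_layers=conv_layers)


def grid_search(
    train_val: LabeledDataset,
    grid: HyperGrid,
    family: str = "cnn",
    k: int = 10,
    rng=0,
    smote_config: Optional[SmoteConfig] = None,
) -> GridSearchResult:
    """k-fold stratified grid search over ``grid`` on the train+val data.

    SMOTE balancing is applied to each fold's nine training folds only.
    The (combination, fold) pair with the highest validation accuracy wins;
    ties resolve to the first in enumeration order.  Unbuildable combinations
    (kernel chain too large for the image) are skipped and logged.
    """
    rng = _as_rng(rng)
    train_val.require_two_classes()
    if len(grid) == 0:
        raise ConfigurationError("empty hyperparameter grid")
    smote_config = smote_config or SmoteConfig()
    labels = train_val.labels
    min_class = min(train_val.class_counts().values())
    if min_class < k:
        raise ConfigurationError(
            f"minority class of {min_class} does not admit {k} stratified folds"
        )
    input_shape = train_val.images[0].shape
    fold_seed = int(rng.integers(2**31))
    base_seed = int(rng.integers(2**31))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
    folds = list(skf.split(np.zeros(len(train_val)), labels))

    best = None  # (acc, combo_i, fold_i, model, optimal)
    skipped: List[Tuple[str, str]] = []
    smote_parent_ids: set = set()
    best_fold_accs: List[float] = []

    for combo_i, (conv, lr, ep, vf, plane) in enumerate(grid.combinations()):
        spec = _spec_for(family, conv)
        try:
            _make_classifier(family, spec, input_shape)
        except ArchitectureError as exc:
            skipped.append((f"conv={conv} lr={lr} epochs={ep}", str(exc)))
            continue
        fold_accs = []
        fold_models = []
        for fold_i, (tr_idx, va_idx) in enumerate(folds):
            seed_ij = (base_seed + 9973 * combo_i + fold_i) % (2**31)
            fold_train = train_val.subset(tr_idx)
            fold_val = train_val.subset(va_idx)
            balanced, log = balance(fold_train, replace(smote_config, seed=seed_ij))
            smote_parent_ids.update(log.parent_subject_id)
            smote_parent_ids.update(log.neighbour_subject_id)
            cfg = TrainConfig(
                learning_rate=lr, epochs=ep, validation_frequency=vf,
                seed=seed_ij, batch_size=grid.batch_size,
            )
            model = _make_classifier(family, spec, input_shape).fit(balanced, fold_val, cfg)
            acc = float(np.mean(model.predict_labels(fold_val) == fold_val.labels))
            fold_accs.append(acc)
            fold_models.append(model)
        for fold_i, acc in enumerate(fold_accs):
            if best is None or acc > best[0]:
                optimal = OptimalParams(
                    spec=spec,
                    cfg=fold_models[fold_i].cfg,
                    plane_index=plane,
                )
                best = (acc, combo_i, fold_i, fold_models[fold_i], optimal)
                best_fold_accs = fold_accs
    if best is None:
        raise ConfigurationError("no grid combination was buildable: " + repr(skipped))
    acc, combo_i, fold_i, model, optimal = best
    return GridSearchResult(
        optimal=optimal,
        winning_model=model,
        winning_fold=fold_i,
        fold_accuracies=best_fold_accs,
        skipped=skipped,
        smote_parent_ids=smote_parent_ids,
        best_accuracy=acc,
    )


# --------------------------------------------------------------------------
# test-set evaluation
# --------------------------------------------------------------------------

@dataclass
class RepeatOutcome:
    confusion: ConfusionMatrix
    metrics: MetricsSummary
    subgroup_metrics: Dict[str, MetricsSummary]
    model: Optional[TrainedModel] = None
    scores: Optional[np.ndarray] = None
    audit: dict = field(default_factory=dict)


def _subgroup_mask(records, name: str) -> np.ndarray:
    """Test-subset mask: all controls plus the named patient subgroup."""
    def flag(r: SubjectRecord) -> bool:
        if r.group == "HC":
            return True
        if name == "lesional":
            return r.lesional is True
        if name == "non_lesional":
            return r.lesional is False
        if name == "seizure_free":
            return r.seizure_free is True
        if name == "non_seizure_free":
            return r.seizure_free is False
        raise KeyError(name)

    return np.array([flag(r) for r in records], dtype=bool)


def evaluate_on_test(
    params: OptimalParams,
    train_val: LabeledDataset,
    test: LabeledDataset,
    family: str = "cnn",
    smote_config: Optional[SmoteConfig] = None,
    seed: int = 0,
    retrain: bool = True,
    winning_model: Optional[TrainedModel] = None,
) -> RepeatOutcome:
    """Step 4: construct the optimal model and measure it on the test split.

    With ``retrain`` (default) the model is retrained on the full, balanced
    training+validation set; otherwise the supplied winning fold model is
    reused.  Test samples never enter SMOTE or training.  Metrics on an empty
    or single-class subset come back as NaN with the metric named in
    ``undefined`` — never silent zeros.
    """
    smote_config = smote_config or SmoteConfig()
    smote_parent_ids: set = set()
    if retrain:
        balanced, log = balance(train_val, replace(smote_config, seed=seed))
        smote_parent_ids.update(log.parent_subject_id)
        smote_parent_ids.update(log.neighbour_subject_id)
        cfg = replace(params.cfg, seed=seed)
        model = _make_classifier(family, params.spec, train_val.images[0].shape).fit(
            balanced, None, cfg
        )
    else:
        if winning_model is None:
            raise ConfigurationError("retrain=False requires a winning_model")
        model = winning_model

    scores = model.predict_scores(test)
    y_true = test.labels
    y_pred = (scores >= 0.5).astype(int)
    cm = ConfusionMatrix.from_predictions(y_true, y_pred)
    metrics = MetricsSummary.compute(cm, y_true, scores)

    subgroup_metrics: Dict[str, MetricsSummary] = {}
    has_flags = any(r.lesional is not None for r in test.records)
    if has_flags:
        for name in SUBGROUP_NAMES:
            mask = _subgroup_mask(test.records, name)
            if np.sum(y_true[mask] == 1) == 0:
                continue  # subgroup absent from this test split
            sub_cm = ConfusionMatrix.from_predictions(y_true[mask], y_pred[mask])
            subgroup_metrics[name] = MetricsSummary.compute(sub_cm, y_true[mask], scores[mask])

    audit = {
        "test_ids": set(test.subject_ids),
        "train_ids": set(model.train_subject_ids),
        "smote_parent_ids": smote_parent_ids,
    }
    return RepeatOutcome(
        confusion=cm,
        metrics=metrics,
        subgroup_metrics=subgroup_metrics,
        model=model,
        scores=scores,
        audit=audit,
    )


# --------------------------------------------------------------------------
# repeated protocol and permutation null
# --------------------------------------------------------------------------

@dataclass
class StudyResults:
    """Results object for a repeated run: distributions, confusions, audit."""

    kind: str  # "correct" or "null"
    family: str
    confusions: List[ConfusionMatrix]
    metrics: MetricDistribution
    subgroup_metrics: Dict[str, MetricDistribution]
    optimal_params: List[OptimalParams]
    audit: List[dict]
    seed: int

    def p_values(self, null: "StudyResults") -> Dict[str, float]:
        """Per-metric significance of this (correct) run against a null run."""
        return {
            m: p_value(self.metrics.mean(m), [v for v in null.metrics.values[m]
                                              if np.isfinite(v)])
            for m in METRIC_NAMES
        }

    def summary(self, null: Optional["StudyResults"] = None) -> str:
        label = "correctly trained" if self.kind == "correct" else "permuted-label (null)"
        lines = [
            f"{self.family.upper()} {label} model — {len(self.metrics)} repeats",
            f"{'metric':<8}{'mean':>8}{'sd':>8}" + ("{:>10}".format("p") if null else ""),
        ]
        pvals = self.p_values(null) if null else {}
        for m in METRIC_NAMES:
            row = f"{m.upper():<8}{self.metrics.mean(m):>8.3f}{self.metrics.sd(m):>8.3f}"
            if null:
                row += f"{pvals[m]:>10.4f}"
            lines.append(row)
        for name, dist in self.subgroup_metrics.items():
            if len(dist):
                lines.append(
                    f"  {name}: ACC {dist.mean('acc'):.3f} ± {dist.sd('acc'):.3f} "
                    f"(n={len(dist)})"
                )
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "kind": self.kind,
            "family": self.family,
            "seed": self.seed,
            "repeats": len(self.metrics),
            "confusions": [
                {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn} for c in self.confusions
            ],
            "metrics": {
                m: {
                    "values": self.metrics.values[m],
                    "mean": self.metrics.mean(m),
                    "sd": self.metrics.sd(m),
                    "n_undefined": self.metrics.n_undefined(m),
                }
                for m in METRIC_NAMES
            },
            "subgroups": {
                name: {
                    m: {"mean": dist.mean(m), "sd": dist.sd(m), "n": len(dist)}
                    for m in METRIC_NAMES
                }
                for name, dist in self.subgroup_metrics.items()
                if len(dist)
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _permute_labels(dataset: LabeledDataset, rng: np.random.Generator) -> LabeledDataset:
    """Random reassignment of group labels (image-label pairing broken)."""
    perm = rng.permutation(len(dataset))
    groups = [dataset.records[i].group for i in perm]
    records = [
        SubjectRecord(subject_id=r.subject_id, group=g, site=r.site)
        for r, g in zip(dataset.records, groups)
    ]
    return LabeledDataset(images=list(dataset.images), records=records)


def run_protocol(
    dataset: LabeledDataset,
    grid: HyperGrid,
    family: str = "cnn",
    repeats: int = 20,
    seed: int = 0,
    test_fraction: float = 0.2,
    k: int = 10,
    smote_config: Optional[SmoteConfig] = None,
    retrain: bool = True,
) -> StudyResults:
    """Run the full steps-1-to-4 pipeline ``repeats`` times."""
    if repeats < 1:
        raise ConfigurationError("repeats must be >= 1")
    metrics = MetricDistribution()
    subgroup_dists: Dict[str, MetricDistribution] = {
        n: MetricDistribution() for n in SUBGROUP_NAMES
    }
    confusions: List[ConfusionMatrix] = []
    optima: List[OptimalParams] = []
    audit: List[dict] = []
    for i in range(repeats):
        rng = np.random.default_rng([seed, 0, i])
        train_val, test = stratified_split(dataset, test_fraction, rng)
        gs = grid_search(train_val, grid, family, k, rng, smote_config)
        outcome = evaluate_on_test(
            gs.optimal,
            train_val,
            test,
            family=family,
            smote_config=smote_config,
            seed=int(rng.integers(2**31)),
            retrain=retrain,
            winning_model=gs.winning_model,
        )
        outcome.audit["smote_parent_ids"] |= gs.smote_parent_ids
        confusions.append(outcome.confusion)
        metrics.add(outcome.metrics)
        for name, summary in outcome.subgroup_metrics.items():
            subgroup_dists[name].add(summary)
        optima.append(gs.optimal)
        audit.append(outcome.audit)
    return StudyResults(
        kind="correct",
        family=family,
        confusions=confusions,
        metrics=metrics,
        subgroup_metrics={n: d for n, d in subgroup_dists.items() if len(d)},
        optimal_params=optima,
        audit=audit,
        seed=seed,
    )


def run_permutation_null(
    dataset: LabeledDataset,
    optimal: OptimalParams,
    family: str = "cnn",
    repeats: int = 50,
    seed: int = 0,
    test_fraction: float = 0.2,
    k: int = 10,
    smote_config: Optional[SmoteConfig] = None,
) -> StudyResults:
    """Permuted-label null distribution at fixed (optimal) parameters.

    Per repeat: re-draw the stratified split, permute the train+validation
    labels, run a 10-fold stratified CV at the supplied parameters (SMOTE on
    each fold's training portion, no grid search), select the best random
    fold model by validation accuracy, and evaluate it on the test split with
    its true labels.
    """
    if repeats < 1:
        raise ConfigurationError("repeats must be >= 1")
    smote_config = smote_config or SmoteConfig()
    metrics = MetricDistribution()
    confusions: List[ConfusionMatrix] = []
    audit: List[dict] = []
    input_shape = dataset.images[0].shape
    for i in range(repeats):
        rng = np.random.default_rng([seed, 1, i])
        train_val, test = stratified_split(dataset, test_fraction, rng)
        permuted = _permute_labels(train_val, rng)
        labels = permuted.labels
        fold_seed = int(rng.integers(2**31))
        base_seed = int(rng.integers(2**31))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        best_model = None
        best_acc = -1.0
        smote_parent_ids: set = set()
        for fold_i, (tr_idx, va_idx) in enumerate(
            skf.split(np.zeros(len(permuted)), labels)
        ):
            seed_f = (base_seed + fold_i) % (2**31)
            fold_train = permuted.subset(tr_idx)
            fold_val = permuted.subset(va_idx)
            balanced, log = balance(fold_train, replace(smote_config, seed=seed_f))
            smote_parent_ids.update(log.parent_subject_id)
            cfg = replace(optimal.cfg, seed=seed_f)
            model = _make_classifier(family, optimal.spec, input_shape).fit(
                balanced, fold_val, cfg
            )
            acc = float(np.mean(model.predict_labels(fold_val) == fold_val.labels))
            if acc > best_acc:
                best_acc = acc
                best_model = model
        scores = best_model.predict_scores(test)
        y_true = test.labels
        y_pred = (scores >= 0.5).astype(int)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred)
        metrics.add(MetricsSummary.compute(cm, y_true, scores))
        confusions.append(cm)
        audit.append(
            {
                "test_ids": set(test.subject_ids),
                "train_ids": set(best_model.train_subject_ids),
                "smote_parent_ids": smote_parent_ids,
            }
        )
    return StudyResults(
        kind="null",
        family=family,
        confusions=confusions,
        metrics=metrics,
        subgroup_metrics={},
        optimal_params=[optimal] * repeats,
        audit=audit,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Model/Results facade
# --------------------------------------------------------------------------

class StudyProtocol:
    """Model-style wrapper: a cohort plus an evaluation configuration.

    ``fit`` runs the correctly-labelled repeated pipeline; ``fit_null`` runs
    the permuted-label counterpart at fixed parameters.  Both return
    :class:`StudyResults`.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        grid: Optional[HyperGrid] = None,
        family: str = "cnn",
        smote_config: Optional[SmoteConfig] = None,
        test_fraction: float = 0.2,
        n_folds: int = 10,
        retrain: bool = True,
    ):
        dataset.require_two_classes()
        if family not in ("cnn", "dag"):
            raise ConfigurationError(f"unknown model family {family!r}")
        self.dataset = dataset
        self.grid = grid or HyperGrid()
        self.family = family
        self.smote_config = smote_config or SmoteConfig()
        self.test_fraction = test_fraction
        self.n_folds = n_folds
        self.retrain = retrain

    def fit(self, repeats: int = 20, seed: int = 0) -> StudyResults:
        return run_protocol(
            self.dataset,
            self.grid,
            family=self.family,
            repeats=repeats,
            seed=seed,
            test_fraction=self.test_fraction,
            k=self.n_folds,
            smote_config=self.smote_config,
            retrain=self.retrain,
        )

    def fit_null(self, optimal: OptimalParams, repeats: int = 50, seed: int = 0) -> StudyResults:
        return run_permutation_null(
            self.dataset,
            optimal,
            family=self.family,
            repeats=repeats,
            seed=seed,
            test_fraction=self.test_fraction,
            k=self.n_folds,
            smote_config=self.smote_config,
        )
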