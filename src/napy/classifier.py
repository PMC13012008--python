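"""Nested cross-validated linear SVM classification of NAPY subtypes.

The classifier is a one-vs-rest linear soft-margin SVM over the 4 x k
(default 80) downstream-program genes, trained on gene-wise z-scores whose
scaling parameters are fitted on the training samples only and frozen into
the model.  Feature selection (program derivation) and the cost
hyperparameter are tuned inside a nested CV: outer 4-fold CV repeated on 5
random splits (20 runs), inner 3-fold CV selecting the cost from a log2
grid by mean macro balanced accuracy.  Programs and scaling are re-derived
on each outer-training part so no test-sample information leaks into
feature selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import LinearSVC

from .errors import ContractError, DomainError, InsufficientDataError, MissingGeneError
from .expression import (
    ExpressionMatrix,
    GeneScalingParams,
    apply_gene_scaling,
    fit_gene_scaling,
)
from .labeling import SUBTYPES, SubtypeCall
from .programs import DerivationConfig, TFProgram, derive_programs, program_feature_genes

DEFAULT_COST_GRID = tuple(float(2.0**e) for e in range(-10, 6))


@dataclass
class TrainingConfig:
    outer_folds: int = 4
    outer_repeats: int = 5
    inner_folds: int = 3
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    final_cost: float = 0.031
    holdout_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.holdout_fraction < 1):
            raise DomainError("holdout_fraction must be in (0, 1)")
        if any(c <= 0 for c in self.cost_grid) or self.final_cost <= 0:
            raise DomainError("costs must be positive")

    @property
    def n_runs(self) -> int:
        return self.outer_folds * self.outer_repeats


@dataclass
class ClassifierModel:
    """Self-contained linear one-vs-rest model.

    Stores the feature gene list, the training-set scaling parameters, and
    per-class weight vectors/intercepts.  Prediction is the argmax of the
    per-class decision values with ties broken by ``class_order``.
    """

    feature_genes: list[str]
    scaling: GeneScalingParams
    class_weights: np.ndarray      # (4, n_features)
    intercepts: np.ndarray         # (4,)
    cost: float
    class_order: tuple[str, ...] = SUBTYPES

    def decision_values(self, m: ExpressionMatrix) -> pd.DataFrame:
        missing = [g for g in self.feature_genes if g not in m.values.index]
        if missing:
            raise MissingGeneError(f"feature genes absent from matrix: {missing}")
        z = apply_gene_scaling(m.subset_genes(self.feature_genes), self.scaling)
        X = z.values.to_numpy(dtype=float).T  # samples x features
        D = X @ self.class_weights.T + self.intercepts
        return pd.DataFrame(D, index=m.sample_ids, columns=list(self.class_order))

    def to_json(self) -> str:
        doc = {
            "format": "napy-classifier",
            "class_order": list(self.class_order),
            "cost": self.cost,
            "feature_genes": self.feature_genes,
            "scaling": {
                "mean": self.scaling.mean.loc[self.feature_genes].tolist(),
                "sd": self.scaling.sd.loc[self.feature_genes].tolist(),
            },
            "class_weights": self.class_weights.tolist(),
            "intercepts": self.intercepts.tolist(),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        doc = json.loads(text)
        genes = doc["feature_genes"]
        scaling = GeneScalingParams(
            mean=pd.Series(doc["scaling"]["mean"], index=genes),
            sd=pd.Series(doc["scaling"]["sd"], index=genes),
        )
        return cls(genes, scaling, np.asarray(doc["class_weights"], float),
                   np.asarray(doc["intercepts"], float), float(doc["cost"]),
                   tuple(doc["class_order"]))


@dataclass
class PerformanceReport:
    """Confusion matrix plus one-vs-rest per-class and macro metrics."""

    confusion: pd.DataFrame        # truth x predicted
    per_class: pd.DataFrame        # metric columns per class row
    macro: dict[str, float]
    accuracy: float


def stratified_split(labels: pd.Series, fraction: float, seed: int):
    """Class-stratified train/holdout split of sample IDs (holdout=fraction)."""
    if not (0 < fraction < 1):
        raise ContractError("fraction must be in (0, 1)")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ContractError(f"classes with < 2 samples: {small.index.tolist()}")
    train, hold = train_test_split(
        labels.index.to_numpy(), test_size=fraction, stratify=labels.to_numpy(),
        random_state=seed, shuffle=True,
    )
    return list(train), list(hold)


def _labels_series(labels) -> pd.Series:
    if isinstance(labels, pd.Series):
        return labels
    if isinstance(labels, dict):
        return pd.Series(labels)
    if labels and isinstance(labels[0], SubtypeCall):
        return pd.Series({c.sample_id: c.label for c in labels})
    raise ContractError("labels must be a Series, dict, or list of SubtypeCall")


def train_model(m: ExpressionMatrix, labels, programs: dict[str, TFProgram],
                cost: float, class_order: tuple[str, ...] = SUBTYPES) -> ClassifierModel:
    """Fit the one-vs-rest linear SVM on the given training samples.

    Per-gene z-scaling is fitted on these samples only and frozen into the
    returned model.
    """
    y = _labels_series(labels).loc[m.sample_ids]
    missing_classes = [c for c in class_order if c not in set(y)]
    if missing_classes:
        raise ContractError(f"classes absent from training labels: {missing_classes}")
    genes = program_feature_genes(programs)
    sub = m.subset_genes(genes)
    scaling = fit_gene_scaling(sub)
    X = apply_gene_scaling(sub, scaling).values.to_numpy(dtype=float).T
    W = np.zeros((len(class_order), X.shape[1]))
    b = np.zeros(len(class_order))
    for i, cls in enumerate(class_order):
        ybin = np.where(y.to_numpy() == cls, 1, -1)
        svm = LinearSVC(C=cost, loss="squared_hinge", dual=False, tol=1e-6,
                        max_iter=100_000)
        svm.fit(X, ybin)
        sign = 1.0 if svm.classes_[1] == 1 else -1.0
        W[i] = sign * svm.coef_[0]
        b[i] = sign * svm.intercept_[0]
    return ClassifierModel(genes, scaling, W, b, cost, tuple(class_order))


def predict(model: ClassifierModel, m: ExpressionMatrix) -> list[SubtypeCall]:
    """Argmax-decision subtype calls (provenance ``ml``); never unassigned."""
    D = model.decision_values(m)
    arr = D.to_numpy()
    best = arr.argmax(axis=1)  # first max on ties = class order
    return [SubtypeCall(s, model.class_order[best[i]], "ml")
            for i, s in enumerate(D.index)]


def predict_series(model: ClassifierModel, m: ExpressionMatrix) -> pd.Series:
    return pd.Series({c.sample_id: c.label for c in predict(model, m)}, name="label")


def evaluate(pred, truth, class_order: tuple[str, ...] = SUBTYPES) -> PerformanceReport:
    """One-vs-rest per-class metrics and unweighted macro averages.

    Undefined ratios (0/0) are reported as NaN and excluded from the macro
    mean with a warning.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ContractError("pred and truth must have equal length")
    k = len(class_order)
    idx = {c: i for i, c in enumerate(class_order)}
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, pred):
        conf[idx[t], idx[p]] += 1
    total = conf.sum()
    rows = {}
    for i, cls in enumerate(class_order):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = total - tp - fn - fp

        def ratio(num, den):
            return num / den if den > 0 else np.nan

        sens = ratio(tp, tp + fn)
        spec = ratio(tn, tn + fp)
        ppv = ratio(tp, tp + fp)
        npv = ratio(tn, tn + fn)
        f = (2 * ppv * sens / (ppv + sens)
             if np.isfinite(ppv) and np.isfinite(sens) and (ppv + sens) > 0
             else np.nan)
        bal = (sens + spec) / 2
        rows[cls] = {"sensitivity": sens, "specificity": spec, "ppv": ppv,
                     "npv": npv, "f_measure": f, "balanced_accuracy": bal}
    per_class = pd.DataFrame(rows).T
    if per_class.isna().to_numpy().any():
        warnings.warn("undefined (0/0) per-class metrics excluded from macro means",
                      stacklevel=2)
    macro = per_class.mean(axis=0, skipna=True).to_dict()
    confusion = pd.DataFrame(conf, index=list(class_order), columns=list(class_order))
    accuracy = float(np.trace(conf) / total) if total else np.nan
    return PerformanceReport(confusion, per_class, macro, accuracy)


@dataclass
class CVRun:
    repeat: int
    fold: int
    programs: dict[str, TFProgram]
    best_cost: float
    report: PerformanceReport
    test_ids: list[str] = field(default_factory=list)


@dataclass
class NestedCVResult:
    runs: list[CVRun]
    pooled: PerformanceReport      # over all outer-fold predictions
    mean_macro_balanced_accuracy: float

    def best_run(self) -> CVRun:
        """Run with maximal outer macro balanced accuracy; ties -> lowest index."""
        scores = [r.report.macro["balanced_accuracy"] for r in self.runs]
        return self.runs[int(np.argmax(scores))]


def _inner_select_cost(m: ExpressionMatrix, y: pd.Series, programs,
                       cfg: TrainingConfig, rng_seed: int,
                       class_order) -> float:
    """Mean macro balanced accuracy over inner folds, per candidate cost."""
    skf = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True,
                          random_state=rng_seed)
    ids = np.asarray(m.sample_ids)
    folds = list(skf.split(ids, y.loc[ids].to_numpy()))
    scores = np.zeros(len(cfg.cost_grid))
    for tr, te in folds:
        m_tr = m.subset_samples(ids[tr])
        m_te = m.subset_samples(ids[te])
        y_tr, y_te = y.loc[ids[tr]], y.loc[ids[te]]
        for ci, cost in enumerate(cfg.cost_grid):
            model = train_model(m_tr, y_tr, programs, cost, class_order)
            rep = evaluate(predict_series(model, m_te).to_numpy(),
                           y_te.to_numpy(), class_order)
            scores[ci] += rep.macro["balanced_accuracy"]
    return float(cfg.cost_grid[int(np.argmax(scores))])  # first max on ties


def nested_cv(m: ExpressionMatrix, labels, derivation_cfg: DerivationConfig,
              training_cfg: TrainingConfig, tf_genes=None,
              class_order: tuple[str, ...] = SUBTYPES) -> NestedCVResult:
    """Outer-repeats x outer-folds nested CV with in-fold feature selection.

    Programs and scaling are derived on each outer-training part only; the
    inner CV selects the cost; the refit model is scored on the outer test
    fold.  The pooled report concatenates all outer-fold predictions.
    """
    from .labeling import LabelingConfig

    tf_genes = tuple(tf_genes) if tf_genes else LabelingConfig().tf_genes
    y = _labels_series(labels)
    ids_all = [s for s in m.sample_ids if s in y.index]
    y = y.loc[ids_all]
    bad = set(y) - set(class_order)
    if bad:
        raise ContractError(f"labels outside class universe: {sorted(bad)}")
    m = m.subset_samples(ids_all)
    ids = np.asarray(ids_all)
    runs: list[CVRun] = []
    pooled_pred: list[str] = []
    pooled_truth: list[str] = []
    for rep_i in range(training_cfg.outer_repeats):
        folds = None
        for attempt in range(5):
            seed = training_cfg.seed + 1000 * rep_i + attempt
            skf = StratifiedKFold(n_splits=training_cfg.outer_folds,
                                  shuffle=True, random_state=seed)
            cand = list(skf.split(ids, y.to_numpy()))
            if all(len(set(y.iloc[tr])) == len(class_order) for tr, _ in cand):
                folds = cand
                break
            warnings.warn(f"repeat {rep_i}: fold missing a class, re-drawing",
                          stacklevel=2)
        if folds is None:
            raise InsufficientDataError(
                "could not draw outer folds containing every class")
        for fold_i, (tr, te) in enumerate(folds):
            m_tr = m.subset_samples(ids[tr])
            m_te = m.subset_samples(ids[te])
            programs = derive_programs(m_tr, tf_genes, derivation_cfg)
            best_cost = _inner_select_cost(
                m_tr, y, programs, training_cfg,
                rng_seed=training_cfg.seed + 1000 * rep_i + 10 * fold_i,
                class_order=class_order)
            model = train_model(m_tr, y.loc[ids[tr]], programs, best_cost,
                                class_order)
            pred = predict_series(model, m_te)
            report = evaluate(pred.to_numpy(), y.loc[ids[te]].to_numpy(),
                              class_order)
            runs.append(CVRun(rep_i, fold_i, programs, best_cost, report,
                              list(ids[te])))
            pooled_pred.extend(pred.to_numpy())
            pooled_truth.extend(y.loc[ids[te]].to_numpy())
    pooled = evaluate(np.asarray(pooled_pred), np.asarray(pooled_truth),
                      class_order)
    mean_bal = float(np.mean([r.report.macro["balanced_accuracy"] for r in runs]))
    return NestedCVResult(runs, pooled, mean_bal)


def fit_final_model(m: ExpressionMatrix, labels, cv_result: NestedCVResult,
                    cost: float | None = None,
                    class_order: tuple[str, ...] = SUBTYPES) -> ClassifierModel:
    """Refit on all training samples using the best run's feature group.

    ``cost`` defaults to the best run's inner-selected cost; pass the
    published final cost explicitly to reproduce a fixed model.
    """
    best = cv_result.best_run()
    return train_model(m, labels, best.programs,
                       cost if cost is not None else best.best_cost, class_order)
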