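"""Four-way stage classification and the full evaluation protocol.

Evaluation follows the method's protocol: per stage, samples split 30%
reference / 40% training / 30% test; reference samples define the
co-expression networks, training samples fit the classifier under
repeated stratified cross-validation (3 folds x 100 repeats by default),
and held-out test samples yield per-stage sensitivity and specificity,
overall accuracy and Cohen's kappa.  The whole procedure repeats over
independent splits (10 by default) and metrics are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .diffexpr import StageDEGSet, balance_deg_sets, identify_degs
from .io import CONTROL, STAGES, ExpressionMatrix, samples_by_group
from .perturbation import PerturbationFeaturizer

DEFAULT_FRACTIONS = (0.3, 0.4, 0.3)


# ---------------------------------------------------------------------------
# splitting

@dataclass
class SplitPlan:
    """Stage-stratified reference/training/test partition."""

    seed: int
    reference: dict[int, list[str]]
    training: dict[int, list[str]]
    test: dict[int, list[str]]

    def all_reference(self) -> list[str]:
        return [s for st in STAGES for s in self.reference[st]]

    def all_training(self) -> list[str]:
        return [s for st in STAGES for s in self.training[st]]

    def all_test(self) -> list[str]:
        return [s for st in STAGES for s in self.test[st]]


def split_samples(labels: Mapping[str, int | str],
                  fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
                  seed: int = 0) -> SplitPlan:
    """Stage-stratified split: floor(f*n) reference and test, rest training."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    groups = samples_by_group(labels)
    reference, training, test = {}, {}, {}
    for stage in STAGES:
        pool = groups[stage]
        n = len(pool)
        if n < 4:
            raise ValueError(
                f"stage {stage} has only {n} samples; need >=4 for a 3-way split"
            )
        n_ref = int(np.floor(fractions[0] * n))
        n_test = int(np.floor(fractions[2] * n))
        perm = [pool[i] for i in rng.permutation(n)]
        reference[stage] = sorted(perm[:n_ref])
        test[stage] = sorted(perm[n_ref:n_ref + n_test])
        training[stage] = sorted(perm[n_ref + n_test:])
    return SplitPlan(seed, reference, training, test)


# ---------------------------------------------------------------------------
# classifier backends

def _backend_registry(seed: int | None) -> dict[str, tuple[BaseEstimator, dict]]:
    """The six learners mapped onto scikit-learn equivalents.

    c50 -> gradient-boosted decision trees; treebag -> bagged trees;
    rf -> random forest; wsrf -> random forest drawing a larger random
    feature subspace per split; rferns -> extremely randomized shallow
    trees; nb -> Gaussian naive Bayes.  Each entry carries a small
    default hyperparameter grid searched by repeated CV.
    """
    return {
        "c50": (GradientBoostingClassifier(random_state=seed, max_features="sqrt"),
                {"n_estimators": [100], "max_depth": [3]}),
        "treebag": (BaggingClassifier(estimator=DecisionTreeClassifier(random_state=seed),
                                      random_state=seed),
                    {"n_estimators": [25]}),
        "rf": (RandomForestClassifier(random_state=seed),
               {"n_estimators": [200], "max_features": ["sqrt"]}),
        "wsrf": (RandomForestClassifier(random_state=seed),
                 {"n_estimators": [200], "max_features": [0.5]}),
        "rferns": (ExtraTreesClassifier(random_state=seed),
                   {"n_estimators": [200], "max_depth": [5]}),
        "nb": (GaussianNB(), {"var_smoothing": [1e-9]}),
    }


BACKENDS = tuple(_backend_registry(None))


class StageClassifier(BaseEstimator, ClassifierMixin):
    """Stage predictor over perturbation feature vectors.

    Wraps one backend of the registry; hyperparameters are selected by
    repeated stratified cross-validation maximizing accuracy, then the
    winning configuration is refit on all training data.

    Parameters
    ----------
    backend : registry name (``c50`` default, the headline learner).
    cv_folds, cv_repeats : cross-validation geometry (3 x 100 default).
    param_grid : overrides the backend's default grid when given.
    seed : controls fold assignment and any backend randomness.
    layout_checksum : optional digest of the feature layout the features
        were built under; ``predict`` refuses features built under a
        different layout.
    """

    def __init__(self, backend: str = "c50", cv_folds: int = 3,
                 cv_repeats: int = 100, param_grid: dict | None = None,
                 seed: int = 0, layout_checksum: str | None = None):
        self.backend = backend
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.param_grid = param_grid
        self.seed = seed
        self.layout_checksum = layout_checksum

    def fit(self, X, y, layout_checksum: str | None = None) -> "StageClassifier":
        registry = _backend_registry(self.seed)
        if self.backend not in registry:
            raise ValueError(f"unknown backend {self.backend!r}; "
                             f"choose from {sorted(registry)}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(set(y)) < 2:
            raise ValueError("training labels must span at least 2 stages")
        base, default_grid = registry[self.backend]
        grid = self.param_grid if self.param_grid is not None else default_grid
        cv = RepeatedStratifiedKFold(n_splits=self.cv_folds,
                                     n_repeats=self.cv_repeats,
                                     random_state=self.seed)
        search = GridSearchCV(clone(base), grid, scoring="accuracy", cv=cv,
                              refit=True, n_jobs=None)
        search.fit(X, y)
        self.model_ = search.best_estimator_
        self.best_params_ = search.best_params_
        self.cv_accuracy_ = float(search.best_score_)
        self.classes_ = search.best_estimator_.classes_
        self.layout_checksum_ = layout_checksum or self.layout_checksum
        return self

    def _check_layout(self, layout_checksum: str | None) -> None:
        stored = getattr(self, "layout_checksum_", None)
        if stored is not None and layout_checksum is not None and stored != layout_checksum:
            raise ValueError(
                "feature layout mismatch: features were built under a "
                "different network manifest than the model was trained on"
            )

    def predict(self, X, layout_checksum: str | None = None) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        self._check_layout(layout_checksum)
        return self.model_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvaluationReport:
    """Confusion matrix (rows = predicted, columns = annotated) and metrics."""

    confusion: np.ndarray
    sensitivity: dict[int, float]
    specificity: dict[int, float]
    accuracy: float
    kappa: float
    n_iterations: int = 1
    metric_sd: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion_predicted_by_annotated": self.confusion.tolist(),
            "sensitivity": {str(s): v for s, v in self.sensitivity.items()},
            "specificity": {str(s): v for s, v in self.specificity.items()},
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "n_iterations": self.n_iterations,
            "metric_sd": dict(self.metric_sd),
        }


def confusion_matrix_predicted_by_annotated(
        predicted, annotated, classes: tuple[int, ...] = STAGES) -> np.ndarray:
    """Count matrix with predictions on rows and annotations on columns."""
    idx = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for p, a in zip(predicted, annotated, strict=True):
        m[idx[int(p)], idx[int(a)]] += 1
    return m


def metrics_from_confusion(m: np.ndarray,
                           classes: tuple[int, ...] = STAGES) -> dict:
    """Per-class one-vs-rest sensitivity/specificity, accuracy, Cohen's kappa."""
    m = np.asarray(m, dtype=float)
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(m)
    col = m.sum(axis=0)  # annotated totals
    row = m.sum(axis=1)  # predicted totals
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(col > 0, tp / col, np.nan)
        fp = row - tp
        tn = total - row - col + tp
        spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
    accuracy = tp.sum() / total
    p_e = float((row * col).sum()) / total ** 2
    kappa = (accuracy - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    return {
        "sensitivity": {c: float(sens[i]) for i, c in enumerate(classes)},
        "specificity": {c: float(spec[i]) for i, c in enumerate(classes)},
        "accuracy": float(accuracy),
        "kappa": float(kappa),
    }


def evaluate(predictions: Mapping[str, int],
             truth: Mapping[str, int | str]) -> EvaluationReport:
    """Score sample-level predictions against annotated stages."""
    if not predictions:
        raise ValueError("empty prediction set")
    missing = [s for s in predictions if s not in truth]
    if missing:
        raise ValueError(f"predicted samples without truth labels: {missing[:5]}")
    pred = [predictions[s] for s in predictions]
    annot = [truth[s] for s in predictions]
    m = confusion_matrix_predicted_by_annotated(pred, annot)
    met = metrics_from_confusion(m)
    return EvaluationReport(confusion=m, sensitivity=met["sensitivity"],
                            specificity=met["specificity"],
                            accuracy=met["accuracy"], kappa=met["kappa"])


# ---------------------------------------------------------------------------
# full protocol

@dataclass
class ProtocolConfig:
    """Everything one evaluation run needs, with the method's defaults."""

    logfc_cut: float = 2.5
    p_cut: float = 0.05
    tau: float = 0.7
    network_p_cut: float = 0.05
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    backend: str = "c50"
    cv_folds: int = 3
    cv_repeats: int = 100
    param_grid: dict | None = None
    n_iterations: int = 10
    master_seed: int = 0
    strict_split: bool = False
    assume_counts: bool | None = None


def _iteration_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2 ** 31 - 1) for s in ss.generate_state(n)]


def run_iteration(expr: ExpressionMatrix, labels: Mapping[str, int | str],
                  config: ProtocolConfig, seed: int) -> tuple[EvaluationReport, dict]:
    """One split -> DEG -> network -> feature -> train -> test pass."""
    plan = split_samples(labels, config.fractions, seed)
    groups = samples_by_group(labels)

    if config.strict_split:
        visible = {st: plan.reference[st] + plan.training[st] for st in STAGES}
        deg_pool = {st: visible[st] + groups[CONTROL] for st in STAGES}
    else:
        visible = {st: groups[st] for st in STAGES}
        deg_pool = {st: None for st in STAGES}

    per_stage = {}
    for stage in STAGES:
        records = identify_degs(expr, labels, stage,
                                logfc_cut=config.logfc_cut, p_cut=config.p_cut,
                                samples=deg_pool[stage],
                                assume_counts=config.assume_counts)
        per_stage[stage] = StageDEGSet(stage, records)
    balanced = balance_deg_sets(per_stage, expr, labels,
                                variance_samples=visible,
                                assume_counts=config.assume_counts)
    stage_genes = {st: balanced[st].selected_genes for st in STAGES}

    def frame(samples: list[str]) -> pd.DataFrame:
        return expr.subset(samples=samples).to_frame().T

    ref_samples = plan.all_reference()
    ref_y = [labels[s] for s in ref_samples]
    featurizer = PerturbationFeaturizer(stage_genes=stage_genes, tau=config.tau,
                                        p_cut=config.network_p_cut,
                                        assume_counts=config.assume_counts)
    featurizer.fit(frame(ref_samples), ref_y)

    train_samples = plan.all_training()
    test_samples = plan.all_test()
    X_train = featurizer.transform(frame(train_samples))
    X_test = featurizer.transform(frame(test_samples))
    y_train = np.array([int(labels[s]) for s in train_samples])

    clf = StageClassifier(backend=config.backend, cv_folds=config.cv_folds,
                          cv_repeats=config.cv_repeats,
                          param_grid=config.param_grid, seed=seed)
    clf.fit(X_train, y_train, layout_checksum=featurizer.layout_.checksum())
    pred = clf.predict(X_test, layout_checksum=featurizer.layout_.checksum())

    report = evaluate(dict(zip(test_samples, (int(p) for p in pred))),
                      {s: labels[s] for s in test_samples})
    details = {"split": plan, "stage_genes": stage_genes,
               "n_features": featurizer.n_features_out_,
               "cv_accuracy": clf.cv_accuracy_}
    return report, details


def average_reports(reports: list[EvaluationReport]) -> EvaluationReport:
    """Mean metrics (with SDs) over iterations; confusion counts pooled."""
    if not reports:
        raise ValueError("no reports to average")
    acc = np.array([r.accuracy for r in reports])
    kap = np.array([r.kappa for r in reports])
    sens = {s: np.nanmean([r.sensitivity[s] for r in reports]) for s in STAGES}
    spec = {s: np.nanmean([r.specificity[s] for r in reports]) for s in STAGES}
    pooled = np.sum([r.confusion for r in reports], axis=0)
    sd = {"accuracy": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
          "kappa": float(kap.std(ddof=1)) if len(kap) > 1 else 0.0}
    return EvaluationReport(confusion=pooled,
                            sensitivity={s: float(v) for s, v in sens.items()},
                            specificity={s: float(v) for s, v in spec.items()},
                            accuracy=float(acc.mean()), kappa=float(kap.mean()),
                            n_iterations=len(reports), metric_sd=sd)


def run_protocol(expr: ExpressionMatrix, labels: Mapping[str, int | str],
                 config: ProtocolConfig | None = None) -> EvaluationReport:
    """Repeat the full pipeline over independent splits and average."""
    config = config or ProtocolConfig()
    seeds = _iteration_seeds(config.master_seed, config.n_iterations)
    reports = [run_iteration(expr, labels, config, s)[0] for s in seeds]
    return average_reports(reports)
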