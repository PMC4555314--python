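"""Prognosis benchmark: predict the next qualifier of a target ICF category.

The clinical decision support task is multiclass classification of the
qualifier (5 classes, 0–4) a person will show for a target category
(e.g. emotional functions b152, executive functions b164) at their last
evaluation year, from demographics plus earlier ICF measurements.

Eligibility: only people with at least three years of measurements and a
non-empty (ordered) target value in the label year enter the benchmark —
the last measurement is what validates the prediction.

Two temporal feature representations are compared:

* *full time-series* — one feature per (ICF code, predictor year) pair
  over all years before the label year;
* *previous state* — one feature per code: its most recent ordered
  value before the label year.

Four learner families are benchmarked: k-nearest neighbours (k = 7),
naive Bayes, a support-vector machine, and a C4.5-style decision tree.
Evaluation uses stratified k-fold cross-validation with a fixed seed;
missing features are imputed inside training folds only.  Metrics are
the four confusion-matrix ratios

    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)

computed one-vs-rest per class and support-weighted across classes
(support-weighted recall then coincides with overall accuracy).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .monitor import PersonProfile

__all__ = [
    "CohortSpec",
    "FeatureMatrix",
    "ConfusionMatrix",
    "BenchmarkReport",
    "select_cohort",
    "features_full_series",
    "features_previous_state",
    "evaluate",
    "binary_metrics",
    "default_learners",
    "benchmark",
    "attribute_importance",
]

DEMOGRAPHIC_NUMERIC = ("age", "years_from_diagnosis")
DEMOGRAPHIC_CATEGORICAL = ("gender", "disease", "origin")
METRIC_COLUMNS = ("accuracy", "precision", "recall", "specificity")


@dataclass(frozen=True)
class CohortSpec:
    """Target category, label year and eligibility threshold for one benchmark."""

    target_code: str
    label_year: int
    min_series_length: int = 3

    def __post_init__(self) -> None:
        if self.min_series_length < 2:
            raise ValueError("min_series_length must be >= 2 (label + >=1 predictor year)")


def select_cohort(
    cohort: Sequence[PersonProfile], spec: CohortSpec
) -> list[PersonProfile]:
    """Eligibility filter: >= min distinct measurement years AND an ordered
    target value in the label year."""
    out = []
    for p in cohort:
        if p.series_length < spec.min_series_length:
            continue
        if p.ordered_value(spec.target_code, spec.label_year) is None:
            continue
        out.append(p)
    return out


@dataclass
class FeatureMatrix:
    """Design matrix for one temporal representation.

    ``X`` is indexed by person id; demographic columns come first, then
    the temporal block.  Missing temporal cells (never measured, or
    sentinel 8/9) are NaN.  ``y`` holds the target qualifier (0–4).
    """

    X: pd.DataFrame
    y: pd.Series
    representation: str
    spec: CohortSpec
    categorical: tuple[str, ...] = DEMOGRAPHIC_CATEGORICAL
    temporal: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.y.isna().any():
            raise ValueError("feature matrix has rows with a missing label")

    @property
    def numeric(self) -> tuple[str, ...]:
        return tuple(c for c in self.X.columns if c not in self.categorical)

    @property
    def n_classes(self) -> int:
        return int(self.y.nunique())


def _demographics(profiles: Sequence[PersonProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": [p.age for p in profiles],
            "gender": [p.gender for p in profiles],
            "years_from_diagnosis": [p.years_from_diagnosis for p in profiles],
            "disease": [p.disease for p in profiles],
            "origin": [p.origin for p in profiles],
        },
        index=pd.Index([p.person_id for p in profiles], name="person_id"),
    )


def _labels(profiles: Sequence[PersonProfile], spec: CohortSpec) -> pd.Series:
    vals = [p.ordered_value(spec.target_code, spec.label_year) for p in profiles]
    if any(v is None for v in vals):
        raise ValueError("a profile lacks an ordered label-year target value; "
                         "run select_cohort first")
    return pd.Series(
        vals, index=[p.person_id for p in profiles], name=spec.target_code, dtype=int
    )


def _codes_in_scope(profiles: Sequence[PersonProfile], spec: CohortSpec) -> list[str]:
    """All ICF codes with an ordered value in >=1 profile in a predictor year."""
    codes: set[str] = set()
    for p in profiles:
        for year, snap in p.snapshots.items():
            if year >= spec.label_year:
                continue
            codes.update(
                c for c in snap.codes() if snap.ordered_value(c) is not None
            )
    return sorted(codes)


def features_full_series(
    profiles: Sequence[PersonProfile], spec: CohortSpec
) -> FeatureMatrix:
    """Full time-series representation: one column per (code, predictor year)."""
    if not profiles:
        raise ValueError("empty cohort; nothing to featurize")
    codes = _codes_in_scope(profiles, spec)
    years = sorted(
        {y for p in profiles for y in p.years if y < spec.label_year}
    )
    X = _demographics(profiles)
    temporal = []
    for code in codes:
        for year in years:
            vals = [
                np.nan if (v := p.ordered_value(code, year)) is None else float(v)
                for p in profiles
            ]
            if all(np.isnan(v) for v in vals):
                continue  # no eligible profile carries this code that year
            col = f"{code} {year}"
            temporal.append(col)
            X[col] = vals
    return FeatureMatrix(
        X=X, y=_labels(profiles, spec), representation="full time-series",
        spec=spec, temporal=tuple(temporal),
    )


def features_previous_state(
    profiles: Sequence[PersonProfile], spec: CohortSpec
) -> FeatureMatrix:
    """Previous-state representation: per code, the most recent ordered value
    before the label year (NaN if there is none)."""
    if not profiles:
        raise ValueError("empty cohort; nothing to featurize")
    codes = _codes_in_scope(profiles, spec)
    X = _demographics(profiles)
    temporal = []
    for code in codes:
        col = f"{code} prev"
        temporal.append(col)
        vals = []
        for p in profiles:
            prev = None
            for year in p.years:
                if year >= spec.label_year:
                    break
                v = p.ordered_value(code, year)
                if v is not None:
                    prev = v
            vals.append(np.nan if prev is None else float(prev))
        X[col] = vals
    return FeatureMatrix(
        X=X, y=_labels(profiles, spec), representation="previous state",
        spec=spec, temporal=tuple(temporal),
    )


# ---------------------------------------------------------------------------
# confusion matrices and metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """A K×K count table; rows = true class, columns = predicted class."""

    labels: tuple[Any, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=int)
        k = len(self.labels)
        if self.table.shape != (k, k):
            raise ValueError("confusion table shape does not match labels")
        if (self.table < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[Any], y_pred: Sequence[Any],
        labels: Optional[Sequence[Any]] = None,
    ) -> "ConfusionMatrix":
        if labels is None:
            labels = sorted(set(y_true) | set(y_pred))
        table = _sk_confusion_matrix(y_true, y_pred, labels=list(labels))
        return cls(labels=tuple(labels), table=table)

    @classmethod
    def from_binary_counts(cls, tp: int, fp: int, fn: int, tn: int) -> "ConfusionMatrix":
        """2×2 table with the positive class first."""
        return cls(labels=("positive", "negative"),
                   table=np.array([[tp, fn], [fp, tn]]))

    @property
    def total(self) -> int:
        return int(self.table.sum())

    def support(self, label: Any) -> int:
        return int(self.table[self.labels.index(label)].sum())

    def counts_for(self, label: Any) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, FP, FN, TN) for one class."""
        i = self.labels.index(label)
        tp = int(self.table[i, i])
        fp = int(self.table[:, i].sum() - tp)
        fn = int(self.table[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def _ratio(num: float, den: float, what: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(what)
        return 0.0
    return num / den


def binary_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """The four confusion-matrix ratios for one (positive-class) cell set.

    A zero denominator yields 0 for that metric (flagged via a warning).
    """
    flags: list[str] = []
    out = {
        "accuracy": _ratio(tp + tn, tp + fp + fn + tn, "accuracy", flags),
        "precision": _ratio(tp, tp + fp, "precision", flags),
        "recall": _ratio(tp, tp + fn, "recall", flags),
        "specificity": _ratio(tn, tn + fp, "specificity", flags),
    }
    if flags:
        _warnings.warn(f"zero denominator in {flags}; metric(s) reported as 0")
    return out


def evaluate(
    cm: ConfusionMatrix,
    average: str = "weighted",
    positive_label: Any = None,
) -> dict[str, float]:
    """Accuracy, precision, recall and specificity from a confusion matrix.

    ``average='weighted'`` (default) computes the per-class one-vs-rest
    ratios and support-weights them; accuracy is the overall fraction of
    correct predictions (equal to support-weighted recall).
    ``average='macro'`` weights classes equally.  ``average='binary'``
    applies the formulas verbatim to the counts of ``positive_label``
    (2-class tables only).
    """
    if cm.total == 0:
        raise ValueError("cannot evaluate an empty confusion matrix")

    if average == "binary":
        if len(cm.labels) != 2:
            raise ValueError("binary averaging requires a 2-class table")
        label = positive_label if positive_label is not None else cm.labels[0]
        return binary_metrics(*cm.counts_for(label))

    if average not in ("weighted", "macro"):
        raise ValueError(f"unknown averaging {average!r}")

    per_class = []
    weights = []
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        for label in cm.labels:
            per_class.append(binary_metrics(*cm.counts_for(label)))
            weights.append(cm.support(label))
    w = np.asarray(weights, dtype=float)
    if average == "macro":
        w = np.ones_like(w)
    w = w / w.sum()

    out = {
        m: float(np.dot(w, [pc[m] for pc in per_class]))
        for m in ("precision", "recall", "specificity")
    }
    out["accuracy"] = float(np.trace(cm.table) / cm.total)
    return {m: out[m] for m in METRIC_COLUMNS}


# ---------------------------------------------------------------------------
# learners and benchmark
# ---------------------------------------------------------------------------


def default_learners(seed: int = 0, knn_k: int = 7) -> dict[str, Any]:
    """The benchmarked learner families with their default configurations.

    The decision tree plays the role of a C4.5-style learner; the SVM
    uses an RBF kernel.
    """
    return {
        f"KNN (k = {knn_k})": KNeighborsClassifier(n_neighbors=knn_k),
        "NB": GaussianNB(),
        "SVM": SVC(kernel="rbf", random_state=seed),
        "J48": DecisionTreeClassifier(random_state=seed),
    }


def _preprocessor(fm: FeatureMatrix, scale: bool = True) -> ColumnTransformer:
    """Impute + encode, fitted inside CV training folds only."""
    cat = [c for c in fm.categorical if c in fm.X.columns]
    num = [c for c in fm.X.columns if c not in cat]
    num_steps = [("impute", SimpleImputer(strategy="median"))]
    if scale:
        num_steps.append(("scale", StandardScaler()))
    return ColumnTransformer(
        [
            ("num", Pipeline(num_steps), num),
            (
                "cat",
                Pipeline(
                    [
                        ("impute", SimpleImputer(strategy="most_frequent")),
                        ("onehot", OneHotEncoder(handle_unknown="ignore",
                                                 sparse_output=False)),
                    ]
                ),
                cat,
            ),
        ]
    )


@dataclass
class BenchmarkReport:
    """Learner × representation metric table plus run metadata."""

    table: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)
    confusions: dict[tuple[str, str], ConfusionMatrix] = field(default_factory=dict)

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False, float_format="%.4f")


def benchmark(
    matrices: FeatureMatrix | Sequence[FeatureMatrix],
    learners: Optional[Mapping[str, Any]] = None,
    seed: int = 0,
    n_splits: int = 10,
    average: str = "weighted",
) -> BenchmarkReport:
    """Cross-validated benchmark over representations × learners.

    Stratified k-fold with shuffling under ``seed``; the fold count is
    reduced to the smallest class support when necessary (recorded in
    the metadata).  All learners of one representation share the same
    folds, so their confusion totals agree.  Deterministic given seed.
    """
    if isinstance(matrices, FeatureMatrix):
        matrices = [matrices]
    if learners is None:
        learners = default_learners(seed)

    rows = []
    confusions: dict[tuple[str, str], ConfusionMatrix] = {}
    effective_splits = {}
    for fm in matrices:
        counts = fm.y.value_counts()
        if len(counts) < 2:
            raise ValueError(
                f"representation {fm.representation!r} has a single label class; "
                "nothing to learn"
            )
        splits = int(min(n_splits, counts.min()))
        if splits < 2:
            raise ValueError(
                f"class {counts.idxmin()} has a single instance; "
                "stratified cross-validation impossible"
            )
        effective_splits[fm.representation] = splits
        cv = StratifiedKFold(n_splits=splits, shuffle=True, random_state=seed)
        labels = sorted(fm.y.unique())
        for name, learner in learners.items():
            pipe = Pipeline(
                [("prep", _preprocessor(fm)), ("learner", learner)]
            )
            y_pred = cross_val_predict(pipe, fm.X, fm.y, cv=cv)
            cm = ConfusionMatrix.from_predictions(fm.y, y_pred, labels=labels)
            confusions[(fm.representation, name)] = cm
            metrics = evaluate(cm, average=average)
            rows.append(
                {"representation": fm.representation, "learner": name, **metrics}
            )

    table = pd.DataFrame(
        rows, columns=["representation", "learner", *METRIC_COLUMNS]
    )
    return BenchmarkReport(
        table=table,
        metadata={
            "seed": seed,
            "requested_splits": n_splits,
            "effective_splits": effective_splits,
            "averaging": average,
            "protocol": "stratified k-fold cross-validation",
        },
        confusions=confusions,
    )


def attribute_importance(
    fm: FeatureMatrix,
    seed: int = 0,
    top: int = 10,
    n_estimators: int = 300,
) -> list[tuple[str, float]]:
    """Rank features by impurity importance from a random-forest ensemble.

    One-hot encoded categorical columns are folded back onto their source
    feature.  The reported (at most ``top``) importances are rescaled to
    sum to 100%, descending.
    """
    prep = _preprocessor(fm, scale=False)
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    pipe = Pipeline([("prep", prep), ("forest", forest)])
    pipe.fit(fm.X, fm.y)

    names = pipe.named_steps["prep"].get_feature_names_out()
    importances = pipe.named_steps["forest"].feature_importances_
    agg: dict[str, float] = {}
    for name, imp in zip(names, importances):
        kind, _, rest = name.partition("__")
        if kind == "cat":
            # onehot names look like "<column>_<level>"
            source = next(c for c in fm.categorical if rest.startswith(c + "_"))
        else:
            source = rest
        agg[source] = agg.get(source, 0.0) + float(imp)

    ranked = sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    total = sum(v for _, v in ranked)
    if total <= 0:
        return [(k, 100.0 / len(ranked)) for k, _ in ranked]
    return [(k, 100.0 * v / total) for k, v in ranked]
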