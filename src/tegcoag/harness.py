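"""Benchmark the RFCBC against six standard binary classifiers.

All models see byte-identical stratified train/test splits (repeated k-fold),
and both cross-validated and resubstitution accuracy are reported — the
published comparison does not state which protocol produced its accuracy
figures, so the harness surfaces both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .rfcbc import RfcbcClassifier

__all__ = [
    "FEATURE_SETS",
    "BenchmarkReport",
    "default_models",
    "run_benchmark",
    "accuracy",
    "plot_benchmark",
]

#: Named feature sets: the TEG five items and the conventional nine-item panel.
FEATURE_SETS = {
    "teg_five": ["R", "K", "Angle", "MA", "CI"],
    "thromboelastogram_nine": [
        "PT", "INR", "PTA", "APTT", "FIB", "TT", "D_dimer", "FDP", "AT_III",
    ],
}


@dataclass(frozen=True)
class BenchmarkReport:
    feature_set: str
    cv_accuracy: dict  # model -> {"mean", "sd", "folds": [...]}
    resubstitution: dict  # model -> accuracy
    ranking: list  # model names sorted by CV mean, descending
    config: dict

    def __post_init__(self):
        means = [self.cv_accuracy[m]["mean"] for m in self.ranking]
        if any(means[i] < means[i + 1] - 1e-12 for i in range(len(means) - 1)):
            raise ValueError("ranking must be sorted descending by CV mean")

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "cv_accuracy": self.cv_accuracy,
            "resubstitution": self.resubstitution,
            "ranking": self.ranking,
            "config": self.config,
        }

    def fold_frame(self) -> pd.DataFrame:
        rows = []
        for model, d in self.cv_accuracy.items():
            for i, acc in enumerate(d["folds"]):
                rows.append({"model": model, "fold": i, "accuracy": acc})
        return pd.DataFrame(rows)


def accuracy(pred_labels, true_labels) -> float:
    """Fraction of exact label matches."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if len(pred) != len(true):
        raise ValueError("length mismatch")
    if len(pred) == 0:
        raise ValueError("empty label vectors")
    return float((pred == true).mean())


def default_models(seed: int = 0, rfcbc_max_epochs: int = 150) -> dict:
    """The six standard baselines (library defaults) plus the RFCBC."""
    return {
        "logistic_regression": LogisticRegression(max_iter=2000),
        "svm": SVC(),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "random_forest": RandomForestClassifier(random_state=seed),
        "knn": KNeighborsClassifier(),
        "naive_bayes": GaussianNB(),
        "rfcbc": RfcbcClassifier(seed=seed, max_epochs=rfcbc_max_epochs),
    }


def _clone(model):
    if isinstance(model, RfcbcClassifier):
        return RfcbcClassifier(**model.get_params())
    return clone(model)


def run_benchmark(df: pd.DataFrame, feature_set, target_label: str,
                  models: dict | None = None, cv_folds: int = 5,
                  repeats: int = 10, seed: int = 0) -> BenchmarkReport:
    """Uniform-protocol benchmark over one feature set.

    ``feature_set`` is a key of :data:`FEATURE_SETS` or an explicit variable
    list; ``target_label`` is a binary column of ``df``.  Fold assignments are
    generated once and shared by every model, so accuracy differences are
    attributable to the models alone.
    """
    if isinstance(feature_set, str):
        fs_name, variables = feature_set, FEATURE_SETS[feature_set]
    else:
        fs_name, variables = "custom", list(feature_set)
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    data = df.dropna(subset=variables + [target_label])
    X = data[variables].to_numpy(dtype=float)
    y_raw = data[target_label]
    classes = sorted(pd.unique(y_raw))
    if len(classes) != 2:
        raise ValueError(f"target {target_label!r} must be binary, got {classes}")
    y = (y_raw == classes[1]).to_numpy(dtype=int)
    if min((y == 0).sum(), (y == 1).sum()) < cv_folds:
        raise ValueError("smallest class has fewer members than cv_folds")

    models = models or default_models(seed=seed)
    splitter = RepeatedStratifiedKFold(
        n_splits=cv_folds, n_repeats=repeats, random_state=seed
    )
    splits = list(splitter.split(X, y))  # identical for every model

    cv_accuracy = {}
    resub = {}
    for name in models:
        model = models[name]
        fold_accs = []
        for train_idx, test_idx in splits:
            m = _clone(model)
            m.fit(X[train_idx], y[train_idx])
            fold_accs.append(accuracy(m.predict(X[test_idx]), y[test_idx]))
        fold_accs = np.asarray(fold_accs)
        cv_accuracy[name] = {
            "mean": float(fold_accs.mean()),
            "sd": float(fold_accs.std(ddof=1)) if len(fold_accs) > 1 else 0.0,
            "folds": fold_accs.tolist(),
        }
        m_full = _clone(model)
        m_full.fit(X, y)
        resub[name] = accuracy(m_full.predict(X), y)

    ranking = sorted(cv_accuracy, key=lambda k: -cv_accuracy[k]["mean"])
    config = {
        "cv_folds": cv_folds, "repeats": repeats, "seed": seed,
        "n": int(len(y)), "positive_class": str(classes[1]),
        "variables": variables,
        "model_settings": {
            name: {k: str(v) for k, v in _model_params(m).items()}
            for name, m in models.items()
        },
    }
    return BenchmarkReport(
        feature_set=fs_name, cv_accuracy=cv_accuracy,
        resubstitution=resub, ranking=ranking, config=config,
    )


def _model_params(model) -> dict:
    try:
        return model.get_params()
    except Exception:  # pragma: no cover
        return {}


def plot_benchmark(report: BenchmarkReport, path) -> None:
    """Bar chart of CV accuracy (mean +/- sd) per model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = report.ranking
    means = [report.cv_accuracy[m]["mean"] for m in names]
    sds = [report.cv_accuracy[m]["sd"] for m in names]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(range(len(names)), means, yerr=sds, capsize=4, color="#4878a8")
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=30, ha="right")
    ax.set_ylabel("CV accuracy")
    ax.set_ylim(0, 1)
    ax.set_title(f"Classifier comparison — {report.feature_set}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
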