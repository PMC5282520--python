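"""The eight benchmark schemas and the cross-validated runner.

Schema registry (feature extraction x classifier):

1. color + texture (38)            -> extreme learning machine (80 hidden units)
2. color + texture (38)            -> SVM, linear kernel
3. color + texture (38)            -> GA-selected subset + SVM, linear kernel
4. color + texture (38)            -> kNN (k in {5, 10, 20}, default 10)
5. two-level DWT coefficients      -> SVM (linear or polynomial kernel)
6. windowed uniform-LBP histograms -> SVM (linear or polynomial kernel)
7. raw 5x10 gray pixels            -> sparse-representation classifier (DE-L1)
8. color + texture (38)            -> sparse-representation classifier (DE-L1)

Every schema is evaluated with seeded stratified 4-fold cross validation.
Schemas 7 and 8 replace the classifier fit with the dictionary protocol: a
fixed number of negative/positive training samples of the fold become the
over-complete dictionary and each test sample is classified by its smaller
class-restricted reconstruction residual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .classify import KNNConfig, elm_train, knn_predict, svm_train
from .evaluate import FoldMetrics, MetricsReport, confusion_metrics, roc_auc, stratified_kfold
from .features.handcrafted import color_texture_vector
from .features.transform import LBPConfig, WaveletConfig, dwt_feature_vector, lbp_feature_vector
from .ga_selection import GAConfig, ga_select
from .prep import to_gray
from .sparse import DEConfig, build_dictionary, de_solve_l1, src_classify
from .synthetic import LabeledImageSet

__all__ = ["SchemaSpec", "SCHEMAS", "get_schema", "extract_features", "run_schema", "render_report"]


@dataclass(frozen=True)
class SchemaSpec:
    id: int
    feature: str  # color_texture | wavelet | lbp | raw_pixels
    classifier: str  # elm | svm | ga_svm | knn | src
    kernel: str = "linear"
    k: int = 10
    knn_distance: str = "euclidean"
    n_hidden: int = 80
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    lbp: LBPConfig = field(default_factory=LBPConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    de: DEConfig = field(default_factory=DEConfig)
    dict_neg: int = 5
    dict_pos: int = 70
    sample_size: tuple[int, int] = (5, 10)


SCHEMAS: dict[int, SchemaSpec] = {
    1: SchemaSpec(id=1, feature="color_texture", classifier="elm"),
    2: SchemaSpec(id=2, feature="color_texture", classifier="svm"),
    3: SchemaSpec(id=3, feature="color_texture", classifier="ga_svm"),
    4: SchemaSpec(id=4, feature="color_texture", classifier="knn"),
    5: SchemaSpec(id=5, feature="wavelet", classifier="svm"),
    6: SchemaSpec(id=6, feature="lbp", classifier="svm"),
    7: SchemaSpec(id=7, feature="raw_pixels", classifier="src", dict_neg=1, dict_pos=80),
    8: SchemaSpec(id=8, feature="color_texture", classifier="src", dict_neg=5, dict_pos=70),
}


def get_schema(schema_id: int, **overrides) -> SchemaSpec:
    if schema_id not in SCHEMAS:
        raise ValueError(f"schema id must be 1..8, got {schema_id}")
    spec = SCHEMAS[schema_id]
    return replace(spec, **overrides) if overrides else spec


def extract_features(spec: SchemaSpec, data: LabeledImageSet) -> np.ndarray | None:
    """Per-image feature matrix for the schema (None for raw-pixel SRC)."""
    if spec.feature == "color_texture":
        return np.stack([color_texture_vector(img).values for img in data.images])
    if spec.feature == "wavelet":
        return np.stack(
            [dwt_feature_vector(to_gray(img), spec.wavelet).values for img in data.images]
        )
    if spec.feature == "lbp":
        return np.stack(
            [lbp_feature_vector(to_gray(img), spec.lbp).values for img in data.images]
        )
    if spec.feature == "raw_pixels":
        return None
    raise ValueError(f"unknown feature kind {spec.feature!r}")


def _query_seed(seed: int, fold: int, query: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(fold, query)).generate_state(1)[0] % (2**31))


def _run_src_fold(
    spec: SchemaSpec,
    data: LabeledImageSet,
    X: np.ndarray | None,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    seed: int,
    fold: int,
) -> tuple[np.ndarray, np.ndarray]:
    if spec.feature == "raw_pixels":
        train = data.subset(train_idx)
        problem, transform, _ = build_dictionary(
            train, spec.dict_neg, spec.dict_pos, sample_size=spec.sample_size, seed=seed + fold
        )
        queries = [transform(data.images[i]) for i in test_idx]
    else:
        # feature-based dictionary: standardize on the fold's training data
        mu = X[train_idx].mean(axis=0)
        sd = X[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        problem, transform, _ = build_dictionary(
            (Z[train_idx], data.labels[train_idx]),
            spec.dict_neg,
            spec.dict_pos,
            sample_size=None,
            seed=seed + fold,
        )
        queries = [transform(Z[i]) for i in test_idx]
    preds = np.empty(len(test_idx), dtype=int)
    scores = np.empty(len(test_idx))
    for qi, y_vec in enumerate(queries):
        de_cfg = replace(spec.de, seed=_query_seed(seed, fold, qi))
        result = de_solve_l1(problem, y_vec, de_cfg)
        label, _, score = src_classify(problem, y_vec, result.x)
        preds[qi], scores[qi] = label, score
    return preds, scores


def run_schema(
    spec: SchemaSpec | int,
    data: LabeledImageSet,
    seed: int = 0,
    k: int = 4,
    max_folds: int | None = None,
    features: np.ndarray | None = None,
) -> MetricsReport:
    """Evaluate one schema with stratified k-fold cross validation.

    ``features`` may carry a precomputed feature matrix (as returned by
    :func:`extract_features`) so several schemas can share one extraction
    pass. ``max_folds`` limits how many folds are evaluated — useful for the
    expensive sparse-representation schemas, whose per-query DE solve
    dominates runtime.
    """
    if isinstance(spec, int):
        spec = get_schema(spec)
    X = features if features is not None else extract_features(spec, data)
    y = data.labels
    folds = stratified_kfold(y, k=k, seed=seed)
    if max_folds is not None:
        folds = folds[:max_folds]

    fold_metrics: list[FoldMetrics] = []
    for fold, (train_idx, test_idx) in enumerate(folds):
        if spec.classifier == "src":
            preds, scores = _run_src_fold(spec, data, X, train_idx, test_idx, seed, fold)
        elif spec.classifier == "svm":
            model = svm_train(X[train_idx], y[train_idx], kernel=spec.kernel)
            preds = model.predict(X[test_idx])
            scores = model.decision_scores(X[test_idx])
        elif spec.classifier == "elm":
            model = elm_train(X[train_idx], y[train_idx], n_hidden=spec.n_hidden, seed=seed + fold)
            scores = model.decision_scores(X[test_idx])
            preds = (scores >= 0).astype(int)
        elif spec.classifier == "knn":
            cfg = KNNConfig(k=spec.k, distance=spec.knn_distance)
            preds, scores = knn_predict(X[train_idx], y[train_idx], X[test_idx], cfg)
        elif spec.classifier == "ga_svm":
            ga_cfg = replace(spec.ga, seed=seed + fold)
            best, _ = ga_select(X[train_idx], y[train_idx], ga_cfg)
            mask = best.bits
            model = svm_train(X[train_idx][:, mask], y[train_idx], kernel=spec.kernel)
            preds = model.predict(X[test_idx][:, mask])
            scores = model.decision_scores(X[test_idx][:, mask])
        else:
            raise ValueError(f"unknown classifier kind {spec.classifier!r}")

        metrics = confusion_metrics(y[test_idx], preds)
        roc_points, auc_value = roc_auc(y[test_idx], scores)
        fold_metrics.append(
            FoldMetrics(
                counts=metrics.counts,
                accuracy=metrics.accuracy,
                sensitivity=metrics.sensitivity,
                specificity=metrics.specificity,
                fnr=metrics.fnr,
                fpr=metrics.fpr,
                auc=auc_value,
                roc_points=roc_points,
            )
        )
    return MetricsReport(fold_metrics)


def render_report(reports: dict[str, MetricsReport], out_dir: str | Path) -> Path:
    """Write metrics.csv, metrics.json, per-fold ROC CSVs and a ROC plot PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for name, report in reports.items():
        acc, sens, spec_, auc_ = report.accuracy, report.sensitivity, report.specificity, report.auc
        rows.append(
            {
                "schema": name,
                "accuracy_mean": acc[0],
                "accuracy_std": acc[1],
                "sensitivity_mean": sens[0],
                "sensitivity_std": sens[1],
                "specificity_mean": spec_[0],
                "specificity_std": spec_[1],
                "auc_mean": auc_[0],
                "auc_std": auc_[1],
            }
        )
    columns = [
        "schema",
        "accuracy_mean",
        "accuracy_std",
        "sensitivity_mean",
        "sensitivity_std",
        "specificity_mean",
        "specificity_std",
        "auc_mean",
        "auc_std",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(out_dir / "metrics.csv", index=False)
    (out_dir / "metrics.json").write_text(
        json.dumps({name: r.as_dict() for name, r in reports.items()}, indent=2)
    )

    fig, ax = plt.subplots(figsize=(6, 5))
    for name, report in reports.items():
        for fold, fm in enumerate(report.folds):
            if fm.roc_points is None:
                continue
            pd.DataFrame(fm.roc_points, columns=["fpr", "tpr"]).to_csv(
                out_dir / f"roc_{name}_fold{fold}.csv", index=False
            )
        first = report.folds[0]
        if first.roc_points is not None:
            ax.plot(first.roc_points[:, 0], first.roc_points[:, 1], label=f"{name} (fold 1)")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if reports:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "roc.png", dpi=120)
    plt.close(fig)
    return out_dir / "metrics.csv"
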