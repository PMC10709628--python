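"""The classification model: PCA reduction to 95% explained variance
(capped at 16 components), k-nearest-neighbour classification (k = 4,
Euclidean metric, inverse-distance weighting) in the PCA score space,
repeated stratified cross-validation, and degree-of-similarity
classification of unknown candidate spectra.

The five performance indicators reported by :func:`repeated_stratified_cv`
are the standard chemometrics-suite set: macro one-vs-rest AUC, overall
classification accuracy, and support-weighted F1 / precision / recall,
pooled over all held-out predictions across repeats (per-repeat means are
reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import (
    accuracy_score,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .preprocess import PreprocessConfig, preprocess_features
from .spectra import ClassLabel, SpectralLibrary, Spectrum

__all__ = [
    "PCAModel",
    "KNNConfig",
    "ChemometricModel",
    "CVReport",
    "ClassificationResult",
    "fit_pca",
    "project",
    "knn_predict",
    "train_model",
    "repeated_stratified_cv",
    "compute_metrics",
    "classify_unknowns",
]

EPSILON = 1e-12  # regulariser in inverse-distance weights


@dataclass
class PCAModel:
    """Centered PCA basis retaining >= ``variance_target`` cumulative
    explained variance, capped at ``max_components`` leading components."""

    mean: np.ndarray
    loadings: np.ndarray               # (n_components, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    n_components: int
    variance_target: float

    @property
    def cumulative_variance(self) -> float:
        return float(self.explained_variance_ratio.sum())


def fit_pca(
    features: np.ndarray,
    variance_target: float = 0.95,
    max_components: int = 16,
) -> PCAModel:
    """Fit PCA and retain the minimal leading components reaching the
    variance target, capped at ``max_components``.

    Centering uses the training mean; no further scaling (the preprocessing
    chain already vector-normalizes). Zero-variance input is rejected.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("zero-variance feature matrix; PCA is degenerate")
    full = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    full.fit(X)
    cum = np.cumsum(full.explained_variance_ratio_)
    reached = np.searchsorted(cum, variance_target - 1e-12) + 1
    n_comp = int(min(reached, max_components, len(cum)))
    return PCAModel(
        mean=full.mean_,
        loadings=full.components_[:n_comp],
        explained_variance_ratio=full.explained_variance_ratio_[:n_comp],
        n_components=n_comp,
        variance_target=variance_target,
    )


def project(model: PCAModel, features: np.ndarray) -> np.ndarray:
    """Project feature vectors into the retained score space."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.mean.size:
        raise ValueError(
            f"feature length {X.shape[1]} does not match model ({model.mean.size})"
        )
    scores = (X - model.mean) @ model.loadings.T
    return scores if np.asarray(features).ndim == 2 else scores[0]


@dataclass
class KNNConfig:
    k: int = 4
    weighting: str = "inverse_distance"  # or "uniform"; metric is Euclidean

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.weighting not in ("inverse_distance", "uniform"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass
class ClassificationResult:
    """Per-class similarity weights (summing to 1) for one query."""

    weights: dict[str, float]
    top_class: str
    top_weight: float


def _class_weights(
    neighbor_labels: list[str],
    neighbor_dists: np.ndarray,
    classes: list[str],
    weighting: str,
) -> dict[str, float]:
    weights = {c: 0.0 for c in classes}
    zero = neighbor_dists == 0.0
    if weighting == "inverse_distance" and zero.any():
        # an exact match dominates: weight goes to the zero-distance labels
        for lab, z in zip(neighbor_labels, zero):
            if z:
                weights[lab] += 1.0
    else:
        for lab, d in zip(neighbor_labels, neighbor_dists):
            w = 1.0 / (d + EPSILON) if weighting == "inverse_distance" else 1.0
            weights[lab] += w
    total = sum(weights.values())
    return {c: w / total for c, w in weights.items()}


def knn_predict(
    train_scores: np.ndarray,
    train_labels: list[str],
    query: np.ndarray,
    config: KNNConfig | None = None,
    classes: list[str] | None = None,
) -> ClassificationResult:
    """kNN in score space with the documented deterministic semantics.

    Neighbour ranking ties are broken by smaller training index (stable
    sort); class weights are normalized sums of 1/(d + 1e-12); an
    exact-zero-distance neighbour short-circuits to weight 1 for its label;
    a tied top class is resolved in lexicographic class order.
    """
    if config is None:
        config = KNNConfig()
    train_scores = np.asarray(train_scores, dtype=float)
    if train_scores.shape[0] == 0:
        raise ValueError("model has no training scores")
    if config.k > train_scores.shape[0]:
        raise ValueError("k exceeds training set size")
    if classes is None:
        classes = sorted(set(train_labels))
    d = np.linalg.norm(train_scores - np.asarray(query, dtype=float), axis=1)
    order = np.argsort(d, kind="stable")[: config.k]
    weights = _class_weights(
        [train_labels[i] for i in order], d[order], classes, config.weighting
    )
    top_class = max(sorted(weights), key=lambda c: weights[c])
    return ClassificationResult(weights, top_class, weights[top_class])


@dataclass
class ChemometricModel:
    """Preprocessing config + PCA basis + training scores/labels + kNN."""

    preprocess: PreprocessConfig
    pca: PCAModel
    training_scores: np.ndarray
    training_labels: list[str]
    label_map: dict[str, ClassLabel]
    knn: KNNConfig = field(default_factory=KNNConfig)

    def __post_init__(self) -> None:
        if self.training_scores.shape[0] != len(self.training_labels):
            raise ValueError("score row count must equal label count")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.training_labels))


def _feature_matrix(library: SpectralLibrary, config: PreprocessConfig) -> np.ndarray:
    return np.vstack([preprocess_features(s, config) for s in library.spectra])


def train_model(
    library: SpectralLibrary,
    preprocess_config: PreprocessConfig | None = None,
    variance_target: float = 0.95,
    max_components: int = 16,
    knn_config: KNNConfig | None = None,
) -> ChemometricModel:
    """Fit the full pipeline on a labeled library."""
    if preprocess_config is None:
        preprocess_config = PreprocessConfig()
    if knn_config is None:
        knn_config = KNNConfig()
    library.validate_for_cv(min_per_class=2)
    X = _feature_matrix(library, preprocess_config)
    pca = fit_pca(X, variance_target, max_components)
    scores = project(pca, X)
    labels = [lab.key for lab in library.labels]
    return ChemometricModel(
        preprocess=preprocess_config,
        pca=pca,
        training_scores=scores,
        training_labels=labels,
        label_map={lab.key: lab for lab in library.labels},
        knn=knn_config,
    )


@dataclass
class CVReport:
    """Cross-validation performance: the five printed indicators plus
    per-class and per-repeat detail."""

    auc: float
    ca: float
    f1: float
    precision: float
    recall: float
    per_class: pd.DataFrame
    per_repeat: pd.DataFrame
    folds: int
    repeats: int
    seed: int
    n_components: list[int] = field(default_factory=list)
    cumulative_variance: list[float] = field(default_factory=list)

    def summary(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "ca": self.ca,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
        }


def compute_metrics(
    truth: list[str],
    predicted: list[str],
    class_scores: np.ndarray,
    classes: list[str],
) -> dict:
    """CA, support-weighted precision/recall/F1, and macro one-vs-rest AUC
    computed from the per-class similarity weights."""
    y = np.asarray(truth)
    yhat = np.asarray(predicted)
    if not (len(y) == len(yhat) == class_scores.shape[0]):
        raise ValueError("truth, predictions and scores must align")
    present = [c for c in classes if (y == c).any()]
    if len(present) < len(classes):
        import warnings

        missing = sorted(set(classes) - set(present))
        warnings.warn(f"classes absent from truth excluded from AUC: {missing}")
    if len(present) == 2:
        pos = present[1]
        auc = roc_auc_score((y == pos).astype(int), class_scores[:, classes.index(pos)])
    else:
        cols = [classes.index(c) for c in present]
        auc = roc_auc_score(
            y, class_scores[:, cols], multi_class="ovr", average="macro", labels=present
        )
    prec, rec, f1, support = precision_recall_fscore_support(
        y, yhat, labels=present, average=None, zero_division=0
    )
    weights = support / support.sum()
    per_class = pd.DataFrame(
        {"class": present, "precision": prec, "recall": rec, "f1": f1, "support": support}
    )
    return {
        "auc": float(auc),
        "ca": float(accuracy_score(y, yhat)),
        "precision": float(np.sum(prec * weights)),
        "recall": float(np.sum(rec * weights)),
        "f1": float(np.sum(f1 * weights)),
        "per_class": per_class,
    }


def repeated_stratified_cv(
    library: SpectralLibrary,
    preprocess_config: PreprocessConfig | None = None,
    variance_target: float = 0.95,
    max_components: int = 16,
    knn_config: KNNConfig | None = None,
    folds: int = 10,
    repeats: int = 6,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation repeated with fresh seeded
    partitions; PCA is fitted on training folds only (no leakage), metrics
    are pooled over all held-out predictions across repeats."""
    import warnings

    if preprocess_config is None:
        preprocess_config = PreprocessConfig()
    if knn_config is None:
        knn_config = KNNConfig()
    library.validate_for_cv(min_per_class=2)
    min_class = min(library.class_counts().values())
    if folds > min_class:
        warnings.warn(
            f"reducing folds from {folds} to {min_class} (smallest class size)"
        )
        folds = min_class
    # Per-sample preprocessing is deterministic and sample-local, so the
    # feature matrix can be computed once without train/test leakage.
    X = _feature_matrix(library, preprocess_config)
    y = np.array([lab.key for lab in library.labels])
    classes = sorted(set(y))
    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(repeats)]

    all_truth: list[str] = []
    all_pred: list[str] = []
    all_scores: list[np.ndarray] = []
    repeat_rows = []
    n_components: list[int] = []
    cumulative: list[float] = []
    for r, rseed in enumerate(repeat_seeds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rseed)
        r_truth: list[str] = []
        r_pred: list[str] = []
        r_scores: list[np.ndarray] = []
        for train_idx, test_idx in skf.split(X, y):
            pca = fit_pca(X[train_idx], variance_target, max_components)
            n_components.append(pca.n_components)
            cumulative.append(pca.cumulative_variance)
            train_scores = project(pca, X[train_idx])
            train_labels = list(y[train_idx])
            for ti in test_idx:
                res = knn_predict(
                    train_scores, train_labels, project(pca, X[ti]), knn_config, classes
                )
                r_truth.append(y[ti])
                r_pred.append(res.top_class)
                r_scores.append(np.array([res.weights[c] for c in classes]))
        rm = compute_metrics(r_truth, r_pred, np.vstack(r_scores), classes)
        repeat_rows.append({"repeat": r, **{k: rm[k] for k in ("auc", "ca", "f1", "precision", "recall")}})
        all_truth.extend(r_truth)
        all_pred.extend(r_pred)
        all_scores.extend(r_scores)

    pooled = compute_metrics(all_truth, all_pred, np.vstack(all_scores), classes)
    return CVReport(
        auc=pooled["auc"],
        ca=pooled["ca"],
        f1=pooled["f1"],
        precision=pooled["precision"],
        recall=pooled["recall"],
        per_class=pooled["per_class"],
        per_repeat=pd.DataFrame(repeat_rows),
        folds=folds,
        repeats=repeats,
        seed=seed,
        n_components=n_components,
        cumulative_variance=cumulative,
    )


def classify_unknowns(
    model: ChemometricModel,
    spectra: list[Spectrum],
) -> tuple[list[ClassificationResult], pd.DataFrame]:
    """Classify candidate spectra and build the bar-chart summary.

    Each spectrum is preprocessed with the training configuration, projected
    into the model's score space and kNN-classified. The summary aggregates
    per-class assignment counts and mean similarity weights, with the
    organ-type rollup (USO vs ASO vs contaminant) alongside.
    """
    results: list[ClassificationResult] = []
    classes = model.classes
    rows = []
    for i, spec in enumerate(spectra):
        feats = preprocess_features(spec, model.preprocess)
        scores = project(model.pca, feats)
        res = knn_predict(
            model.training_scores, model.training_labels, scores, model.knn, classes
        )
        results.append(res)
        top_label = model.label_map[res.top_class]
        rows.append(
            {
                "spectrum": spec.meta.get("id", f"ASC-{i}"),
                "top_class": res.top_class,
                "top_weight": res.top_weight,
                "organ_type": top_label.organ_type,
                **{f"w[{c}]": res.weights[c] for c in classes},
            }
        )
    detail = pd.DataFrame(rows)
    if len(detail):
        summary = (
            detail.groupby("top_class")
            .agg(count=("top_class", "size"), mean_weight=("top_weight", "mean"))
            .reset_index()
        )
        summary["organ_type"] = [
            model.label_map[c].organ_type for c in summary["top_class"]
        ]
    else:
        summary = pd.DataFrame(columns=["top_class", "count", "mean_weight", "organ_type"])
    detail.attrs["summary"] = summary
    return results, detail
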