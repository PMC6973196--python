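"""End-to-end experiment orchestration.

The full procedure: normalize the expression matrix, split it into training
and held-out test sets, fix a 5-fold plan on the training set, run a
particle swarm over the chosen kernel's hyperparameter space with per-fold
PCA cross-validated accuracy as the fitness, then refit PCA on the whole
training set, train the final one-vs-one SVM with the best parameters, and
score the held-out test set with imbalance-aware metrics (accuracy, macro
F-score, G-mean).

Per-fold PCA means each cross-validation fold's loadings and means come
only from its four calibration folds; the held-out fold is centered with
the calibration means and projected onto the calibration loadings, so no
validation information leaks into the feature extraction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .data import (
    ExpressionMatrix,
    FoldPlan,
    make_fold_plan,
    minmax_normalize,
    split_train_test,
)
from .kernels import KernelParams, check_psd, gram_matrix
from .metrics import confusion, multiclass_f_score, multiclass_g_mean, weighted_accuracy
from .pca import fit_pca, transform
from .pso import SwarmConfig, build_search_space, decode_position, optimize
from .svm import predict, train_mcsvm
from .synth import SynthSpec, generate_dataset


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment."""

    model_kind: str = "LGP"
    data_path: str | None = None
    label_column: str | None = "class"
    labels_path: str | None = None
    orientation: str = "samples_in_rows"
    synth: SynthSpec | None = None
    n_test: int | None = None
    test_fraction: float = 0.25
    stratified: bool = True
    k_folds: int = 5
    ppv_threshold: float = 0.95
    normalization: str = "global"
    fitness_metric: str = "accuracy"  # or "g_mean"
    strict_psd: bool = False
    n_particles: int | None = None  # None -> 10 x D
    max_iters: int = 50
    seed_split: int = 0
    seed_folds: int = 1
    seed_pso: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synth" in raw and raw["synth"] is not None:
            synth = dict(raw["synth"])
            for key in ("class_sizes", "diffuse_classes"):
                if key in synth:
                    synth[key] = tuple(synth[key])
            raw["synth"] = SynthSpec(**synth)
        return cls(**raw)


@dataclass
class RunReport:
    """Result of one experiment: best parameters and held-out metrics."""

    model_kind: str
    best_C: float
    best_params: KernelParams
    best_cv_fitness: float
    cv_fold_scores: list[float]
    cv_fold_components: list[int]
    final_components: int
    confusion_counts: list[list[int]]
    classes: list[int]
    test_accuracy: float
    test_f_score: float
    test_g_mean: float
    pso_history: list[float]
    psd_warnings: list[str]
    seeds: dict
    n_train: int
    n_test: int

    def to_json(self) -> str:
        d = asdict(self)
        d["best_params"] = asdict(self.best_params)
        return json.dumps(d, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    def metrics_tsv(self) -> str:
        header = "model\taccuracy\tf_score\tg_mean"
        row = (
            f"{self.model_kind}\t{self.test_accuracy:.4f}"
            f"\t{self.test_f_score:.4f}\t{self.test_g_mean:.4f}"
        )
        return header + "\n" + row + "\n"


def psd_gate(K: np.ndarray, strict: bool = False, tol: float = 1e-8) -> list[str]:
    """Validate a training Gram matrix's positive semidefiniteness.

    Returns the (possibly empty) list of warning messages.  An indefinite
    matrix raises when ``strict`` is set; otherwise it warns — libsvm's
    solver tolerates mildly indefinite precomputed kernels, and the hybrid
    kernel is not PSD for every admissible parameter set.
    """
    is_psd, min_eig = check_psd(K, tol)
    if is_psd:
        return []
    message = (
        f"training Gram matrix is not PSD (min eigenvalue {min_eig:.3e}); "
        "the soft-margin solver tolerates indefinite kernels"
    )
    if strict:
        raise ValueError(message)
    warnings.warn(message, RuntimeWarning)
    return [message]


def _fold_score(y_true, y_pred, classes, metric: str) -> float:
    if metric == "accuracy":
        return float(np.mean(y_true == y_pred))
    cm = confusion(y_true, y_pred, classes=classes)
    return multiclass_g_mean(cm)


def cv_fitness(
    data: ExpressionMatrix,
    fold_plan: FoldPlan,
    C: float,
    params: KernelParams,
    ppv_threshold: float = 0.95,
    metric: str = "accuracy",
    return_details: bool = False,
):
    """Mean k-fold validation score with per-fold PCA feature extraction.

    For each fold: PCA is fitted on the other k-1 folds (components chosen
    by the cumulative-variance rule), calibration and held-out rows are
    projected, an SVM is trained on the calibration scores' Gram matrix,
    and the held-out fold is scored through the cross Gram matrix.  A
    calibration set missing a class only trains the pairwise models for the
    classes present (a warning is emitted).
    """
    scores, components = [], []
    classes = sorted(set(data.labels.tolist()))
    for j, val_idx in enumerate(fold_plan.folds):
        calib_idx = np.concatenate(
            [f for i, f in enumerate(fold_plan.folds) if i != j]
        )
        y_cal = data.labels[calib_idx]
        present = sorted(set(y_cal.tolist()))
        if len(present) < len(classes):
            warnings.warn(
                f"fold {j}: calibration set is missing a class; pairwise "
                "models restricted to the classes present",
                RuntimeWarning,
            )
        if len(present) < 2:
            # no pairwise model trainable: degenerate to the present class
            y_hat = np.full(len(val_idx), present[0])
            scores.append(_fold_score(data.labels[val_idx], y_hat, classes, metric))
            components.append(0)
            continue
        model_pca = fit_pca(data.values[calib_idx], ppv_threshold)
        s_cal = transform(model_pca, data.values[calib_idx])
        s_val = transform(model_pca, data.values[val_idx])
        K = gram_matrix(s_cal, s_cal, params)
        K_val = gram_matrix(s_val, s_cal, params)
        if not (np.all(np.isfinite(K)) and np.all(np.isfinite(K_val))):
            # kernel overflow (large exponents at extreme parameters):
            # score the fold as worthless so the optimizer moves away
            warnings.warn(
                f"fold {j}: kernel values overflow for C={C:.3g}, "
                f"params={params}; fold scored 0",
                RuntimeWarning,
            )
            scores.append(0.0)
            components.append(model_pca.k)
            continue
        svm = train_mcsvm(K, y_cal, C, kernel_params=params)
        y_hat = predict(svm, K_val)
        scores.append(_fold_score(data.labels[val_idx], y_hat, classes, metric))
        components.append(model_pca.k)
    mean_score = float(np.mean(scores))
    if return_details:
        return mean_score, scores, components
    return mean_score


def _load_data(config: RunConfig) -> ExpressionMatrix:
    if (config.data_path is None) == (config.synth is None):
        raise ValueError("provide exactly one of data_path or synth")
    if config.synth is not None:
        return generate_dataset(config.synth)
    from .data import read_expression_table

    return read_expression_table(
        config.data_path,
        orientation=config.orientation,
        label_column=config.label_column,
        labels_path=config.labels_path,
    )


def run_experiment(config: RunConfig) -> RunReport:
    """Run the full optimize-then-evaluate experiment for one model kind."""
    data = _load_data(config)

    if config.normalization == "global":
        data, _ = minmax_normalize(data, mode="global")
        split = split_train_test(
            data.labels,
            _resolve_n_test(config, data.n_samples),
            seed=config.seed_split,
            stratified=config.stratified,
        )
    elif config.normalization == "train_fitted":
        split = split_train_test(
            data.labels,
            _resolve_n_test(config, data.n_samples),
            seed=config.seed_split,
            stratified=config.stratified,
        )
        from dataclasses import replace

        train_view = replace(
            data,
            values=data.values[split.train_indices],
            sample_ids=[data.sample_ids[i] for i in split.train_indices],
            labels=data.labels[split.train_indices],
        )
        _, stats = minmax_normalize(train_view, mode="train_fitted")
        data, _ = minmax_normalize(data, mode="train_fitted", stats=stats)
    else:
        raise ValueError(f"unknown normalization {config.normalization!r}")

    fold_plan = make_fold_plan(
        split.train_indices, config.k_folds, data.labels, seed=config.seed_folds
    )

    space = build_search_space(config.model_kind)
    swarm = SwarmConfig(
        n_particles=config.n_particles,
        max_iters=config.max_iters,
        seed=config.seed_pso,
    )

    def fitness(raw: np.ndarray) -> float:
        C, params = decode_position(space, raw)
        return cv_fitness(
            data,
            fold_plan,
            C,
            params,
            ppv_threshold=config.ppv_threshold,
            metric=config.fitness_metric,
        )

    result = optimize(space, fitness, swarm)
    best_C, best_params = decode_position(space, result.best_position)
    _, fold_scores, fold_components = cv_fitness(
        data,
        fold_plan,
        best_C,
        best_params,
        ppv_threshold=config.ppv_threshold,
        metric=config.fitness_metric,
        return_details=True,
    )

    # final model: PCA on the whole training set, evaluate the held-out test set
    train_idx, test_idx = split.train_indices, split.test_indices
    model_pca = fit_pca(data.values[train_idx], config.ppv_threshold)
    s_train = transform(model_pca, data.values[train_idx])
    s_test = transform(model_pca, data.values[test_idx])
    K_train = gram_matrix(s_train, s_train, best_params)

    psd_warnings = psd_gate(K_train, strict=config.strict_psd)

    svm = train_mcsvm(K_train, data.labels[train_idx], best_C, kernel_params=best_params)
    K_test = gram_matrix(s_test, s_train, best_params)
    y_hat = predict(svm, K_test)
    classes = sorted(set(data.labels.tolist()))
    cm = confusion(data.labels[test_idx], y_hat, classes=classes)

    return RunReport(
        model_kind=config.model_kind,
        best_C=best_C,
        best_params=best_params,
        best_cv_fitness=result.best_fitness,
        cv_fold_scores=fold_scores,
        cv_fold_components=fold_components,
        final_components=model_pca.k,
        confusion_counts=cm.counts.tolist(),
        classes=classes,
        test_accuracy=weighted_accuracy(cm),
        test_f_score=multiclass_f_score(cm),
        test_g_mean=multiclass_g_mean(cm),
        pso_history=result.history,
        psd_warnings=psd_warnings,
        seeds={
            "split": config.seed_split,
            "folds": config.seed_folds,
            "pso": config.seed_pso,
        },
        n_train=len(train_idx),
        n_test=len(test_idx),
    )


def _resolve_n_test(config: RunConfig, n_samples: int) -> int:
    if config.n_test is not None:
        return config.n_test
    return int(round(config.test_fraction * n_samples))
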