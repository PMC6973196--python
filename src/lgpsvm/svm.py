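"""Multiclass soft-margin SVM on precomputed Gram matrices.

Multiclass decomposition is one-vs-one: one binary soft-margin SVM per
unordered class pair, trained only on that pair's rows/columns of the
training Gram matrix, with majority voting at prediction time (vote ties
broken by the lowest class index).  Each pairwise quadratic program is
solved by libsvm via scikit-learn's precomputed-kernel SVC; the resulting
dual coefficients and bias are extracted into a plain serializable model so
prediction never needs the solver again.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

_DUAL_TOL = 1e-6


@dataclass
class PairwiseModel:
    """Binary model for one class pair; decision > 0 votes ``class_b``."""

    class_a: int
    class_b: int
    support_indices: np.ndarray  # column indices into the training Gram
    dual_coef: np.ndarray  # y_i * alpha_i per support vector
    bias: float


@dataclass
class SVMModel:
    """One-vs-one multiclass SVM over a precomputed training Gram matrix."""

    classes: list[int]
    C: float
    n_train: int
    pairwise: list[PairwiseModel] = field(default_factory=list)
    kernel_params: object | None = None
    train_ref: str | None = None


def train_mcsvm(
    K_train: np.ndarray,
    labels: np.ndarray,
    C: float,
    kernel_params=None,
    train_ref: str | None = None,
) -> SVMModel:
    """Train one soft-margin SVM per class pair on the training Gram matrix.

    Each pairwise problem sees only the sub-Gram of its two classes.  After
    training, the dual box constraints 0 <= alpha_i <= C and the equality
    constraint sum(alpha_i y_i) = 0 are asserted within solver tolerance.
    """
    K_train = np.asarray(K_train, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if K_train.shape != (n, n):
        raise ValueError(f"K_train must be {n}x{n}; got {K_train.shape}")
    if np.isnan(K_train).any():
        raise ValueError("K_train contains NaN")
    if C <= 0:
        raise ValueError("C must be > 0")
    classes = np.unique(labels).tolist()
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")

    model = SVMModel(
        classes=classes,
        C=float(C),
        n_train=n,
        kernel_params=kernel_params,
        train_ref=train_ref,
    )
    for ia, a in enumerate(classes):
        for b in classes[ia + 1 :]:
            idx = np.flatnonzero((labels == a) | (labels == b))
            y = np.where(labels[idx] == b, 1, -1)
            sub = K_train[np.ix_(idx, idx)]
            svc = SVC(C=C, kernel="precomputed")
            svc.fit(sub, y)
            dual = svc.dual_coef_[0]
            # dual_coef_ holds y_i * alpha_i; box and equality constraints
            tol = _DUAL_TOL * max(1.0, C)
            if np.any(np.abs(dual) > C + tol):
                raise AssertionError("dual box constraint violated")
            if abs(dual.sum()) > tol * max(1, len(dual)):
                raise AssertionError("dual equality constraint violated")
            model.pairwise.append(
                PairwiseModel(
                    class_a=int(a),
                    class_b=int(b),
                    support_indices=idx[svc.support_],
                    dual_coef=dual.copy(),
                    bias=float(svc.intercept_[0]),
                )
            )
    return model


def pairwise_decision_values(model: SVMModel, K_test_train: np.ndarray) -> np.ndarray:
    """Decision value of every pairwise model for every test row.

    ``K_test_train`` is the m x n_train cross Gram matrix; columns must
    align with the training rows the model was fitted on.  Column j of the
    result is the decision function of ``model.pairwise[j]``.
    """
    K = np.atleast_2d(np.asarray(K_test_train, dtype=float))
    if K.shape[1] != model.n_train:
        raise ValueError(
            f"K_test_train has {K.shape[1]} columns; model expects {model.n_train}"
        )
    out = np.empty((K.shape[0], len(model.pairwise)))
    for j, pm in enumerate(model.pairwise):
        out[:, j] = K[:, pm.support_indices] @ pm.dual_coef + pm.bias
    return out


def predict(model: SVMModel, K_test_train: np.ndarray) -> np.ndarray:
    """Majority-vote class prediction from pairwise decisions.

    A positive pairwise decision votes for the pair's higher class, a
    non-positive one for the lower; overall vote ties go to the lowest
    class index.
    """
    decisions = pairwise_decision_values(model, K_test_train)
    m = decisions.shape[0]
    class_pos = {c: i for i, c in enumerate(model.classes)}
    votes = np.zeros((m, len(model.classes)), dtype=int)
    for j, pm in enumerate(model.pairwise):
        win_b = decisions[:, j] > 0
        votes[win_b, class_pos[pm.class_b]] += 1
        votes[~win_b, class_pos[pm.class_a]] += 1
    # argmax returns the first (lowest-class) maximum: deterministic ties
    return np.asarray(model.classes, dtype=int)[votes.argmax(axis=1)]


def save_model(model: SVMModel, path: str | Path) -> None:
    """Serialize the model (duals, biases, classes, C, kernel params) to JSON."""
    payload = {
        "classes": model.classes,
        "C": model.C,
        "n_train": model.n_train,
        "train_ref": model.train_ref,
        "kernel_params": None,
        "pairwise": [
            {
                "class_a": pm.class_a,
                "class_b": pm.class_b,
                "support_indices": pm.support_indices.tolist(),
                "dual_coef": pm.dual_coef.tolist(),
                "bias": pm.bias,
            }
            for pm in model.pairwise
        ],
    }
    if model.kernel_params is not None:
        kp = model.kernel_params
        payload["kernel_params"] = {
            "kind": kp.kind,
            "beta": list(kp.beta) if kp.beta is not None else None,
            "eta": kp.eta,
            "delta": kp.delta,
            "degree": kp.degree,
            "sigma": kp.sigma,
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> SVMModel:
    """Load a model serialized by :func:`save_model`."""
    from .kernels import KernelParams

    payload = json.loads(Path(path).read_text())
    kp = payload["kernel_params"]
    kernel_params = None
    if kp is not None:
        kernel_params = KernelParams(
            kind=kp["kind"],
            beta=tuple(kp["beta"]) if kp["beta"] is not None else None,
            eta=kp["eta"],
            delta=kp["delta"],
            degree=kp["degree"],
            sigma=kp["sigma"],
        )
    return SVMModel(
        classes=payload["classes"],
        C=payload["C"],
        n_train=payload["n_train"],
        kernel_params=kernel_params,
        train_ref=payload["train_ref"],
        pairwise=[
            PairwiseModel(
                class_a=pm["class_a"],
                class_b=pm["class_b"],
                support_indices=np.asarray(pm["support_indices"], dtype=int),
                dual_coef=np.asarray(pm["dual_coef"], dtype=float),
                bias=pm["bias"],
            )
            for pm in payload["pairwise"]
        ],
    )
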