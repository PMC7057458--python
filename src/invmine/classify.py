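"""Feature scaling and the SVM that separates inversion from wild-type windows.

The default classifier is a linear-kernel SVM with penalty C = 0.1 (gamma is
recorded for parity with the RBF configuration but is inert for the linear
kernel).  Two scaling modes are supported:

``joint``
    Center/spread computed on the row-stacked training + candidate matrices.
    This mirrors the published procedure of normalizing simulated training
    features together with the candidate features, and is the default.  Note
    it is transductive: candidate statistics leak into the scaler, so the
    model is refit at call time on the jointly scaled training matrix.
``train_only``
    Conventional fit-on-train scaling, recommended when candidates arrive
    incrementally.

Fitting delegates to scikit-learn's SVC; prediction is recomputed from the
stored support vectors, dual coefficients and intercept so a saved model
(plain JSON) round-trips exactly and deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.svm import SVC

from .selection import DegenerateLabelsError


@dataclass
class TrainedClassifier:
    """A fitted margin classifier plus its scaler and feature subset."""

    selected_ids: list
    center: np.ndarray
    spread: np.ndarray
    kernel: str
    C: float
    gamma: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    classes: np.ndarray
    seed: int
    scaling_mode: str = "joint"
    train_X: Optional[np.ndarray] = None  # raw selected-feature training data,
    train_y: Optional[np.ndarray] = None  # kept for joint rescaling at call time

    def decision_function(self, X_scaled) -> np.ndarray:
        X_scaled = np.atleast_2d(np.asarray(X_scaled, dtype=float))
        if X_scaled.shape[1] != self.support_vectors.shape[1]:
            raise ValueError(
                f"expected {self.support_vectors.shape[1]} feature columns, "
                f"got {X_scaled.shape[1]}"
            )
        if self.kernel == "linear":
            K = X_scaled @ self.support_vectors.T
        elif self.kernel == "rbf":
            sq = (
                np.sum(X_scaled**2, axis=1)[:, None]
                - 2 * X_scaled @ self.support_vectors.T
                + np.sum(self.support_vectors**2, axis=1)[None, :]
            )
            K = np.exp(-self.gamma * np.maximum(sq, 0))
        else:
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        return K @ self.dual_coef + self.intercept

    def predict(self, X_scaled) -> np.ndarray:
        d = self.decision_function(X_scaled)
        return np.where(d > 0, self.classes[1], self.classes[0]).astype(int)

    def scale(self, X_raw) -> np.ndarray:
        return (np.asarray(X_raw, dtype=float) - self.center) / self.spread

    # -- persistence (versioned JSON) --------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "selected_ids": [int(i) for i in self.selected_ids],
            "center": self.center.tolist(),
            "spread": self.spread.tolist(),
            "kernel": self.kernel,
            "C": self.C,
            "gamma": self.gamma,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "classes": self.classes.tolist(),
            "seed": int(self.seed),
            "scaling_mode": self.scaling_mode,
            "train_X": None if self.train_X is None else self.train_X.tolist(),
            "train_y": None if self.train_y is None else self.train_y.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=1)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format_version") != 1:
            raise ValueError(f"unsupported model format in {path}")
        return cls(
            selected_ids=list(d["selected_ids"]),
            center=np.asarray(d["center"], dtype=float),
            spread=np.asarray(d["spread"], dtype=float),
            kernel=d["kernel"],
            C=float(d["C"]),
            gamma=float(d["gamma"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            classes=np.asarray(d["classes"], dtype=int),
            seed=int(d["seed"]),
            scaling_mode=d["scaling_mode"],
            train_X=None if d["train_X"] is None else np.asarray(d["train_X"], dtype=float),
            train_y=None if d["train_y"] is None else np.asarray(d["train_y"], dtype=int),
        )


def scale_features(
    train_X, test_X=None, mode: str = "joint"
) -> Tuple[np.ndarray, Optional[np.ndarray], Tuple[np.ndarray, np.ndarray]]:
    """Standardize feature columns to mean 0 / spread 1.

    ``joint`` fits the scaler on the stacked [train; test] rows; ``train_only``
    on the training rows alone.  Zero-spread columns fall back to spread 1
    (a constant column scales to all zeros).
    """
    train_X = np.asarray(train_X, dtype=float)
    if train_X.size == 0:
        raise ValueError("empty training matrix")
    if mode not in ("joint", "train_only"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    if test_X is not None:
        test_X = np.asarray(test_X, dtype=float)
        if test_X.shape[1] != train_X.shape[1]:
            raise ValueError("train/test column counts differ")
    fit_on = (
        np.vstack([train_X, test_X])
        if (mode == "joint" and test_X is not None and test_X.size)
        else train_X
    )
    center = fit_on.mean(axis=0)
    spread = fit_on.std(axis=0, ddof=0)
    spread = np.where(spread == 0, 1.0, spread)
    train_s = (train_X - center) / spread
    test_s = None if test_X is None else (test_X - center) / spread
    return train_s, test_s, (center, spread)


def train(
    X_scaled,
    y,
    kernel: str = "linear",
    C: float = 0.1,
    gamma: float = 20.0,
    seed: int = 0,
    selected_ids: Optional[Sequence[int]] = None,
    scaler: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    scaling_mode: str = "joint",
) -> TrainedClassifier:
    """Fit the SVM on an already-scaled matrix."""
    X_scaled = np.asarray(X_scaled, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("training labels contain a single class")
    svc = SVC(kernel=kernel, C=C, gamma=gamma, random_state=seed)
    svc.fit(X_scaled, y)
    n_cols = X_scaled.shape[1]
    if scaler is None:
        scaler = (np.zeros(n_cols), np.ones(n_cols))
    return TrainedClassifier(
        selected_ids=list(selected_ids) if selected_ids is not None else [],
        center=np.asarray(scaler[0], dtype=float),
        spread=np.asarray(scaler[1], dtype=float),
        kernel=kernel,
        C=C,
        gamma=gamma,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        classes=svc.classes_.astype(int),
        seed=seed,
        scaling_mode=scaling_mode,
    )


def predict(model: TrainedClassifier, X_scaled) -> np.ndarray:
    """0/1 labels for already-scaled rows."""
    return model.predict(X_scaled)


def fit_model(
    X_raw,
    y,
    selected_ids: Sequence[int],
    kernel: str = "linear",
    C: float = 0.1,
    gamma: float = 20.0,
    seed: int = 0,
    scaling_mode: str = "joint",
) -> TrainedClassifier:
    """Scale (on train) and fit; keeps the raw training data for joint mode."""
    X_raw = np.asarray(X_raw, dtype=float)
    X_s, _, scaler = scale_features(X_raw, None, mode="train_only")
    model = train(
        X_s,
        y,
        kernel=kernel,
        C=C,
        gamma=gamma,
        seed=seed,
        selected_ids=selected_ids,
        scaler=scaler,
        scaling_mode=scaling_mode,
    )
    model.train_X = X_raw.copy()
    model.train_y = np.asarray(y, dtype=int).copy()
    return model


def apply_model(model: TrainedClassifier, X_raw) -> np.ndarray:
    """Score raw candidate feature rows with a trained model.

    In joint mode the scaler is refit on the stacked training + candidate
    rows and the SVM refit (same hyperparameters and seed) on the rescaled
    training data, reproducing the transductive published procedure.  In
    train_only mode the stored scaler and fit are reused as-is.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    if X_raw.size == 0:
        return np.zeros(0, dtype=int)
    if model.scaling_mode == "joint":
        if model.train_X is None:
            raise ValueError("joint scaling requires the stored training matrix")
        train_s, test_s, _ = scale_features(model.train_X, X_raw, mode="joint")
        refit = train(
            train_s,
            model.train_y,
            kernel=model.kernel,
            C=model.C,
            gamma=model.gamma,
            seed=model.seed,
        )
        return refit.predict(test_s)
    return model.predict(model.scale(X_raw))
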