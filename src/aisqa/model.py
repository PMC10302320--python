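"""Gaussian-process regression from the 22-feature space to the quality index.

The continuous signal-quality index (AISQA) lives on [0, 3], anchored to the
ordinal expert grades 0 (excellent) .. 3 (uninterpretable) but treated as a
real-valued regression target: the GP posterior mean interpolates between
the heuristic grade anchors.  Three stationary kernels are supported —
rational quadratic, Matérn 5/2 and the exponential kernel (Matérn 1/2) —
each combined with a fitted homoscedastic noise term, since expert labels
carry subjective rating noise.  Features are standardized on training
statistics; GP length-scales are scale-sensitive and the 22 features mix
units (mV, ms, s, dB, dimensionless).
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    ConstantKernel,
    Matern,
    RationalQuadratic,
    WhiteKernel,
)
from sklearn.model_selection import KFold, train_test_split
from sklearn.preprocessing import StandardScaler

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

KERNELS = ("rational_quadratic", "matern52", "exponential")
SCORE_RANGE = (0.0, 3.0)

__all__ = ["AISQAModel", "SplitSpec", "KERNELS", "split_holdout", "train",
           "cross_val_predictions", "predict_aisqa", "save_model", "load_model"]


def _make_kernel(name: str):
    if name == "rational_quadratic":
        base = RationalQuadratic(length_scale=1.0, alpha=1.0)
    elif name == "matern52":
        base = Matern(length_scale=1.0, nu=2.5)
    elif name == "exponential":
        base = Matern(length_scale=1.0, nu=0.5)
    else:
        raise ValueError(f"unknown kernel {name!r}; choose from {KERNELS}")
    return ConstantKernel(1.0) * base + WhiteKernel(noise_level=0.1)


@dataclass
class SplitSpec:
    """Holdout / cross-validation layout."""

    holdout_fraction: float = 0.2
    cv_folds: int = 5
    seed: int = 0
    stratify_by_label: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in (0, 1)")


@dataclass
class AISQAModel:
    """Trained quality-index regressor (scaler + GP + metadata)."""

    kernel_name: str
    scaler: StandardScaler
    gp: GaussianProcessRegressor
    seed: int
    n_train: int
    cv_folds: int
    feature_names: tuple = field(default=FEATURE_NAMES)


def split_holdout(X: np.ndarray, y: np.ndarray, spec: SplitSpec):
    """Disjoint, exhaustive, label-stratified holdout split (seeded).

    Continuous targets are stratified on their rounded integer grade; if a
    grade has too few members for stratification the split falls back to a
    plain random split with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < 25:
        raise ValueError("need at least 25 records to split")
    strat = None
    if spec.stratify_by_label:
        bins = np.clip(np.round(y), 0, 3).astype(int)
        counts = np.bincount(bins, minlength=4)
        if np.all((counts == 0) | (counts >= 2)):
            strat = bins
        else:
            logger.warning("a quality class is too small to stratify; plain split")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=spec.holdout_fraction, random_state=spec.seed, stratify=strat
    )
    present = set(np.unique(np.clip(np.round(y_tr), 0, 3)))
    missing = set(np.unique(np.clip(np.round(y), 0, 3))) - present
    if missing:
        logger.warning("quality class(es) %s absent from the training split", missing)
    return X_tr, X_te, y_tr, y_te


def train(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "exponential",
    spec: SplitSpec | None = None,
    n_restarts: int = 3,
) -> AISQAModel:
    """Fit the GP by marginal-likelihood maximization on standardized features."""
    spec = spec or SplitSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("features and labels must be finite")
    scaler = StandardScaler().fit(X)
    gp = GaussianProcessRegressor(
        kernel=_make_kernel(kernel),
        normalize_y=True,
        n_restarts_optimizer=n_restarts,
        random_state=spec.seed,
    )
    gp.fit(scaler.transform(X), y)
    return AISQAModel(
        kernel_name=kernel,
        scaler=scaler,
        gp=gp,
        seed=spec.seed,
        n_train=len(X),
        cv_folds=spec.cv_folds,
    )


def cross_val_predictions(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "exponential",
    spec: SplitSpec | None = None,
) -> np.ndarray:
    """Out-of-fold predictions under k-fold CV (the validation-phase scores)."""
    spec = spec or SplitSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    preds = np.empty(len(y))
    kf = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    for tr, te in kf.split(X):
        fold = train(X[tr], y[tr], kernel=kernel, spec=spec)
        preds[te] = predict_aisqa(fold, X[te])
    return preds


def predict_aisqa(
    model: AISQAModel, X: np.ndarray, return_std: bool = False
):
    """GP posterior mean clipped to the [0, 3] quality range."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    Xs = model.scaler.transform(X)
    if return_std:
        mean, std = model.gp.predict(Xs, return_std=True)
        return np.clip(mean, *SCORE_RANGE), std
    return np.clip(model.gp.predict(Xs), *SCORE_RANGE)


def save_model(model: AISQAModel, path: str | Path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> AISQAModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, AISQAModel):
        raise TypeError(f"{path} does not contain an AISQAModel")
    return model
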