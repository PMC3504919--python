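"""nu-SVR regression of imputation quality from the 12-feature descriptor.

The model regresses one of three targets per SNP — IQS, the observed
agreement Po, or the chance agreement Pc — with a radial-basis-function
kernel, k(x, x') = exp(-gamma ||x - x'||^2), gamma fixed at 1/d for d = 12
features. The nu formulation trades the epsilon-tube width off automatically:
nu lower-bounds the fraction of support vectors and upper-bounds the fraction
of margin errors (training points outside the tube). nu is selected from the
grid {0.1, ..., 1.0} by 10-fold cross-validated mean squared error with a
seeded fold shuffle; the penalty C stays at the libsvm default of 1.

Features are min-max scaled to [0, 1] on the training data only; with a
shared gamma, unscaled bp positions would otherwise dominate the kernel.
Predicted targets are returned raw (not clipped): kappa can legitimately be
negative, and clipping is a display decision left to the evaluation layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import KFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import NuSVR

from .features import N_FEATURES

__all__ = [
    "DEFAULT_NU_GRID",
    "RegressionModel",
    "fit_scaler",
    "select_nu",
    "fit",
    "combine_po_pc",
    "nu_bound_fractions",
]

TARGET_KINDS = ("IQS", "Po", "Pc")
DEFAULT_NU_GRID: Tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 11))
DEFAULT_C = 1.0
DEFAULT_SEED = 42


def fit_scaler(X: np.ndarray) -> MinMaxScaler:
    """Fit a per-feature min-max transform to [0, 1]; constant features map to 0."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("feature matrix must be 2-D and non-empty")
    return MinMaxScaler().fit(X)


def _check_training(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError(
            "training data contains NaN; exclude undefined-IQS SNPs upstream"
        )
    return X, y


def select_nu(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[float] = DEFAULT_NU_GRID,
    c_penalty: float = DEFAULT_C,
    n_folds: int = 10,
    seed: int = DEFAULT_SEED,
) -> Tuple[float, dict]:
    """Pick nu from ``grid`` by minimal mean k-fold CV mean squared error.

    Folds come from a seeded shuffle shared across the grid; ties resolve to
    the smaller nu. The scaler is refit inside every fold so no test-fold
    information leaks into the transform. Returns (best_nu, {nu: cv_mse}).
    """
    X, y = _check_training(X, y)
    grid = sorted(set(float(v) for v in grid))
    if not grid:
        raise ValueError("empty nu grid")
    if len(X) < 2 * n_folds:
        raise ValueError(f"need >= {2 * n_folds} training rows for {n_folds}-fold CV")
    folds = list(KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(X))
    cv_mse = {}
    for nu in grid:
        errs = []
        for tr, te in folds:
            scaler = fit_scaler(X[tr])
            svr = NuSVR(nu=nu, C=c_penalty, kernel="rbf", gamma=1.0 / X.shape[1])
            svr.fit(scaler.transform(X[tr]), y[tr])
            resid = y[te] - svr.predict(scaler.transform(X[te]))
            errs.append(float(np.mean(resid**2)))
        cv_mse[nu] = float(np.mean(errs))
    best = min(grid, key=lambda v: (cv_mse[v], v))
    return best, cv_mse


@dataclass
class RegressionModel:
    """A fitted nu-SVR for one quality target, bundled with its feature scaler."""

    target_kind: str
    nu: float
    c_penalty: float
    gamma: float
    scaler: MinMaxScaler
    svr: Optional[NuSVR] = None
    # populated on save/load so a deserialized model predicts without libsvm state
    _sv: Optional[np.ndarray] = field(default=None, repr=False)
    _dual_coef: Optional[np.ndarray] = field(default=None, repr=False)
    _intercept: float = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Raw regression outputs for an (n, d) feature matrix (never clipped)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.scaler.n_features_in_:
            raise ValueError(
                f"expected {self.scaler.n_features_in_} feature columns, "
                f"got shape {X.shape}"
            )
        Xs = self.scaler.transform(X)
        if self.svr is not None:
            return self.svr.predict(Xs)
        # explicit RBF kernel expansion over the stored support vectors
        sq = ((Xs[:, None, :] - self._sv[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * sq) @ self._dual_coef + self._intercept

    # -- serialization: JSON key-value container, round-trip exact ------------

    def save(self, path: str | Path) -> None:
        if self.svr is not None:
            sv = self.svr.support_vectors_
            dual = self.svr.dual_coef_.ravel()
            intercept = float(self.svr.intercept_[0])
        else:
            sv, dual, intercept = self._sv, self._dual_coef, self._intercept
        payload = {
            "format": "iqspred-nusvr",
            "version": 1,
            "target_kind": self.target_kind,
            "nu": self.nu,
            "c_penalty": self.c_penalty,
            "gamma": self.gamma,
            "scaler_min": self.scaler.data_min_.tolist(),
            "scaler_max": self.scaler.data_max_.tolist(),
            "support_vectors": sv.tolist(),
            "dual_coef": dual.tolist(),
            "intercept": intercept,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "RegressionModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "iqspred-nusvr":
            raise ValueError(f"{path}: not an iqspred model file")
        scaler = MinMaxScaler()
        scaler.fit(np.vstack([payload["scaler_min"], payload["scaler_max"]]))
        return cls(
            target_kind=payload["target_kind"],
            nu=payload["nu"],
            c_penalty=payload["c_penalty"],
            gamma=payload["gamma"],
            scaler=scaler,
            svr=None,
            _sv=np.asarray(payload["support_vectors"], dtype=float),
            _dual_coef=np.asarray(payload["dual_coef"], dtype=float),
            _intercept=float(payload["intercept"]),
        )


def fit(
    X: np.ndarray,
    y: np.ndarray,
    nu: float,
    target_kind: str = "IQS",
    c_penalty: float = DEFAULT_C,
) -> RegressionModel:
    """Fit a nu-SVR with RBF kernel, gamma = 1/d, on unscaled features.

    The min-max scaler is fit here, on the training rows only; callers pass
    raw feature matrices to both :func:`fit` and :meth:`RegressionModel.predict`.
    """
    if target_kind not in TARGET_KINDS:
        raise ValueError(f"target_kind must be one of {TARGET_KINDS}")
    if not 0.0 < nu <= 1.0:
        raise ValueError("nu must be in (0, 1]")
    X, y = _check_training(X, y)
    scaler = fit_scaler(X)
    gamma = 1.0 / X.shape[1]
    svr = NuSVR(nu=nu, C=c_penalty, kernel="rbf", gamma=gamma)
    svr.fit(scaler.transform(X), y)
    if svr.fit_status_ != 0:
        raise RuntimeError(
            f"nu-SVR solver did not converge (status {svr.fit_status_}, "
            f"nu={nu}, C={c_penalty}, n={len(X)})"
        )
    return RegressionModel(
        target_kind=target_kind,
        nu=nu,
        c_penalty=c_penalty,
        gamma=gamma,
        scaler=scaler,
        svr=svr,
    )


def fit_with_selection(
    X: np.ndarray,
    y: np.ndarray,
    target_kind: str = "IQS",
    grid: Sequence[float] = DEFAULT_NU_GRID,
    c_penalty: float = DEFAULT_C,
    n_folds: int = 10,
    seed: int = DEFAULT_SEED,
) -> RegressionModel:
    """Grid-search nu by CV, then fit on the full training set."""
    best, _ = select_nu(X, y, grid=grid, c_penalty=c_penalty, n_folds=n_folds, seed=seed)
    return fit(X, y, nu=best, target_kind=target_kind, c_penalty=c_penalty)


def nu_bound_fractions(model: RegressionModel, n_train: int) -> Tuple[float, float]:
    """(support-vector fraction, margin-error fraction) of a fitted model.

    Margin errors are training points outside the epsilon tube; their dual
    coefficients sit at the box bound C, so they are counted directly from the
    solver state rather than re-estimating epsilon.
    """
    if model.svr is None:
        raise ValueError("bound diagnostics require the fitted solver handle")
    dual = np.abs(model.svr.dual_coef_.ravel())
    sv_frac = dual.size / n_train
    at_bound = np.sum(dual >= model.c_penalty * (1.0 - 1e-8))
    return float(sv_frac), float(at_bound / n_train)


def combine_po_pc(po_hat: np.ndarray, pc_hat: np.ndarray) -> np.ndarray:
    """Combine separate Po and Pc predictions into an IQS estimate.

    (po - pc) / (1 - pc), elementwise; entries with pc >= 1 - 1e-6 are
    undefined and returned as NaN.
    """
    po = np.asarray(po_hat, dtype=float)
    pc = np.asarray(pc_hat, dtype=float)
    out = np.full(np.broadcast(po, pc).shape, np.nan)
    ok = pc < 1.0 - 1e-6
    out[ok] = (po - pc)[ok] / (1.0 - pc[ok])
    return out
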