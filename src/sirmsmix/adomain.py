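"""Applicability domain via leverage and standardized residuals.

A prediction is trusted only for mixtures structurally similar to the
training set.  Similarity is measured by the leverage

    h_i = x_i (X^T X)^{-1} x_i^T

computed with the intercept-augmented training descriptor matrix X; the
warning threshold is h* = 3(p+1)/n_train.  The response axis of the Williams
plot uses cross-validated standardized residuals: leave-one-out residuals
for training samples, raw residuals for test samples, both scaled by the
training LOO-residual standard deviation.  A sample is an outlier of the
domain when h > h* (structural extrapolation) or |standardized residual| > 3
(response outlier); both inequalities are strict, and high-leverage samples
that are still predicted within 3 SD are flagged but considered acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import QsprModel, SingularDesignError, loo_residuals, predict


def warning_leverage(p: int, n: int) -> float:
    """Warning leverage h* = 3(p+1)/n for p model parameters and n training
    samples."""
    if p < 1 or n <= p:
        raise ValueError(f"need p >= 1 and n > p, got p={p}, n={n}")
    return 3.0 * (p + 1) / n


def leverages(X_train, X_query=None) -> np.ndarray:
    """Leverage of each query row w.r.t. the training cross-product matrix.

    Rows of the hat matrix diagonal when ``X_query`` is the training set
    itself (then the values sum to p+1, the hat-matrix trace).
    """
    Xt = np.asarray(
        X_train.to_numpy() if isinstance(X_train, pd.DataFrame) else X_train,
        dtype=float,
    )
    Xq = Xt if X_query is None else np.asarray(
        X_query.to_numpy() if isinstance(X_query, pd.DataFrame) else X_query,
        dtype=float,
    )
    A = np.column_stack([np.ones(len(Xt)), Xt])
    B = np.column_stack([np.ones(len(Xq)), Xq])
    xtx = A.T @ A
    if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
        raise SingularDesignError("X^T X is singular; leverages undefined")
    xtx_inv = np.linalg.inv(xtx)
    return np.einsum("ij,jk,ik->i", B, xtx_inv, B)


def standardized_cv_residuals(
    model: QsprModel, X, y, train: bool = True, scale_sd: float | None = None
) -> np.ndarray:
    """Standardized residuals for the Williams plot.

    Training rows use leave-one-out residuals; test rows use plain
    residuals.  Both are divided by ``scale_sd`` (the training LOO-residual
    SD) or, when not given, by the SD of the residuals themselves.  An
    identically-zero residual vector returns zeros rather than dividing.
    """
    y = np.asarray(y, dtype=float)
    if train:
        Xm = X[model.names].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        resid = loo_residuals(Xm, y)
    else:
        resid = y - predict(model, X)
    if np.allclose(resid, 0.0):
        return np.zeros_like(resid)
    sd = scale_sd if scale_sd is not None else float(np.std(resid, ddof=1))
    if sd <= 0:
        raise ZeroDivisionError("zero residual variance; cannot standardize")
    return resid / sd


@dataclass
class ADReport:
    """Per-sample applicability-domain diagnostics plus h*."""

    table: pd.DataFrame  # sample_id, set, leverage, std_residual, flags
    h_star: float
    p: int
    n_train: int

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def williams_points(self) -> pd.DataFrame:
        """Two-column (leverage, std residual) table for external plotting."""
        return self.table[["leverage", "std_residual"]].copy()

    @property
    def outliers(self) -> pd.DataFrame:
        return self.table[self.table.high_leverage | self.table.response_outlier]


def williams_report(
    model: QsprModel,
    X_train,
    y_train,
    X_test=None,
    y_test=None,
    train_ids=None,
    test_ids=None,
) -> ADReport:
    """Leverage + standardized-residual classification for every sample."""
    Xtr = X_train[model.names] if isinstance(X_train, pd.DataFrame) else X_train
    y_train = np.asarray(y_train, dtype=float)
    n, p = np.asarray(Xtr, dtype=float).shape
    h_star = warning_leverage(p, n)

    loo = loo_residuals(Xtr, y_train)
    train_sd = float(np.std(loo, ddof=1)) if not np.allclose(loo, 0) else None
    h_tr = leverages(Xtr)
    std_tr = standardized_cv_residuals(model, Xtr, y_train, train=True, scale_sd=train_sd)

    if train_ids is None:
        train_ids = (
            list(X_train.index) if isinstance(X_train, pd.DataFrame)
            else [f"train_{i}" for i in range(n)]
        )
    records = [
        {"sample_id": sid, "set": "train", "leverage": float(h),
         "std_residual": float(r)}
        for sid, h, r in zip(train_ids, h_tr, std_tr)
    ]

    if X_test is not None and y_test is not None and len(np.asarray(y_test)) > 0:
        Xte = X_test[model.names] if isinstance(X_test, pd.DataFrame) else X_test
        h_te = leverages(Xtr, Xte)
        std_te = standardized_cv_residuals(
            model, X_test, np.asarray(y_test, float), train=False, scale_sd=train_sd
        )
        if test_ids is None:
            test_ids = (
                list(X_test.index) if isinstance(X_test, pd.DataFrame)
                else [f"test_{i}" for i in range(len(h_te))]
            )
        records += [
            {"sample_id": sid, "set": "test", "leverage": float(h),
             "std_residual": float(r)}
            for sid, h, r in zip(test_ids, h_te, std_te)
        ]

    table = pd.DataFrame.from_records(records)
    table["high_leverage"] = table.leverage > h_star
    table["response_outlier"] = table.std_residual.abs() > 3.0
    table["inside_ad"] = ~(table.high_leverage | table.response_outlier)
    return ADReport(table=table, h_star=h_star, p=p, n_train=n)
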