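"""Internal and external model validation.

Internal robustness is judged by leave-one-out cross-validation
(Q2_LOO = 1 - PRESS/TSS) and by Y-randomization: the response vector is
scrambled repeatedly, descriptor selection is rerun on each scramble and the
model is declared free of chance correlation when the true R^2 exceeds the
mean highest random R^2 by more than 2.3 SD (1% level) resp. 3 SD (0.1%
level).

External validation uses the compounds-out strategy: whole pure compounds
are withheld so that every test mixture contains at least one compound the
model never saw, and predictions are scored with
Q2_EXT = 1 - sum(y - yhat)^2 / sum(y - ybar_train)^2 (training mean in the
denominator) plus AAE, RMSE and mean/max percent errors.

"Points out" and "mixtures out" partitions are weaker alternatives
(mixtures of known compounds can appear in both sets) and are deliberately
not implemented.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .mixture import MixtureSample
from .model import (
    GAConfig,
    QsprModel,
    _as_matrix,
    fit_mlr,
    ga_select,
    loo_residuals,
    predict,
)
from .model import q2_loo  # noqa: F401  (re-exported: internal validation statistic)


@dataclass
class ErrorStats:
    aae: float
    rmse: float
    are_percent: float
    max_percent_error: float


def error_stats(y, y_pred) -> ErrorStats:
    """AAE, RMSE, mean and max percent error of predictions."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.size == 0 or y.shape != y_pred.shape:
        raise ValueError("observed and predicted vectors must be equal-length, nonempty")
    resid = y - y_pred
    if np.any(y == 0):
        raise ZeroDivisionError("percent errors undefined: observed value of 0 K")
    pct = np.abs(resid) / np.abs(y) * 100.0
    return ErrorStats(
        aae=float(np.mean(np.abs(resid))),
        rmse=float(np.sqrt(np.mean(resid**2))),
        are_percent=float(np.mean(pct)),
        max_percent_error=float(np.max(pct)),
    )


def q2_ext_from_predictions(y_test, y_pred, ybar_train: float) -> float:
    """External predictive squared correlation with the training mean in the
    denominator."""
    y_test = np.asarray(y_test, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_test.size == 0:
        raise ValueError("empty test set")
    denom = float(np.sum((y_test - ybar_train) ** 2))
    if denom <= 0:
        raise ZeroDivisionError("all test responses equal the training mean")
    return 1.0 - float(np.sum((y_test - y_pred) ** 2)) / denom


def q2_ext(model: QsprModel, X_test, y_test, ybar_train: float) -> float:
    return q2_ext_from_predictions(y_test, predict(model, X_test), ybar_train)


@dataclass
class ValidationReport:
    """Training/test statistics in the usual QSPR reporting layout."""

    r2_train: float
    q2_loo: float
    rmse_train: float
    aae_train: float
    are_train_percent: float
    n_train: int
    r2_test: float | None = None
    q2_ext: float | None = None
    rmse_test: float | None = None
    aae_test: float | None = None
    are_test_percent: float | None = None
    max_percent_error: float | None = None
    n_test: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    def to_text(self) -> str:
        def fmt(v):
            return "-" if v is None else (f"{v:.3f}" if isinstance(v, float) else str(v))

        rows = [
            ("R2", self.r2_train, self.r2_test),
            ("Q2_LOO", self.q2_loo, None),
            ("Q2_EXT", None, self.q2_ext),
            ("RMSE (K)", self.rmse_train, self.rmse_test),
            ("AAE (K)", self.aae_train, self.aae_test),
            ("ARE (%)", self.are_train_percent, self.are_test_percent),
            ("n", self.n_train, self.n_test),
        ]
        width = max(len(r[0]) for r in rows)
        lines = [f"{'parameter':<{width}}  training  test"]
        for label, tr, te in rows:
            lines.append(f"{label:<{width}}  {fmt(tr):>8}  {fmt(te):>4}")
        return "\n".join(lines)


def validation_report(
    model: QsprModel, X_train, y_train, X_test=None, y_test=None
) -> ValidationReport:
    y_train = np.asarray(y_train, dtype=float)
    yhat_tr = predict(model, X_train)
    tr = error_stats(y_train, yhat_tr)
    rep = ValidationReport(
        r2_train=model.stats["r2"],
        q2_loo=model.stats["q2_loo"],
        rmse_train=tr.rmse,
        aae_train=tr.aae,
        are_train_percent=tr.are_percent,
        n_train=len(y_train),
    )
    if X_test is not None and y_test is not None and len(np.asarray(y_test)) > 0:
        y_test = np.asarray(y_test, dtype=float)
        yhat_te = predict(model, X_test)
        te = error_stats(y_test, yhat_te)
        ss_res = float(np.sum((y_test - yhat_te) ** 2))
        ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
        rep.r2_test = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        rep.q2_ext = q2_ext_from_predictions(y_test, yhat_te, float(y_train.mean()))
        rep.rmse_test = te.rmse
        rep.aae_test = te.aae
        rep.are_test_percent = te.are_percent
        all_pct = error_stats(
            np.concatenate([y_train, y_test]), np.concatenate([yhat_tr, yhat_te])
        )
        rep.max_percent_error = all_pct.max_percent_error
        rep.n_test = len(y_test)
    return rep


# --- compounds-out partitioning --------------------------------------------


@dataclass
class SplitPlan:
    held_out_compounds: list[str]
    train_ids: list[str]
    test_ids: list[str]
    test_fraction: float
    seed: int


class SplitError(ValueError):
    pass


def compounds_out_split(
    samples: list[MixtureSample],
    test_fraction: float = 0.25,
    seed: int = 0,
    max_candidates: int = 500,
    max_held_out: int = 3,
    fraction_slack: float = 0.15,
) -> SplitPlan:
    """Partition mixtures by withholding whole compounds.

    Every mixture containing a held-out compound goes to the test set, so no
    test mixture is composed purely of training compounds.  Candidate
    held-out subsets of 1..max_held_out compounds are scored by how close the
    induced test count is to ``test_fraction``; when there are no more than
    ``max_candidates`` such subsets they are all examined, otherwise a seeded
    random sample is drawn.  Fails when the best achievable fraction misses
    the target by more than ``fraction_slack`` (relative).
    """
    compounds = sorted({cid for s in samples for cid in s.compound_ids})
    if len(compounds) < 3:
        raise SplitError("need at least 3 distinct compounds for a compounds-out split")
    target = test_fraction * len(samples)

    all_subsets = [
        tuple(c)
        for size in range(1, max_held_out + 1)
        for c in itertools.combinations(compounds, size)
    ]
    if len(all_subsets) > max_candidates:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(all_subsets), size=max_candidates, replace=False)
        all_subsets = [all_subsets[i] for i in sorted(idx)]

    def score(subset):
        held = set(subset)
        n_test = sum(1 for s in samples if held & set(s.compound_ids))
        return abs(n_test - target), len(subset), subset

    best = min(all_subsets, key=score)
    held = set(best)
    test_ids = [s.sample_id for s in samples if held & set(s.compound_ids)]
    train_ids = [s.sample_id for s in samples if not (held & set(s.compound_ids))]
    achieved = len(test_ids) / len(samples)
    if abs(achieved - test_fraction) > fraction_slack * test_fraction:
        raise SplitError(
            f"no held-out compound subset reaches a test fraction near "
            f"{test_fraction} (best: {achieved:.3f}); try a different fraction"
        )
    return SplitPlan(
        held_out_compounds=sorted(held),
        train_ids=train_ids,
        test_ids=test_ids,
        test_fraction=achieved,
        seed=seed,
    )


# --- Y-randomization --------------------------------------------------------


@dataclass
class YRandSelectionConfig:
    """Descriptor-selection protocol applied to each scrambled response.

    ``mode='ga'`` reruns a (budget-reduced by default) GA at the model's
    subset size; ``mode='refit'`` only refits the already-selected columns.
    Rerunning the full-budget GA per scramble is available by passing the
    training GAConfig explicitly.
    """

    mode: str = "ga"
    k: int = 6
    ga: GAConfig = field(default_factory=lambda: GAConfig(population=30, generations=20))


@dataclass
class YRandomizationReport:
    n_iterations: int
    highest_r2: list[float]
    mhr_r2: float
    sd: float
    model_r2: float
    significant_1pct: bool  # model R2 - mhr R2 > 2.3 SD
    significant_01pct: bool  # model R2 - mhr R2 > 3 SD
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def y_randomization(
    X,
    y,
    model_r2: float,
    n_iter: int = 100,
    selection_cfg: YRandSelectionConfig | None = None,
    seed: int = 0,
    names: list[str] | None = None,
) -> YRandomizationReport:
    """Response-scrambling test for chance correlation.

    Each iteration permutes y, reruns descriptor selection per
    ``selection_cfg`` and records the highest R^2 achieved; the verdicts
    compare the true model's R^2 against the mean highest random R^2 via
    the 2.3 SD / 3 SD rule.
    """
    if n_iter < 2:
        raise ValueError("need at least 2 scrambles")
    cfg = selection_cfg or YRandSelectionConfig()
    Xm, names = _as_matrix(X, names)
    rng = np.random.default_rng(seed)
    highest: list[float] = []
    for it in range(n_iter):
        y_perm = rng.permutation(np.asarray(y, dtype=float))
        if cfg.mode == "refit":
            fit = fit_mlr(Xm, y_perm, names=names)
            highest.append(fit.stats["r2"])
        elif cfg.mode == "ga":
            ga_cfg = GAConfig(**{**asdict(cfg.ga), "seed": seed * 100003 + it})
            res = ga_select(Xm, y_perm, cfg.k, ga_cfg, names=names)
            fit = fit_mlr(Xm[:, res.indices], y_perm, names=res.names)
            highest.append(fit.stats["r2"])
        else:
            raise ValueError(f"unknown Y-randomization mode {cfg.mode!r}")
    arr = np.array(highest)
    mhr = float(arr.mean())
    sd = float(arr.std(ddof=1))
    diff = model_r2 - mhr
    return YRandomizationReport(
        n_iterations=n_iter,
        highest_r2=[float(v) for v in arr],
        mhr_r2=mhr,
        sd=sd,
        model_r2=float(model_r2),
        significant_1pct=diff > 2.3 * sd,
        significant_01pct=diff > 3.0 * sd,
        seed=seed,
    )
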