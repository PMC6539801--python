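"""MLR fitting, leave-one-out cross-validation and GA descriptor selection.

The response model is ordinary least squares on a small subset of descriptor
columns,

    AIT = b0 + sum_j b_j * d_j   (kelvin),

with training statistics R^2, standard error s = sqrt(RSS/(n-p-1)) and the
Fisher ratio F = (R^2/p) / ((1-R^2)/(n-p-1)).  Leave-one-out prediction
errors are obtained from the closed form e_i / (1 - h_ii) (algebraically
identical to refitting without sample i), which keeps the GA fitness —
rmsecv, the root mean square error of cross-validation — cheap enough to
evaluate tens of thousands of candidate subsets.

Subset selection is a fixed-size genetic algorithm (tournament selection,
uniform-union crossover with repair, per-gene mutation, elitism) wrapped in
an incremental search that grows the subset size until rmsecv stops
improving by a relative tolerance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class SingularDesignError(ValueError):
    pass


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters for subset selection."""

    population: int = 100
    generations: int = 200
    crossover_rate: float = 0.7
    mutation_rate: float | None = None  # default 1/k: about one gene swap per child
    tournament: int = 3
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.population, self.generations, self.tournament) < 1:
            raise ValueError("population, generations and tournament must be >= 1")
        if self.elitism < 0 or self.elitism >= self.population:
            raise ValueError("elitism must be in [0, population)")


@dataclass
class QsprModel:
    """A fitted linear mixture-property model on selected descriptors."""

    intercept: float
    coefficients: dict[str, float]
    names: list[str]
    stats: dict[str, float]
    coef_se: dict[str, float] = field(default_factory=dict)
    ga_config: dict | None = None
    train_fingerprint: str | None = None
    ad_summary: dict | None = None  # training cross-product inverse etc.

    @property
    def p(self) -> int:
        return len(self.names)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "QsprModel":
        return cls(**json.loads(Path(path).read_text()))


def _as_matrix(X, names=None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def _design(Xm: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(Xm)), Xm])


def _check_rank(A: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(A)
    if r < A.shape[1]:
        # point at columns whose removal restores full rank
        collinear = []
        for j in range(1, A.shape[1]):
            sub = np.delete(A, j, axis=1)
            if np.linalg.matrix_rank(sub) == r:
                collinear.append(names[j - 1])
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear columns: {collinear}"
        )


def fit_mlr(X, y, names: list[str] | None = None) -> QsprModel:
    """Ordinary least-squares fit with intercept and training statistics."""
    Xm, names = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 residual degrees of freedom (n={n}, p={p})")
    A = _design(Xm)
    _check_rank(A, names)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    dof = n - p - 1
    s = float(np.sqrt(rss / dof))
    f_stat = (r2 / p) / ((1.0 - r2) / dof) if 0 <= r2 < 1 else float("inf")
    q2 = q2_loo(Xm, y)
    xtx_inv = np.linalg.inv(A.T @ A)
    se = np.sqrt(np.maximum(np.diag(xtx_inv), 0.0) * rss / dof)
    return QsprModel(
        intercept=float(beta[0]),
        coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
        names=names,
        stats={"r2": r2, "q2_loo": q2, "s": s, "f": float(f_stat),
               "n_train": n, "rmsecv": rmsecv_loo(Xm, y)},
        coef_se={nm: float(v) for nm, v in zip(names, se[1:])},
        train_fingerprint=matrix_fingerprint(Xm),
    )


def matrix_fingerprint(X) -> str:
    Xm, _ = _as_matrix(X)
    return hashlib.sha256(np.ascontiguousarray(Xm).tobytes()).hexdigest()[:16]


def loo_residuals(X, y) -> np.ndarray:
    """Leave-one-out prediction residuals y_i - yhat_(-i).

    Uses the hat-matrix identity e_i/(1-h_ii), exactly equal to refitting
    the model n times with one sample deleted.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 for leave-one-out (n={n}, p={p})")
    A = _design(Xm)
    Q, R = np.linalg.qr(A)
    if np.min(np.abs(np.diag(R))) < 1e-10 * max(1.0, np.max(np.abs(R))):
        raise SingularDesignError("singular design in leave-one-out fit")
    h = np.sum(Q * Q, axis=1)
    resid = y - A @ np.linalg.solve(R, Q.T @ y)
    denom = 1.0 - h
    if np.any(denom <= 1e-12):
        raise SingularDesignError("a leave-one-out fold has leverage 1 (singular fold)")
    return resid / denom


def rmsecv_loo(X, y) -> float:
    """Root mean square error of leave-one-out cross-validation (kelvin)."""
    r = loo_residuals(X, y)
    return float(np.sqrt(np.mean(r * r)))


def q2_loo(X, y) -> float:
    """Leave-one-out predictive squared correlation,
    1 - PRESS / sum (y - ybar)^2."""
    y = np.asarray(y, dtype=float)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        raise ValueError("constant response: Q2_LOO denominator is zero")
    r = loo_residuals(X, y)
    return 1.0 - float(r @ r) / tss


def predict(model: QsprModel, X) -> np.ndarray:
    """Apply the fitted linear model; errors if a selected column is absent."""
    if isinstance(X, pd.DataFrame):
        missing = [nm for nm in model.names if nm not in X.columns]
        if missing:
            raise KeyError(f"descriptor columns missing from input: {missing}")
        Xm = X[model.names].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.shape[1] != model.p:
            raise ValueError(f"expected {model.p} columns, got {Xm.shape[1]}")
    beta = np.array([model.coefficients[nm] for nm in model.names])
    return model.intercept + Xm @ beta


@dataclass
class MeanEffectReport:
    """Signed percent-scaled descriptor contributions, summing to 100."""

    effects: dict[str, float]

    def ranked(self) -> list[str]:
        return sorted(self.effects, key=lambda nm: -abs(self.effects[nm]))


def mean_effects(model: QsprModel, X_train, centered: bool = False) -> MeanEffectReport:
    """Mean effect of each descriptor:
    ME_j = 100 * beta_j * sum_i d_ij / sum_k beta_k * sum_i d_ik.

    The ``centered`` variant replaces the raw column sums by sums of
    absolute deviations from the column mean, weighting each descriptor by
    the variability it contributes rather than by its level (the raw sums
    of a centred column are identically zero, so literal centring is
    degenerate).  Default is raw.
    """
    if isinstance(X_train, pd.DataFrame):
        Xm = X_train[model.names].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X_train, dtype=float)
    beta = np.array([model.coefficients[nm] for nm in model.names])
    if centered:
        contrib = beta * np.abs(Xm - Xm.mean(axis=0)).sum(axis=0)
    else:
        contrib = beta * Xm.sum(axis=0)
    denom = contrib.sum()
    if abs(denom) < 1e-12:
        raise ZeroDivisionError("mean-effect denominator is zero")
    return MeanEffectReport(
        effects={nm: float(100.0 * c / denom) for nm, c in zip(model.names, contrib)}
    )


# --- GA subset selection ----------------------------------------------------


def _loo_press_fast(A: np.ndarray, y: np.ndarray) -> float:
    """PRESS/n -> rmsecv for an already-built design matrix; inf when any
    fold is singular (such subsets are simply unfit)."""
    Q, R = np.linalg.qr(A)
    if np.min(np.abs(np.diag(R))) < 1e-10 * max(1.0, np.max(np.abs(R))):
        return float("inf")
    h = np.sum(Q * Q, axis=1)
    denom = 1.0 - h
    if np.any(denom <= 1e-12):
        return float("inf")
    resid = y - A @ np.linalg.solve(R, Q.T @ y)
    r = resid / denom
    return float(np.sqrt(np.mean(r * r)))


@dataclass
class GAResult:
    names: list[str]
    indices: tuple[int, ...]
    rmsecv: float
    evaluations: int


def ga_select(X, y, k: int, cfg: GAConfig | None = None,
              names: list[str] | None = None,
              initial: list[tuple[int, ...]] | None = None) -> GAResult:
    """Search for the k-descriptor subset minimising rmsecv.

    Deterministic for a fixed seed.  Fitness ties break on the
    lexicographically smallest name subset so reruns cannot flip between
    equivalent optima.  ``initial`` seeds part of the starting population
    with known-good individuals (the incremental search passes extensions
    of the best smaller subset); the rest is random.
    """
    cfg = cfg or GAConfig()
    Xm, names = _as_matrix(X, names)
    n, ncols = Xm.shape
    if k < 1 or k >= ncols:
        raise ValueError(f"subset size k={k} infeasible for {ncols} columns")
    if 5 * k > n:
        raise ValueError(f"k={k} risks overfitting with only n={n} samples "
                         "(need 5*k <= n)")
    rng = np.random.default_rng(cfg.seed)
    pm = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / k
    ones = np.ones((n, 1))

    cache: dict[tuple[int, ...], float] = {}

    def fitness(ind: tuple[int, ...]) -> float:
        val = cache.get(ind)
        if val is None:
            A = np.concatenate([ones, Xm[:, ind]], axis=1)
            val = _loo_press_fast(A, y)
            cache[ind] = val
        return val

    def sort_key(ind: tuple[int, ...]):
        return (fitness(ind), tuple(names[j] for j in ind))

    def random_ind() -> tuple[int, ...]:
        return tuple(sorted(rng.choice(ncols, size=k, replace=False).tolist()))

    pop = []
    if initial:
        for ind in initial:
            ind = tuple(sorted(set(int(j) for j in ind)))
            if len(ind) == k and all(0 <= j < ncols for j in ind):
                pop.append(ind)
        pop = pop[: cfg.population // 2]
    while len(pop) < cfg.population:
        pop.append(random_ind())
    best = min(pop, key=sort_key)

    for _ in range(cfg.generations):
        new_pop: list[tuple[int, ...]] = sorted(set(pop), key=sort_key)[: cfg.elitism]
        while len(new_pop) < cfg.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = [pop[i] for i in rng.integers(0, len(pop), cfg.tournament)]
                parents.append(min(contenders, key=sort_key))
            child = list(parents[0])
            if rng.random() < cfg.crossover_rate:
                shared = sorted(set(parents[0]) & set(parents[1]))
                pool = sorted(set(parents[0]) ^ set(parents[1]))
                need = k - len(shared)
                picks = rng.choice(len(pool), size=need, replace=False) if need else []
                child = shared + [pool[i] for i in picks]
            # per-gene mutation with repair to keep genes distinct
            members = set(child)
            for pos in range(k):
                if rng.random() < pm:
                    repl = int(rng.integers(0, ncols))
                    while repl in members:
                        repl = int(rng.integers(0, ncols))
                    members.discard(child[pos])
                    child[pos] = repl
                    members.add(repl)
            new_pop.append(tuple(sorted(child)))
        pop = new_pop
        gen_best = min(pop, key=sort_key)
        if sort_key(gen_best) < sort_key(best):
            best = gen_best

    return GAResult(
        names=[names[j] for j in best],
        indices=best,
        rmsecv=fitness(best),
        evaluations=len(cache),
    )


def incremental_subset_search(
    X,
    y,
    cfg: GAConfig | None = None,
    k_max: int = 8,
    tol: float = 0.02,
    names: list[str] | None = None,
) -> QsprModel:
    """Grow the subset size 1, 2, ... until rmsecv stops improving.

    Stops at the first k whose relative rmsecv improvement over k-1 falls
    below ``tol`` (the model at k-1, the elbow, is returned) or at
    ``k_max``.  ``tol = 0`` runs to ``k_max``.  Each size-k population is
    seeded with one-column extensions of the best (k-1)-subset, so the
    search refines rather than restarts as the subset grows.
    """
    cfg = cfg or GAConfig()
    Xm, names = _as_matrix(X, names)
    n, ncols = Xm.shape
    if 5 * k_max > n:
        k_max = max(1, n // 5)
    history: list[GAResult] = []
    chosen: GAResult | None = None
    seed_rng = np.random.default_rng(cfg.seed)
    for k in range(1, k_max + 1):
        sub_cfg = GAConfig(**{**asdict(cfg), "seed": cfg.seed + k})
        initial = None
        if history:
            base = set(history[-1].indices)
            extras = seed_rng.permutation([j for j in range(ncols) if j not in base])
            initial = [tuple(sorted(base | {int(j)})) for j in extras[: cfg.population // 2]]
        res = ga_select(Xm, y, k, sub_cfg, names=names, initial=initial)
        if history:
            prev = history[-1].rmsecv
            improvement = (prev - res.rmsecv) / prev if prev > 0 else 0.0
            if improvement < tol:
                chosen = history[-1]
                break
        history.append(res)
    if chosen is None:
        chosen = history[-1]
    model = fit_mlr(Xm[:, chosen.indices], y, names=chosen.names)
    model.ga_config = asdict(cfg)
    model.stats["k_search_rmsecv"] = chosen.rmsecv
    return model
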