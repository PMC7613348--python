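"""Regression between input and output PCA score spaces.

Kernel ridge regression (KRR) with a Gaussian RBF kernel is the default and
the only regressor required for emulation; a small registry lets alternative
regressors plug in behind the same fit/predict surface.

KRR solves ``(K + lambda I) A = Y`` once for all output columns, so the
multi-output model is trained in a single factorization. Input scores are
standardized per feature before the kernel; output scores are regressed as
they are (PCA scores are already commensurate). Both the regularization
``lambda`` and the kernel length-scale ``sigma`` are tuned by grid search
with k-fold cross-validation; ties prefer the smaller ``lambda``, then the
smaller ``sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.spatial.distance import cdist

from .errors import ArgumentError, NumericalError, ShapeError

_DEFAULT_LAMBDAS = tuple(np.logspace(-8, 1, 10))
_DEFAULT_SIGMA_MULTIPLIERS = (0.25, 0.5, 1.0, 2.0, 4.0)

# fixed prediction block: every kernel/GEMM call sees identical shapes no
# matter how callers chunk their pixels, keeping outputs bit-reproducible
_PREDICT_BLOCK = 256


@dataclass
class RegressorSpec:
    """What to fit and how to tune it."""

    method: str = "krr"
    kernel: str = "rbf"                      # "rbf" | "linear"
    lambda_grid: tuple = _DEFAULT_LAMBDAS
    sigma_grid: tuple | None = None          # None -> median heuristic x multipliers
    sigma_multipliers: tuple = _DEFAULT_SIGMA_MULTIPLIERS
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lambda_grid) == 0:
            raise ArgumentError("lambda grid must be non-empty")
        if self.sigma_grid is not None and len(self.sigma_grid) == 0:
            raise ArgumentError("sigma grid must be non-empty")
        if self.folds < 2:
            raise ArgumentError("cross-validation needs at least 2 folds")


@dataclass
class KRRModel:
    X_train: np.ndarray       # [n, p_in], standardized
    x_mean: np.ndarray        # [p_in]
    x_scale: np.ndarray       # [p_in]
    A: np.ndarray             # dual coefficients [n, p_out]
    sigma: float
    lam: float
    kernel: str = "rbf"
    cv_table: pd.DataFrame | None = field(default=None, repr=False)


def rbf_kernel(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel ``K[i, j] = exp(-|a_i - b_j|^2 / (2 sigma^2))``."""
    if sigma <= 0:
        raise ArgumentError("sigma must be positive")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ShapeError("kernel operands have different feature counts")
    d2 = cdist(A, B, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma * sigma))


def _kernel(A: np.ndarray, B: np.ndarray, kernel: str, sigma: float) -> np.ndarray:
    if kernel == "rbf":
        return rbf_kernel(A, B, sigma)
    if kernel == "linear":
        return np.atleast_2d(A) @ np.atleast_2d(B).T
    raise ArgumentError(f"unknown kernel '{kernel}'")


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return mean, scale


def median_heuristic_sigma(X: np.ndarray, seed: int = 0, max_rows: int = 512) -> float:
    """Median pairwise distance of (a subsample of) the rows of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] > max_rows:
        idx = np.sort(np.random.default_rng(seed).choice(X.shape[0], max_rows,
                                                         replace=False))
        X = X[idx]
    d = cdist(X, X)
    med = float(np.median(d[np.triu_indices_from(d, k=1)])) if X.shape[0] > 1 else 0.0
    return med if med > 0 else 1.0


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    order = np.random.default_rng(seed).permutation(n)
    return [np.sort(order[i::folds]) for i in range(folds)]


def tune_hyperparameters(X: np.ndarray, Y: np.ndarray, spec: RegressorSpec
                         ) -> tuple[float, float, pd.DataFrame]:
    """Grid-search CV over (lambda, sigma); returns the winner and the full table.

    The fold assignment is deterministic from ``spec.seed``. For each sigma
    the full kernel is built once and each training fold eigendecomposed
    once; all lambdas then reuse the factorization, so the lambda sweep is
    nearly free.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = X.shape[0]
    if n < spec.folds:
        raise ArgumentError(f"need at least folds={spec.folds} samples, got {n}")
    x_mean, x_scale = _standardize_fit(X)
    Xs = (X - x_mean) / x_scale

    lambdas = np.sort(np.unique(np.asarray(spec.lambda_grid, dtype=float)))
    if spec.kernel == "linear":
        sigmas = np.array([1.0])
    elif spec.sigma_grid is not None:
        sigmas = np.sort(np.unique(np.asarray(spec.sigma_grid, dtype=float)))
    else:
        med = median_heuristic_sigma(Xs, seed=spec.seed)
        sigmas = np.sort(med * np.asarray(spec.sigma_multipliers, dtype=float))

    folds = _fold_indices(n, spec.folds, spec.seed)
    records = []
    mse = np.full((lambdas.size, sigmas.size), np.inf)
    for j, sigma in enumerate(sigmas):
        K = _kernel(Xs, Xs, spec.kernel, float(sigma))
        fold_mse = np.zeros((lambdas.size, len(folds)))
        for f, val_idx in enumerate(folds):
            tr_idx = np.setdiff1d(np.arange(n), val_idx, assume_unique=False)
            K_tr = K[np.ix_(tr_idx, tr_idx)]
            K_val = K[np.ix_(val_idx, tr_idx)]
            evals, V = eigh(K_tr)
            VtY = V.T @ Y[tr_idx]
            KvV = K_val @ V
            for i, lam in enumerate(lambdas):
                pred = KvV @ (VtY / (evals + lam)[:, None])
                fold_mse[i, f] = float(np.mean((pred - Y[val_idx]) ** 2))
        mse[:, j] = fold_mse.mean(axis=1)
        for i, lam in enumerate(lambdas):
            records.append({"lambda": float(lam), "sigma": float(sigma),
                            "cv_mse": float(mse[i, j])})
    # iterate in (lambda, sigma) sorted order so exact ties resolve to the
    # smallest lambda, then smallest sigma — independent of input grid order
    best_i, best_j = 0, 0
    best = np.inf
    for i in range(lambdas.size):
        for j in range(sigmas.size):
            if mse[i, j] < best:
                best, best_i, best_j = mse[i, j], i, j
    table = pd.DataFrame.from_records(records)
    return float(lambdas[best_i]), float(sigmas[best_j]), table


def fit_krr(X: np.ndarray, Y: np.ndarray, spec: RegressorSpec | None = None) -> KRRModel:
    """Fit a (multi-output) KRR model, tuning hyperparameters if the grid has
    more than one cell."""
    spec = spec or RegressorSpec()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ArgumentError("non-finite entries in training data")
    if X.shape[0] != Y.shape[0]:
        raise ShapeError("X and Y row counts differ")

    single_lambda = len(set(map(float, spec.lambda_grid))) == 1
    single_sigma = (spec.kernel == "linear") or (
        spec.sigma_grid is not None and len(set(map(float, spec.sigma_grid))) == 1
    )
    cv_table = None
    if single_lambda and single_sigma:
        lam = float(spec.lambda_grid[0])
        sigma = 1.0 if spec.kernel == "linear" else float(spec.sigma_grid[0])
    else:
        lam, sigma, cv_table = tune_hyperparameters(X, Y, spec)

    x_mean, x_scale = _standardize_fit(X)
    Xs = (X - x_mean) / x_scale
    K = _kernel(Xs, Xs, spec.kernel, sigma)
    try:
        c = cho_factor(K + lam * np.eye(K.shape[0]), lower=True)
        A = cho_solve(c, Y)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"KRR system singular beyond regularization (lambda={lam}, sigma={sigma})"
        ) from exc
    return KRRModel(X_train=Xs, x_mean=x_mean, x_scale=x_scale, A=A,
                    sigma=sigma, lam=lam, kernel=spec.kernel, cv_table=cv_table)


def predict_krr(model: KRRModel, X_new: np.ndarray) -> np.ndarray:
    """Predict output scores ``k(X_new, X_train) A`` for new input scores."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ShapeError(
            f"expected {model.X_train.shape[1]} features, got {X_new.shape[1]}"
        )
    Xs = (X_new - model.x_mean) / model.x_scale
    m = Xs.shape[0]
    out = np.empty((m, model.A.shape[1]))
    # pad the trailing partial block to _PREDICT_BLOCK rows so every matmul
    # has the same shape regardless of how the caller batched the pixels
    for start in range(0, m, _PREDICT_BLOCK):
        block = Xs[start:start + _PREDICT_BLOCK]
        nb = block.shape[0]
        if nb < _PREDICT_BLOCK:
            block = np.vstack([block, np.tile(Xs[-1:], (_PREDICT_BLOCK - nb, 1))])
        K = _kernel(block, model.X_train, model.kernel, model.sigma)
        out[start:start + nb] = (K @ model.A)[:nb]
    return out


class KernelRidgeRegressor:
    """Registry adapter giving KRR the generic fit/predict surface."""

    name = "krr"
    multi_output = True

    def __init__(self, spec: RegressorSpec | None = None) -> None:
        self.spec = spec or RegressorSpec()
        self.model: KRRModel | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "KernelRidgeRegressor":
        self.model = fit_krr(X, Y, self.spec)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise ArgumentError("regressor is not fitted")
        return predict_krr(self.model, X)

    # --- serialization hooks used by the emulator container ---
    def to_arrays(self) -> dict[str, np.ndarray]:
        m = self.model
        if m is None:
            raise ArgumentError("regressor is not fitted")
        return {
            "X_train": m.X_train, "x_mean": m.x_mean, "x_scale": m.x_scale,
            "A": m.A, "sigma": np.array(m.sigma), "lam": np.array(m.lam),
        }

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray],
                    spec: RegressorSpec) -> "KernelRidgeRegressor":
        reg = cls(spec)
        reg.model = KRRModel(
            X_train=arrays["X_train"], x_mean=arrays["x_mean"],
            x_scale=arrays["x_scale"], A=arrays["A"],
            sigma=float(arrays["sigma"]), lam=float(arrays["lam"]),
            kernel=spec.kernel,
        )
        return reg


class PerOutputLoop:
    """Trains one single-output copy of a regressor per output component.

    Used automatically when a registered regressor does not support
    multi-output training; KRR never needs it (one factorization serves all
    outputs), but plugins may.
    """

    name = "per-output-loop"
    multi_output = True

    def __init__(self, spec: RegressorSpec) -> None:
        self.spec = spec
        self.members: list = []

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "PerOutputLoop":
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        self.members = []
        for j in range(Y.shape[1]):
            member = get_regressor(self.spec)
            member.fit(X, Y[:, j:j + 1])
            self.members.append(member)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.members:
            raise ArgumentError("regressor is not fitted")
        return np.hstack([m.predict(X) for m in self.members])

    def to_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {"loop_n": np.array(len(self.members))}
        for j, member in enumerate(self.members):
            for key, arr in member.to_arrays().items():
                out[f"m{j}_{key}"] = arr
        return out

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray],
                    spec: RegressorSpec) -> "PerOutputLoop":
        loop = cls(spec)
        n = int(arrays["loop_n"])
        member_cls = REGISTRY[spec.method]
        for j in range(n):
            prefix = f"m{j}_"
            sub = {k[len(prefix):]: v for k, v in arrays.items()
                   if k.startswith(prefix)}
            loop.members.append(member_cls.from_arrays(sub, spec))
        return loop


REGISTRY: dict[str, type] = {"krr": KernelRidgeRegressor}


def get_regressor(spec: RegressorSpec):
    try:
        cls = REGISTRY[spec.method]
    except KeyError as exc:
        raise ArgumentError(
            f"unknown regressor '{spec.method}'; registered: {sorted(REGISTRY)}"
        ) from exc
    return cls(spec)
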