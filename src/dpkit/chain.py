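"""Multi-target regressor chains with L1/L2-regularized linear bases.

Predicting a 60-shell scaled DPK from 13 physical/chemical features is a
multi-target regression problem whose targets are strongly coupled
(neighbouring shells carry most of the information about each other).  A
*regressor chain* exploits this: model M_1 maps the features X to the
first target y_1; model M_i maps X plus targets y_1..y_{i-1} to y_i.
Training uses the *observed* previous targets; prediction cascades the
models, feeding each its predecessors' predictions.

Three base objectives are available (w is the coefficient vector, the
intercept is never penalized):

* ridge:       min_w ||Xw - y||^2 + alpha*||w||_2^2            (closed form)
* lasso:       min_w (1/2n)||Xw - y||^2 + alpha*||w||_1        (coordinate descent)
* elasticnet:  min_w (1/2n)||Xw - y||^2 + gamma*alpha*||w||_1
               + alpha*(1-gamma)/2*||w||_2^2                    (coordinate descent)

so elasticnet with gamma=1 is exactly the lasso and gamma=0 is a ridge
up to the 1/(2n) quadratic scaling.  Coordinate descent sweeps columns
in fixed cyclic order from a zero start and stops when the largest
coefficient update falls below ``tol`` (default 1e-6) or after
``max_sweeps`` (default 1e4) sweeps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .emulator import FEATURE_COLUMNS, TARGET_COLUMNS
from .kernels import ScaledDPK, ShellGrid

__all__ = [
    "BASES",
    "FitConfig",
    "BaseModel",
    "ChainModel",
    "MetricReport",
    "fit_base_linear",
    "fit_chain",
    "predict_chain",
    "predictions_to_sdpk",
    "regression_metrics",
    "tune_chain",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_GAMMA_GRID",
    "save_chain",
    "load_chain",
]

BASES = ("ridge", "lasso", "elasticnet")

DEFAULT_ALPHA_GRID = tuple(10.0 ** np.arange(-4, 2))  # 1e-4 .. 1e1, 6 points
DEFAULT_GAMMA_GRID = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class FitConfig:
    """Base-regressor settings shared by every link of the chain."""

    base: str = "ridge"
    alpha: float = 1.0
    gamma: float = 0.5  # L1 mixing, elasticnet only
    standardize: bool = True
    seed: int = 0
    tol: float = 1e-6
    max_sweeps: int = 10_000

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise ValueError(f"base must be one of {BASES}, got {self.base!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")


@dataclass(frozen=True)
class BaseModel:
    """One fitted linear link: coefficients + unpenalized intercept."""

    coef: np.ndarray
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept


def _soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _cd_kernel(G, c, gdiag, n, l1, l2, tol, max_sweeps):
    """Cyclic coordinate descent on the covariance form (G = X'X, c = X'y).

    Alternates one full cyclic sweep with sweeps over the active
    (nonzero) set, the usual pathwise strategy; stops when the largest
    coefficient update in a full sweep falls below ``tol``.
    """
    p = G.shape[0]
    w = np.zeros(p)
    Gw = np.zeros(p)  # G @ w, maintained incrementally
    sweeps = 0
    active_only = False
    while sweeps < max_sweeps:
        max_delta = 0.0
        for j in range(p):
            if active_only and w[j] == 0.0:
                continue
            denom = gdiag[j] / n + l2
            if denom <= 0.0:
                continue
            rho = (c[j] - Gw[j] + gdiag[j] * w[j]) / n
            if rho > l1:
                w_new = (rho - l1) / denom
            elif rho < -l1:
                w_new = (rho + l1) / denom
            else:
                w_new = 0.0
            delta = w_new - w[j]
            if delta != 0.0:
                Gw += G[:, j] * delta
                w[j] = w_new
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        sweeps += 1
        if max_delta < tol:
            if active_only:
                active_only = False
                continue
            break
        active_only = True
    return w


try:  # JIT-compile the hot solver loop when numba is around
    from numba import njit

    _cd_kernel = njit(cache=True)(_cd_kernel)
except ImportError:  # pragma: no cover
    pass


def _coordinate_descent(
    Xc: np.ndarray, yc: np.ndarray, l1: float, l2: float, tol: float, max_sweeps: int
) -> np.ndarray:
    n = Xc.shape[0]
    G = Xc.T @ Xc
    c = Xc.T @ yc
    return _cd_kernel(
        np.ascontiguousarray(G), c, np.ascontiguousarray(np.diag(G)),
        float(n), float(l1), float(l2), float(tol), int(max_sweeps),
    )


def fit_base_linear(X: np.ndarray, y: np.ndarray, config: FitConfig) -> BaseModel:
    """Fit one regularized linear model per the configured objective."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) and y (n,) with matching n")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in inputs")

    mu = X.mean(axis=0)
    if config.standardize:
        sd = X.std(axis=0)
        sd[sd == 0.0] = 1.0
    else:
        sd = np.ones(X.shape[1])
    Xs = (X - mu) / sd
    ybar = y.mean()
    yc = y - ybar

    n, p = Xs.shape
    if config.base == "ridge":
        if config.alpha == 0.0:
            # plain least squares; minimum-norm solution tolerates the
            # exactly collinear designs chained targets can produce
            w = np.linalg.lstsq(Xs, yc, rcond=None)[0]
        else:
            G = Xs.T @ Xs + config.alpha * np.eye(p)
            w = np.linalg.solve(G, Xs.T @ yc)
    else:
        gamma = 1.0 if config.base == "lasso" else config.gamma
        l1 = config.alpha * gamma
        l2 = config.alpha * (1.0 - gamma)
        w = _coordinate_descent(Xs, yc, l1, l2, config.tol, config.max_sweeps)

    coef = w / sd
    intercept = ybar - float(coef @ mu)
    return BaseModel(coef=coef, intercept=intercept)


@dataclass
class ChainModel:
    """An ordered chain of fitted base models plus standardization state.

    ``mu``/``sigma`` are training-set statistics over the augmented
    column set (features followed by targets-as-features); model i
    consumes the first ``n_features + i - 1`` standardized columns.
    """

    models: list[BaseModel]
    feature_names: tuple[str, ...]
    target_names: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray
    config: FitConfig

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_targets(self) -> int:
        return len(self.target_names)


def _split_xy(dataset: pd.DataFrame | tuple) -> tuple[np.ndarray, np.ndarray, tuple, tuple]:
    if isinstance(dataset, pd.DataFrame):
        feats = [c for c in FEATURE_COLUMNS if c in dataset.columns]
        targs = [c for c in TARGET_COLUMNS if c in dataset.columns]
        if len(feats) != len(FEATURE_COLUMNS) or not targs:
            raise ValueError(
                "dataset must carry the 13 feature columns and the target columns"
            )
        return (
            dataset[feats].to_numpy(float),
            dataset[targs].to_numpy(float),
            tuple(feats),
            tuple(targs),
        )
    X, Y = dataset
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    fnames = tuple(f"x{i}" for i in range(X.shape[1]))
    tnames = tuple(f"y{i}" for i in range(Y.shape[1]))
    return X, Y, fnames, tnames


def fit_chain(dataset, config: FitConfig) -> ChainModel:
    """Train the chain on observed targets (cascade happens at predict time)."""
    X, Y, fnames, tnames = _split_xy(dataset)
    if Y.shape[1] < 1:
        raise ValueError("need at least one target")
    A = np.hstack([X, Y[:, :-1]]) if Y.shape[1] > 1 else X.copy()
    mu = A.mean(axis=0)
    if config.standardize:
        sigma = A.std(axis=0)
        sigma[sigma == 0.0] = 1.0
    else:
        sigma = np.ones(A.shape[1])
    As = (A - mu) / sigma
    inner = FitConfig(
        base=config.base,
        alpha=config.alpha,
        gamma=config.gamma,
        standardize=False,  # chain standardizes once, globally
        seed=config.seed,
        tol=config.tol,
        max_sweeps=config.max_sweeps,
    )
    p0 = X.shape[1]
    models = [
        fit_base_linear(As[:, : p0 + i], Y[:, i], inner) for i in range(Y.shape[1])
    ]
    return ChainModel(
        models=models,
        feature_names=fnames,
        target_names=tnames,
        mu=mu,
        sigma=sigma,
        config=config,
    )


def predict_chain(model: ChainModel, features) -> np.ndarray:
    """Cascaded prediction: each link receives the previous links' outputs.

    ``features`` may be an (n, p) array in the fitted column order or a
    DataFrame carrying the fitted feature columns (order is checked).
    """
    if isinstance(features, pd.DataFrame):
        present = [c for c in features.columns if c in model.feature_names]
        if tuple(present) != model.feature_names:
            raise ValueError(
                f"feature columns {tuple(present)} do not match the fitted order "
                f"{model.feature_names}"
            )
        X = features[list(model.feature_names)].to_numpy(float)
    else:
        X = np.asarray(features, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != model.n_features:
            raise ValueError(
                f"expected {model.n_features} feature columns, got {X.shape[1]}"
            )
    n = X.shape[0]
    k = model.n_targets
    p0 = model.n_features
    A = np.empty((n, p0 + k - 1)) if k > 1 else np.empty((n, p0))
    A[:, :p0] = X
    preds = np.empty((n, k))
    for i, m in enumerate(model.models):
        cols = p0 + i
        As = (A[:, :cols] - model.mu[:cols]) / model.sigma[:cols]
        preds[:, i] = m.predict(As)
        if i < k - 1:
            A[:, p0 + i] = preds[:, i]
    return preds


def predictions_to_sdpk(
    model: ChainModel, features, material_labels=None, energies_kev=None
) -> list[ScaledDPK]:
    """Wrap chain predictions as physical kernels (negatives clipped to 0)."""
    raw = np.clip(predict_chain(model, features), 0.0, None)
    grid = ShellGrid(n_shells=model.n_targets)
    out = []
    for i, row in enumerate(raw):
        out.append(
            ScaledDPK(
                grid=grid,
                values=row,
                material_label="" if material_labels is None else material_labels[i],
                energy0_kev=None if energies_kev is None else float(energies_kev[i]),
                scale="r0",
            )
        )
    return out


@dataclass(frozen=True)
class MetricReport:
    """Pooled fit metrics plus a per-target breakdown."""

    r2: float
    rmse: float
    mape: float  # percent
    per_target: pd.DataFrame

    def __repr__(self) -> str:  # keep the frame out of logs
        return f"MetricReport(r2={self.r2:.4f}, rmse={self.rmse:.4g}, mape={self.mape:.2f}%)"


def _r2(y, yp) -> float:
    ss_res = float(np.sum((y - yp) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)


def regression_metrics(y_true, y_pred) -> MetricReport:
    """Pooled R², RMSE and MAPE (percent, over nonzero truths)."""
    y = np.asarray(y_true, float)
    yp = np.asarray(y_pred, float)
    if y.shape != yp.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {yp.shape}")
    if y.ndim == 1:
        y = y[:, None]
        yp = yp[:, None]
    nz = y != 0
    if not nz.any():
        raise ValueError("MAPE undefined: every true value is zero")
    pooled_r2 = _r2(y.ravel(), yp.ravel())
    rmse = float(np.sqrt(np.mean((y - yp) ** 2)))
    mape = float(100.0 * np.mean(np.abs((y - yp)[nz] / y[nz])))
    rows = []
    for j in range(y.shape[1]):
        col_nz = nz[:, j]
        rows.append(
            {
                "target": j,
                "r2": _r2(y[:, j], yp[:, j]),
                "rmse": float(np.sqrt(np.mean((y[:, j] - yp[:, j]) ** 2))),
                "mape": float(
                    100.0 * np.mean(np.abs((y[col_nz, j] - yp[col_nz, j]) / y[col_nz, j]))
                )
                if col_nz.any()
                else np.nan,
            }
        )
    return MetricReport(pooled_r2, rmse, mape, pd.DataFrame(rows))


def tune_chain(
    dataset,
    base: str,
    alphas=DEFAULT_ALPHA_GRID,
    gammas=DEFAULT_GAMMA_GRID,
    val_fraction: float = 0.2,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[FitConfig, pd.DataFrame]:
    """Grid-search alpha (and gamma for elasticnet) on a random validation split.

    Selection is by pooled RMSE of cascaded predictions on the held-out
    20%; returns the winning config (to be refit on the full data) and
    the full search table.
    """
    X, Y, _, _ = _split_xy(dataset)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val, tr = perm[:n_val], perm[n_val:]
    grid = [(a, g) for a in alphas for g in (gammas if base == "elasticnet" else (1.0,))]
    rows = []
    best = None
    for alpha, gamma in grid:
        cfg = FitConfig(base=base, alpha=float(alpha), gamma=float(gamma),
                        standardize=standardize, seed=seed)
        model = fit_chain((X[tr], Y[tr]), cfg)
        pred = predict_chain(model, X[val])
        rmse = float(np.sqrt(np.mean((Y[val] - pred) ** 2)))
        rows.append({"alpha": alpha, "gamma": gamma, "val_rmse": rmse})
        if best is None or rmse < best[0]:
            best = (rmse, cfg)
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence: exact-roundtrip JSON
# ---------------------------------------------------------------------------

def save_chain(path, model: ChainModel) -> None:
    doc = {
        "config": asdict(model.config),
        "feature_names": list(model.feature_names),
        "target_names": list(model.target_names),
        "mu": model.mu.tolist(),
        "sigma": model.sigma.tolist(),
        "models": [
            {"coef": m.coef.tolist(), "intercept": m.intercept} for m in model.models
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_chain(path) -> ChainModel:
    with open(path) as fh:
        doc = json.load(fh)
    return ChainModel(
        models=[
            BaseModel(np.asarray(m["coef"], float), float(m["intercept"]))
            for m in doc["models"]
        ],
        feature_names=tuple(doc["feature_names"]),
        target_names=tuple(doc["target_names"]),
        mu=np.asarray(doc["mu"], float),
        sigma=np.asarray(doc["sigma"], float),
        config=FitConfig(**doc["config"]),
    )
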