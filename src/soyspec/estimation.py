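"""Nitrogen estimation models and the layer x combination x model grid.

Three regressors are fit per screened combination and leaf layer:

* PLSR with the latent-variable count chosen by 10-fold cross-validated
  RMSE (features z-scored on the modeling set);
* a 600-tree random forest on raw features;
* a single-hidden-layer network (15 tanh units, linear output) trained
  by Levenberg-Marquardt on the full modeling batch, with features and
  target z-scored.

The reported determination coefficient defaults to the ratio convention
R2 = sum((yhat - ybar)^2) / sum((y - ybar)^2) with ybar the observed
mean; it equals the squared correlation for least-squares fits but may
exceed 1 for biased predictors.  A ``r2_form="conventional"`` switch
gives 1 - SSE/SST instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .core import LAYERS, ParameterMatrix
from .screening import CombinationSpec, layer_target

logger = logging.getLogger(__name__)

MODELS = ("PLSR", "RF", "BPNN")


@dataclass
class SplitSpec:
    """Disjoint modeling/validation sample-id sets from one seeded draw."""

    modeling_ids: list[str]
    validation_ids: list[str]
    seed: int


def split_modeling_validation(
    sample_ids: list[str], fraction: float = 2.0 / 3.0, seed: int = 0
) -> SplitSpec:
    """Uniform seeded split; modeling size = round(fraction * n)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    ids = list(sample_ids)
    if len(ids) < 6:
        raise ValueError("need at least 6 samples to split")
    k = int(round(fraction * len(ids)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    modeling = [ids[i] for i in sorted(perm[:k])]
    validation = [ids[i] for i in sorted(perm[k:])]
    return SplitSpec(modeling, validation, seed)


class _Standardizer:
    """Column z-scoring fit on the modeling set (zero-variance safe)."""

    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_


class PLSRPredictor:
    def __init__(self, scaler, model, n_components, y_const=None):
        self.scaler = scaler
        self.model = model
        self.n_components = n_components
        self.y_const = y_const

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.y_const is not None:
            return np.full(X.shape[0], self.y_const)
        return self.model.predict(self.scaler.transform(X)).ravel()


def _effective_rank(X: np.ndarray) -> int:
    if X.size == 0:
        return 0
    s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    return int((s > tol).sum())


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 10,
    cv_folds: int = 10,
    seed: int = 0,
) -> PLSRPredictor:
    """PLS regression; latent-variable count minimizes 10-fold CV RMSE."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X and y must align")
    if np.ptp(y) == 0:
        return PLSRPredictor(None, None, 0, y_const=float(y[0]))
    scaler = _Standardizer().fit(X)
    Z = scaler.transform(X)
    cap = min(max_lv, X.shape[1], _effective_rank(Z), X.shape[0] - 1)
    cap = max(cap, 1)
    folds = min(cv_folds, X.shape[0])
    best_k, best_rmse = 1, np.inf
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Z))
    with warnings.catch_warnings():
        # "y residual is constant" fires on exact fits; not actionable here
        warnings.filterwarnings("ignore", message="y residual is constant")
        for k in range(1, cap + 1):
            sse, cnt = 0.0, 0
            for tr, te in splits:
                k_eff = min(k, _effective_rank(Z[tr]), len(tr) - 1)
                if k_eff < 1:
                    continue
                m = PLSRegression(n_components=k_eff, scale=False)
                m.fit(Z[tr], y[tr])
                pred = m.predict(Z[te]).ravel()
                sse += float(((pred - y[te]) ** 2).sum())
                cnt += len(te)
            rmse = np.sqrt(sse / cnt) if cnt else np.inf
            if rmse < best_rmse - 1e-12:
                best_rmse, best_k = rmse, k
        model = PLSRegression(n_components=best_k, scale=False)
        model.fit(Z, y)
    return PLSRPredictor(scaler, model, best_k)


def fit_rf(
    X: np.ndarray, y: np.ndarray, n_trees: int = 600, seed: int = 0
) -> RandomForestRegressor:
    """Seeded 600-tree regression forest on raw features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    model = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    model.fit(X, y)
    return model


class BPNNPredictor:
    """Single-hidden-layer tanh network trained by Levenberg-Marquardt.

    Weight update solves the damped normal equations
    ``(J'J + mu*I) d = J'e`` on the full-batch Jacobian, with the
    damping factor adapted multiplicatively; training stops at the
    epoch limit, on a gradient/improvement tolerance, or when damping
    saturates, returning the best weights seen.
    """

    def __init__(
        self,
        hidden: int = 15,
        max_epochs: int = 200,
        tol: float = 1e-10,
        seed: int = 0,
        mu0: float = 1e-2,
        mu_max: float = 1e10,
    ):
        self.hidden = hidden
        self.max_epochs = max_epochs
        self.tol = tol
        self.seed = seed
        self.mu0 = mu0
        self.mu_max = mu_max

    def _unpack(self, theta, d):
        h = self.hidden
        W1 = theta[: h * d].reshape(h, d)
        b1 = theta[h * d : h * d + h]
        w2 = theta[h * d + h : h * d + 2 * h]
        b2 = theta[-1]
        return W1, b1, w2, b2

    def _residual_jacobian(self, theta, X, y):
        n, d = X.shape
        W1, b1, w2, b2 = self._unpack(theta, d)
        H = np.tanh(X @ W1.T + b1)  # (n, h)
        yhat = H @ w2 + b2
        e = yhat - y
        sech2 = (1.0 - H * H) * w2  # (n, h)
        JW1 = (sech2[:, :, None] * X[:, None, :]).reshape(n, -1)
        J = np.concatenate([JW1, sech2, H, np.ones((n, 1))], axis=1)
        return e, J

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BPNNPredictor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, d = X.shape
        self.xscaler_ = _Standardizer().fit(X)
        Z = self.xscaler_.transform(X)
        self.y_mean_ = y.mean()
        ysd = y.std(ddof=0)
        self.y_sd_ = ysd if ysd > 0 else 1.0
        t = (y - self.y_mean_) / self.y_sd_
        rng = np.random.default_rng(self.seed)
        h = self.hidden
        theta = np.concatenate(
            [
                rng.normal(0.0, 1.0 / np.sqrt(d), h * d),
                rng.normal(0.0, 0.1, h),
                rng.normal(0.0, 1.0 / np.sqrt(h), h),
                np.zeros(1),
            ]
        )
        mu = self.mu0
        e, J = self._residual_jacobian(theta, Z, t)
        sse = float(e @ e)
        best_theta, best_sse = theta.copy(), sse
        eye = np.eye(theta.size)
        converged = False
        for _ in range(self.max_epochs):
            g = J.T @ e
            if np.max(np.abs(g)) < self.tol:
                converged = True
                break
            A = J.T @ J
            accepted = False
            while mu <= self.mu_max:
                try:
                    step = np.linalg.solve(A + mu * eye, g)
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                cand = theta - step
                e_new, J_new = self._residual_jacobian(cand, Z, t)
                sse_new = float(e_new @ e_new)
                if sse_new < sse:
                    theta, e, J, sse = cand, e_new, J_new, sse_new
                    mu = max(mu / 10.0, 1e-12)
                    accepted = True
                    if sse < best_sse:
                        best_theta, best_sse = theta.copy(), sse
                    break
                mu *= 10.0
            if not accepted:
                break
            if sse / n < self.tol:
                converged = True
                break
        if not converged and best_sse / n > 1e-6:
            logger.warning(
                "BPNN LM stopped without convergence (mse=%.3g); "
                "keeping best-so-far weights",
                best_sse / n,
            )
        self.theta_ = best_theta
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = self.xscaler_.transform(X)
        W1, b1, w2, b2 = self._unpack(self.theta_, Z.shape[1])
        t = np.tanh(Z @ W1.T + b1) @ w2 + b2
        return t * self.y_sd_ + self.y_mean_


def fit_bpnn(
    X: np.ndarray,
    y: np.ndarray,
    hidden: int = 15,
    max_epochs: int = 200,
    tol: float = 1e-10,
    seed: int = 0,
) -> BPNNPredictor:
    return BPNNPredictor(hidden=hidden, max_epochs=max_epochs, tol=tol, seed=seed).fit(
        np.asarray(X, dtype=float), np.asarray(y, dtype=float)
    )


def regression_metrics(
    y: np.ndarray, yhat: np.ndarray, r2_form: str = "ratio"
) -> dict:
    """R2, RMSE and MRE(%) for observed vs predicted values.

    ``r2_form="ratio"`` uses sum((yhat-ybar)^2)/sum((y-ybar)^2);
    ``"conventional"`` uses 1 - SSE/SST.  MRE is the mean absolute
    relative error in percent; NaN sentinels flag constant y (R2) or
    zero observations (MRE).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must align")
    n = y.size
    rmse = float(np.sqrt(((yhat - y) ** 2).sum() / n))
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        r2 = float("nan")
    elif r2_form == "ratio":
        r2 = float(((yhat - y.mean()) ** 2).sum() / sst)
    elif r2_form == "conventional":
        r2 = float(1.0 - ((yhat - y) ** 2).sum() / sst)
    else:
        raise ValueError("r2_form must be 'ratio' or 'conventional'")
    if np.any(y == 0):
        mre = float("nan")
    else:
        mre = float(100.0 * np.mean(np.abs(yhat - y) / np.abs(y)))
    return {"r2": r2, "rmse": rmse, "mre_percent": mre, "n": int(n)}


def evaluate(predictor, X: np.ndarray, y: np.ndarray, r2_form: str = "ratio") -> dict:
    """Predict on (X, y) and compute the three accuracy indicators."""
    return regression_metrics(y, predictor.predict(np.asarray(X, dtype=float)), r2_form)


@dataclass
class ModelConfig:
    """Hyperparameters for the three-model grid."""

    plsr_max_lv: int = 10
    plsr_cv_folds: int = 10
    rf_trees: int = 600
    bpnn_hidden: int = 15
    bpnn_max_epochs: int = 200
    bpnn_tol: float = 1e-10
    seed: int = 0
    r2_form: str = "ratio"


def _fit_one(model: str, X, y, cfg: ModelConfig):
    if model == "PLSR":
        return fit_plsr(X, y, cfg.plsr_max_lv, cfg.plsr_cv_folds, cfg.seed)
    if model == "RF":
        return fit_rf(X, y, cfg.rf_trees, cfg.seed)
    if model == "BPNN":
        return fit_bpnn(X, y, cfg.bpnn_hidden, cfg.bpnn_max_epochs, cfg.bpnn_tol, cfg.seed)
    raise KeyError(f"unknown model {model!r}")


def run_experiment_grid(
    params_by_layer: dict[str, ParameterMatrix],
    lnc: pd.DataFrame,
    combos: list[CombinationSpec],
    split: SplitSpec,
    config: ModelConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every (layer, combination, model) cell on one shared split.

    Returns the metrics table (one row per cell and split half) and a
    long predictions table (sample_id, y, yhat, split) per cell.  Empty
    combinations are skipped and flagged in the log.
    """
    config = config or ModelConfig()
    metric_rows: list[dict] = []
    pred_rows: list[dict] = []
    for layer in LAYERS:
        params = params_by_layer[layer]
        ids = params.sample_ids
        target = layer_target(lnc, layer, ids)
        yser = pd.Series(target, index=ids)
        for combo in [c for c in combos if c.layer == layer]:
            if not combo.members:
                logger.warning(
                    "skipping empty combination %s for layer %s", combo.name, layer
                )
                continue
            frame = params.values[combo.members]
            Xm = frame.loc[split.modeling_ids].to_numpy(dtype=float)
            Xv = frame.loc[split.validation_ids].to_numpy(dtype=float)
            ym = yser.loc[split.modeling_ids].to_numpy(dtype=float)
            yv = yser.loc[split.validation_ids].to_numpy(dtype=float)
            if np.isnan(Xm).any() or np.isnan(Xv).any():
                raise ValueError(
                    f"undefined parameter values in combination {combo.name!r} "
                    f"for layer {layer}"
                )
            for model in MODELS:
                predictor = _fit_one(model, Xm, ym, config)
                extra = {}
                if model == "PLSR":
                    extra["latent_variables"] = predictor.n_components
                for split_name, Xs, ys, sids in (
                    ("modeling", Xm, ym, split.modeling_ids),
                    ("validation", Xv, yv, split.validation_ids),
                ):
                    m = evaluate(predictor, Xs, ys, config.r2_form)
                    metric_rows.append(
                        {
                            "layer": layer,
                            "combination": combo.name,
                            "label": combo.label,
                            "model": model,
                            "split": split_name,
                            **m,
                            "n_features": len(combo.members),
                            "seed": split.seed,
                            **extra,
                        }
                    )
                    yhat = predictor.predict(Xs)
                    for sid, yo, yp in zip(sids, ys, yhat):
                        pred_rows.append(
                            {
                                "layer": layer,
                                "combination": combo.name,
                                "model": model,
                                "split": split_name,
                                "sample_id": sid,
                                "y": float(yo),
                                "yhat": float(yp),
                            }
                        )
    return pd.DataFrame(metric_rows), pd.DataFrame(pred_rows)
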