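"""ARD squared-exponential Gaussian-process regression of crystallization propensity.

The propensity π of a protein — the fraction of screened cocktails that
yield a crystal — is mapped to an unbounded response f = √π (signed-square
inverse, so slightly negative predicted propensities are representable),
z-scored features enter an anisotropic squared-exponential kernel

    k(x, x') = σ_f² exp(−½ Σ_d (x_d − x'_d)² / l_d²),

and hyperparameters (σ_f², σ_n², per-feature length scales l_d) are chosen
by maximising the marginal log-likelihood from many random restarts with a
conjugate-gradient search. Because features are z-scored, the fitted
length scales are directly comparable: a small l_d marks a feature whose
variation strongly moves the response (automatic relevance determination).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular

__all__ = [
    "transform",
    "inverse_transform",
    "Scaler",
    "zscore_fit_apply",
    "GPRModel",
    "kernel",
    "log_marginal_likelihood",
    "train_restarts",
    "predict",
    "loo_cv",
    "significant_variables",
    "compare_with_linear",
]

logger = logging.getLogger(__name__)

JITTER_LADDER = (0.0, 1e-10, 1e-8, 1e-6)

# identifiability box for length scales in z-scored units: features span a
# few sd, so l beyond ~100 is observationally flat — CG can drift freely
# there, and reported hyperparameters are saturated to this range
LENGTH_SCALE_BOUNDS = (1e-3, 1e2)


def transform(pi):
    """Propensity → response, f = √π. Rejects values outside [0, 1]."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("propensity must lie in [0, 1]")
    return np.sqrt(pi)


def inverse_transform(f):
    """Response → propensity, signed square: π = sign(f)·f².

    Small negative responses map to small nonphysical negative propensities,
    which are permitted (and should be read as ≈0).
    """
    f = np.asarray(f, dtype=float)
    return np.sign(f) * f**2


@dataclass(frozen=True)
class Scaler:
    columns: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in table.columns]
        if missing:
            raise ValueError(f"table lacks scaled columns: {missing[:5]}")
        x = table[list(self.columns)]
        return (x - self.mean) / self.sd


def zscore_fit_apply(table: pd.DataFrame) -> tuple[pd.DataFrame, Scaler]:
    """Z-score every column; constant columns are dropped with a warning."""
    if len(table) < 2:
        raise ValueError("need at least two rows to z-score")
    sd = table.std(ddof=0)
    keep = sd[sd > 0].index.tolist()
    dropped = [c for c in table.columns if c not in keep]
    if dropped:
        logger.warning("dropping %d constant column(s): %s", len(dropped), dropped[:8])
    scaler = Scaler(tuple(keep), table[keep].mean().to_numpy(), sd[keep].to_numpy())
    return scaler.apply(table), scaler


@dataclass
class GPRModel:
    signal_variance: float
    noise_variance: float
    length_scales: pd.Series           # feature → l_d (z-scored units)
    X: np.ndarray                      # (n, d) scaled training inputs
    y: np.ndarray                      # (n,) transformed responses
    y_mean: float
    scaler: Scaler | None = None
    restart_lmls: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.length_scales.to_numpy() <= 0):
            raise ValueError("length scales must be positive")
        if self.X.shape[0] < 2:
            raise ValueError("need at least two training rows")

    @property
    def feature_names(self) -> list[str]:
        return list(self.length_scales.index)

    def theta(self) -> np.ndarray:
        return np.concatenate(
            [
                [np.log(self.signal_variance), np.log(self.noise_variance)],
                np.log(self.length_scales.to_numpy()),
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "signal_variance": self.signal_variance,
                "noise_variance": self.noise_variance,
                "length_scales": self.length_scales.to_dict(),
                "y_mean": self.y_mean,
                "n_train": int(self.X.shape[0]),
            },
            indent=2,
        )


def _sq_dists(X1: np.ndarray, X2: np.ndarray, ls: np.ndarray) -> np.ndarray:
    A = X1 / ls
    B = X2 / ls
    return np.maximum(
        (A**2).sum(1)[:, None] + (B**2).sum(1)[None, :] - 2 * A @ B.T, 0.0
    )


def kernel(X1: np.ndarray, X2: np.ndarray, signal_variance: float, length_scales: np.ndarray) -> np.ndarray:
    """ARD squared-exponential kernel matrix between row sets X1 and X2."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    ls = np.asarray(length_scales, dtype=float)
    if X1.shape[1] != ls.size or X2.shape[1] != ls.size:
        raise ValueError(
            f"dimension mismatch: inputs have {X1.shape[1]}/{X2.shape[1]} columns, "
            f"model has {ls.size} length scales"
        )
    return signal_variance * np.exp(-0.5 * _sq_dists(X1, X2, ls))


def _chol_with_jitter(Ky: np.ndarray):
    for jitter in JITTER_LADDER:
        try:
            return cho_factor(Ky + jitter * np.eye(Ky.shape[0]), lower=True), jitter
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("kernel matrix not positive definite even with jitter 1e-6")


def _lml_and_grad(theta: np.ndarray, X: np.ndarray, yc: np.ndarray):
    """Marginal log-likelihood and its gradient w.r.t. log-hyperparameters.

    theta = [log σ_f², log σ_n², log l_1 … log l_d]; yc is the centred
    response (y − ȳ).
    """
    n, d = X.shape
    theta = np.clip(theta, -40.0, 40.0)  # keep exp() finite; l=e40 is flat anyway
    sf2, sn2 = np.exp(theta[0]), np.exp(theta[1])
    ls = np.exp(theta[2:])
    K = kernel(X, X, sf2, ls)
    Ky = K + sn2 * np.eye(n)
    (c, lower), _ = _chol_with_jitter(Ky)
    alpha = cho_solve((c, lower), yc)
    lml = (
        -0.5 * yc @ alpha
        - np.sum(np.log(np.diag(c)))
        - 0.5 * n * np.log(2 * np.pi)
    )
    Kinv = cho_solve((c, lower), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv  # dL/dθ = ½ tr(W · dK/dθ)
    grad = np.empty_like(theta)
    grad[0] = 0.5 * np.sum(W * K)                    # ∂K/∂log σ_f² = K
    grad[1] = 0.5 * sn2 * np.trace(W)                # ∂K/∂log σ_n² = σ_n² I
    for j in range(d):
        D = (X[:, j][:, None] - X[:, j][None, :]) ** 2 / ls[j] ** 2
        grad[2 + j] = 0.5 * np.sum(W * (K * D))      # ∂K/∂log l_j = K ∘ d²/l²
    return lml, grad


def log_marginal_likelihood(model: GPRModel, with_gradient: bool = True):
    """LML of a model on its own training data (and gradient w.r.t. log-params)."""
    lml, grad = _lml_and_grad(model.theta(), model.X, model.y - model.y_mean)
    return (lml, grad) if with_gradient else lml


def _optimize_from(theta0, X, yc, maxiter=500, gtol=1e-6):
    def negative(theta):
        lml, grad = _lml_and_grad(theta, X, yc)
        return -lml, -grad

    res = optimize.minimize(
        negative, theta0, jac=True, method="CG", options={"maxiter": maxiter, "gtol": gtol}
    )
    return res.x, -res.fun


def train_restarts(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_restarts: int = 100,
    seed: int = 0,
    maxiter: int = 500,
) -> GPRModel:
    """Fit hyperparameters from ``n_restarts`` random initialisations.

    The first restart starts from the standard ARD init — every length
    scale moderate (√d in z-scored units, so typical pairwise distances
    are order one) with signal/noise split of the response variance —
    and lets relevance pruning decide. The remaining restarts draw
    length scales from a Beta(0.5, 0.5) stretched onto [log 0.05, log 20]
    for a broad multimodal search. The restart with the highest marginal
    log-likelihood wins; all restart LMLs are retained on the model for
    diagnostic plots.
    """
    if n_restarts < 1:
        raise ValueError("need at least one restart")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ybar = float(y.mean())
    yc = y - ybar
    var_y = max(float(yc.var()), 1e-12)
    rng = np.random.default_rng(seed)
    d = Xa.shape[1]

    best_theta, best_lml, lmls = None, -np.inf, []
    for r in range(n_restarts):
        if r == 0:
            theta0 = np.concatenate(
                [[np.log(var_y), np.log(0.1 * var_y)], np.full(d, 0.5 * np.log(d))]
            )
        else:
            b = rng.beta(0.5, 0.5, size=d)
            log_ls = np.log(0.05) + b * (np.log(20.0) - np.log(0.05))
            theta0 = np.concatenate(
                [
                    [np.log(var_y * rng.uniform(0.5, 2.0)), np.log(var_y * rng.uniform(0.05, 0.5))],
                    log_ls,
                ]
            )
        try:
            theta, lml = _optimize_from(theta0, Xa, yc, maxiter=maxiter)
        except np.linalg.LinAlgError:
            continue
        lmls.append(float(lml))
        if lml > best_lml:
            best_theta, best_lml = theta, lml
    if best_theta is None:
        raise RuntimeError("all restarts failed (kernel matrix never positive definite)")

    lo, hi = np.log(LENGTH_SCALE_BOUNDS)
    best_theta = best_theta.copy()
    best_theta[:2] = np.clip(best_theta[:2], -40.0, 40.0)
    best_theta[2:] = np.clip(best_theta[2:], lo, hi)
    return GPRModel(
        signal_variance=float(np.exp(best_theta[0])),
        noise_variance=float(np.exp(best_theta[1])),
        length_scales=pd.Series(np.exp(best_theta[2:]), index=names),
        X=Xa,
        y=y,
        y_mean=ybar,
        restart_lmls=lmls,
    )


def _posterior_pieces(model: GPRModel):
    n = model.X.shape[0]
    ls = model.length_scales.to_numpy()
    K = kernel(model.X, model.X, model.signal_variance, ls)
    Ky = K + model.noise_variance * np.eye(n)
    (c, lower), _ = _chol_with_jitter(Ky)
    return (c, lower), ls


def predict(model: GPRModel, Xs: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and variance (includes observation noise) at rows of ``Xs``."""
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    (c, lower), ls = _posterior_pieces(model)
    Ks = kernel(model.X, Xs, model.signal_variance, ls)
    alpha = cho_solve((c, lower), model.y - model.y_mean)
    mean = model.y_mean + Ks.T @ alpha
    v = solve_triangular(c, Ks, lower=lower)
    var = model.signal_variance - (v**2).sum(axis=0) + model.noise_variance
    return mean, np.maximum(var, 1e-300)


def loo_cv(model: GPRModel) -> pd.DataFrame:
    """Closed-form leave-one-out predictions at fixed hyperparameters.

    Uses μ_i = y_i − [K_y⁻¹(y−ȳ)]_i / [K_y⁻¹]_ii and σ_i² = 1/[K_y⁻¹]_ii,
    equivalent to refitting the posterior without point i.
    """
    if model.X.shape[0] < 3:
        raise ValueError("LOO needs at least three points")
    (c, lower), _ = _posterior_pieces(model)
    n = model.X.shape[0]
    Kinv = cho_solve((c, lower), np.eye(n))
    yc = model.y - model.y_mean
    alpha = Kinv @ yc
    diag = np.diag(Kinv)
    mu = model.y - alpha / diag
    var = 1.0 / diag
    half = 1.959963984540054 * np.sqrt(var)
    return pd.DataFrame(
        {"observed_f": model.y, "loo_mean": mu, "loo_var": var,
         "ci_low": mu - half, "ci_high": mu + half}
    )


def significant_variables(model: GPRModel) -> pd.DataFrame:
    """ARD relevance report, ordered by increasing length scale.

    A feature is significant when l ≤ l* = √(l_min · l_max), the midpoint of
    the observed length scales on a log axis. ``relative`` is l / l_min, so
    the most relevant feature reads 1.00.
    """
    ls = model.length_scales
    lstar = float(np.sqrt(ls.min() * ls.max()))
    out = pd.DataFrame(
        {
            "feature": ls.index,
            "length_scale": ls.to_numpy(),
            "relative": (ls / ls.min()).to_numpy(),
            "significant": (ls <= lstar).to_numpy(),
        }
    ).sort_values("length_scale", ignore_index=True)
    out.attrs["threshold"] = lstar
    return out


def _linear_loo_residuals(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LOO residuals of ordinary least squares.

    Uses the hat-matrix identity when the design has more rows than
    columns; in the (near-)interpolating regime the identity is 0/0, so
    each fold is refit explicitly with the minimum-norm solution.
    """
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    if n > A.shape[1]:
        pinv = np.linalg.pinv(A)
        H = A @ pinv
        resid = y - H @ y
        h = np.clip(np.diag(H), 0.0, 1.0 - 1e-10)
        return resid / (1.0 - h)
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        coef = np.linalg.pinv(A[keep]) @ y[keep]
        out[i] = y[i] - A[i] @ coef
    return out


def compare_with_linear(
    X: pd.DataFrame,
    pi: np.ndarray,
    seed: int = 0,
    n_restarts: int = 20,
    model: GPRModel | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of proteins where GPR beats linear regression under LOO.

    Both models regress the transformed response f = √π on the same z-scored
    features; per-protein absolute LOO residuals are compared and ties count
    half to each model. Returns the fraction plus a per-protein residual
    table.
    """
    f = transform(np.asarray(pi, dtype=float))
    Xs, scaler = zscore_fit_apply(X)
    if model is None:
        model = train_restarts(Xs, f, n_restarts=n_restarts, seed=seed)
        model.scaler = scaler
    gpr_loo = loo_cv(model)
    gpr_res = np.abs(f - gpr_loo["loo_mean"].to_numpy())
    lr_res = np.abs(_linear_loo_residuals(Xs.to_numpy(), f))
    wins = np.where(gpr_res < lr_res, 1.0, np.where(gpr_res > lr_res, 0.0, 0.5))
    table = pd.DataFrame(
        {
            "observed_f": f,
            "gpr_loo": gpr_loo["loo_mean"].to_numpy(),
            "gpr_abs_residual": gpr_res,
            "lr_abs_residual": lr_res,
            "gpr_wins": wins,
        },
        index=X.index,
    )
    return float(wins.mean()), table
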