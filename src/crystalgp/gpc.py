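"""Sparse probit Gaussian-process classification of per-experiment outcomes.

Each screening experiment (protein × cocktail) is a Bernoulli outcome whose
success probability is probit-linked to a latent GP over the 150-feature
joint space (89 protein + 61 cocktail features). Protein-feature length
scales are frozen to their regression values; cocktail-feature length
scales and the signal variance are optimized on a sparse approximation.

Sparsity follows the informative-vector-machine recipe: points enter the
active set greedily by posterior-entropy reduction, with assumed-density-
filtering (ADF) site updates; a few expectation-propagation refresh sweeps
over the active set then polish the site parameters. Hyperparameters are
optimized by conjugate gradients on the Gaussian pseudo-observation
marginal likelihood of the active set, from Beta(0.5, 0.5)-sampled
restarts, alternating with re-selection of the active set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import log_ndtr, ndtr

from . import cocktails as ck
from .gpr import Scaler, kernel

__all__ = [
    "GPCModel",
    "ResponseCurve",
    "ivm_fit",
    "predict_probability",
    "additive_response_curve",
    "fit_quadratic",
    "optimal_condition",
]

logger = logging.getLogger(__name__)

_JITTER = 1e-8


def _probit_moments(y: float, mu: float, var: float) -> tuple[float, float]:
    """ADF tilt for a probit likelihood: returns (g, nu).

    g  = ∂ log Z / ∂mu, nu = −∂² log Z / ∂mu² with
    Z = Φ(y·mu / √(1+var)).
    """
    s = np.sqrt(1.0 + var)
    z = y * mu / s
    # φ(z)/Φ(z), stable in the far tail
    ratio = np.exp(-0.5 * z * z - 0.5 * np.log(2 * np.pi) - log_ndtr(z))
    g = y * ratio / s
    nu = ratio * (ratio + z) / (1.0 + var)
    return g, nu


@dataclass
class GPCModel:
    signal_variance: float
    length_scales: pd.Series            # joint feature space
    fixed_mask: pd.Series               # True where l is frozen (protein features)
    X: np.ndarray                       # (n, d) scaled training inputs
    y: np.ndarray                       # (n,) labels in {-1, +1}
    active_set: list[int] = field(default_factory=list)
    site_precision: np.ndarray | None = None
    site_mean: np.ndarray | None = None
    scaler: Scaler | None = None
    additive_range: pd.Series | None = None   # raw-unit 95th pct per species
    approx_lml: float = float("-inf")
    prior_bias: float = 0.0                   # constant latent prior mean

    def _validate(self) -> None:
        if self.site_precision is not None and np.any(self.site_precision < 0):
            raise ValueError("site precisions must be nonnegative")


def _adf_select(X, y, sf2, ls, d_active, refine_passes=2, bias=0.0):
    """Greedy IVM selection + ADF updates; returns (active, tau, m)."""
    n = X.shape[0]
    mu = np.full(n, bias)
    zeta = np.full(n, sf2)
    M = np.zeros((0, n))
    active: list[int] = []
    tau = np.zeros(d_active)
    mvals = np.zeros(d_active)
    remaining = np.ones(n, dtype=bool)
    for j in range(d_active):
        g = np.zeros(n)
        nu = np.zeros(n)
        idx = np.flatnonzero(remaining)
        for i in idx:
            g[i], nu[i] = _probit_moments(y[i], mu[i], zeta[i])
        with np.errstate(invalid="ignore"):
            dH = -0.5 * np.log1p(-np.clip(nu[idx] * zeta[idx], None, 1 - 1e-12))
        i_star = idx[int(np.argmax(dH))]
        col = kernel(X, X[i_star : i_star + 1], sf2, ls)[:, 0]
        if M.shape[0]:
            s_col = col - M.T @ M[:, i_star]
        else:
            s_col = col
        g_i, nu_i = g[i_star], nu[i_star]
        nu_i = max(nu_i, 1e-12)
        denom = max(1.0 - nu_i * zeta[i_star], 1e-12)
        tau[j] = nu_i / denom
        mvals[j] = mu[i_star] + g_i / nu_i
        mu = mu + g_i * s_col
        zeta = zeta - nu_i * s_col**2
        zeta = np.maximum(zeta, 1e-12)
        M = np.vstack([M, np.sqrt(nu_i) * s_col])
        active.append(int(i_star))
        remaining[i_star] = False
    if refine_passes > 0:
        tau, mvals = _ep_refresh(X[active], y[np.asarray(active)], sf2, ls,
                                 tau, mvals, sweeps=refine_passes, bias=bias)
    return active, tau, mvals


def _ep_refresh(Xa, ya, sf2, ls, tau, m, sweeps=2, bias=0.0):
    """EP sweeps over the active set to polish the ADF site parameters."""
    d = Xa.shape[0]
    K = kernel(Xa, Xa, sf2, ls) + _JITTER * np.eye(d)
    tau_t = tau.copy()
    nu_t = tau * m
    for _ in range(sweeps):
        B = np.eye(d) + np.sqrt(tau_t)[:, None] * K * np.sqrt(tau_t)[None, :]
        (c, lower) = cho_factor(B, lower=True)
        V = solve_triangular(c, np.sqrt(tau_t)[:, None] * K, lower=True)
        Sigma = K - V.T @ V
        mu = bias + Sigma @ (nu_t - tau_t * bias)
        for i in range(d):
            tau_cav = 1.0 / Sigma[i, i] - tau_t[i]
            if tau_cav <= 1e-12:
                continue
            nu_cav = mu[i] / Sigma[i, i] - nu_t[i]
            mu_cav, var_cav = nu_cav / tau_cav, 1.0 / tau_cav
            g, nu_tilt = _probit_moments(ya[i], mu_cav, var_cav)
            mu_hat = mu_cav + g * var_cav
            var_hat = var_cav - nu_tilt * var_cav**2
            var_hat = max(var_hat, 1e-12)
            tau_new = max(1.0 / var_hat - tau_cav, 1e-12)
            nu_new = mu_hat / var_hat - nu_cav
            d_tau = tau_new - tau_t[i]
            tau_t[i] = tau_new
            nu_t[i] = nu_new
            # rank-one update of Sigma and mu
            si = Sigma[:, i]
            Sigma = Sigma - (d_tau / (1.0 + d_tau * Sigma[i, i])) * np.outer(si, si)
            mu = bias + Sigma @ (nu_t - tau_t * bias)
    tau_t = np.maximum(tau_t, 1e-12)
    return tau_t, nu_t / tau_t


def _pseudo_lml_and_grad(log_params, free_idx, base_log_ls, Xa, tau, m):
    """Gaussian pseudo-observation LML over the active set and its gradient.

    log_params = [log sf2, log l_free...]; frozen length scales stay at
    ``base_log_ls``. Observation 'noise' is the fixed site variance 1/tau.
    """
    d = Xa.shape[0]
    log_params = np.clip(log_params, -30.0, 30.0)
    sf2 = np.exp(log_params[0])
    log_ls = base_log_ls.copy()
    log_ls[free_idx] = log_params[1:]
    ls = np.exp(log_ls)
    K = kernel(Xa, Xa, sf2, ls)
    Ky = K + np.diag(1.0 / tau) + _JITTER * np.eye(d)
    try:
        (c, lower) = cho_factor(Ky, lower=True)
    except np.linalg.LinAlgError:
        try:
            (c, lower) = cho_factor(Ky + 1e-6 * sf2 * np.eye(d), lower=True)
        except np.linalg.LinAlgError:
            # numerically infeasible proposal: steer the line search back
            return -1e25, np.zeros_like(log_params)
    alpha = cho_solve((c, lower), m)
    lml = -0.5 * m @ alpha - np.sum(np.log(np.diag(c))) - 0.5 * d * np.log(2 * np.pi)
    Kinv = cho_solve((c, lower), np.eye(d))
    W = np.outer(alpha, alpha) - Kinv
    grad = np.empty_like(log_params)
    grad[0] = 0.5 * np.sum(W * K)
    for j, fi in enumerate(free_idx):
        D = (Xa[:, fi][:, None] - Xa[:, fi][None, :]) ** 2 / ls[fi] ** 2
        grad[1 + j] = 0.5 * np.sum(W * (K * D))
    return lml, grad


def ivm_fit(
    X: pd.DataFrame,
    y01: np.ndarray,
    fixed_lengths: dict[str, float] | pd.Series | None = None,
    d_active: int | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    signal_variance: float = 1.0,
    optimize_hyperparameters: bool = True,
    selection_rounds: int = 2,
    refine_passes: int = 2,
    prior_bias: float | str = 0.0,
) -> GPCModel:
    """Fit the sparse probit GP classifier.

    ``X`` holds scaled features (columns named); ``fixed_lengths`` freezes
    the listed features' length scales (typically the protein block, at
    the regression model's values); the rest are optimized. ``d_active``
    defaults to min(500, max(n//10, 10)). ``prior_bias`` sets the constant
    latent prior mean: 0.0 keeps the classical zero-mean formulation,
    "auto" anchors far-from-data predictions at the training base rate
    (probit of the success fraction) instead of ½ — recommended for
    low-base-rate screens where extrapolated probabilities would
    otherwise drift upward spuriously.
    """
    y01 = np.asarray(y01)
    if set(np.unique(y01)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y01)) < 2:
        raise ValueError("degenerate labels: need both successes and failures")
    y = 2.0 * y01 - 1.0
    if prior_bias == "auto":
        from scipy.special import ndtri

        bias = float(ndtri(np.clip(y01.mean(), 1e-3, 1 - 1e-3)))
    else:
        bias = float(prior_bias)
    names = list(X.columns)
    Xa = np.asarray(X, dtype=float)
    n, d = Xa.shape
    if d_active is None:
        d_active = min(500, max(n // 10, 10))
    d_active = min(d_active, n)
    fixed_lengths = dict(fixed_lengths or {})
    unknown = set(fixed_lengths) - set(names)
    if unknown:
        raise ValueError(f"fixed lengths name unknown features: {sorted(unknown)[:5]}")
    fixed_mask = pd.Series([c in fixed_lengths for c in names], index=names)
    free_idx = np.flatnonzero(~fixed_mask.to_numpy())

    rng = np.random.default_rng(seed)
    base_log_ls = np.zeros(d)
    for i, c in enumerate(names):
        if c in fixed_lengths:
            base_log_ls[i] = np.log(fixed_lengths[c])

    best = None
    restarts = n_restarts if (optimize_hyperparameters and free_idx.size) else 1
    for _ in range(restarts):
        if optimize_hyperparameters and free_idx.size:
            b = rng.beta(0.5, 0.5, size=free_idx.size)
            log_free = np.log(0.05) + b * (np.log(20.0) - np.log(0.05))
            log_sf2 = np.log(signal_variance) + rng.normal(0.0, 0.3)
        else:
            log_free = base_log_ls[free_idx] if free_idx.size else np.empty(0)
            log_sf2 = np.log(signal_variance)
        log_ls = base_log_ls.copy()
        if free_idx.size:
            log_ls[free_idx] = log_free
        sf2 = float(np.exp(log_sf2))
        ls = np.exp(log_ls)
        lml = -np.inf
        active, tau, m = [], None, None
        for _round in range(selection_rounds if optimize_hyperparameters else 1):
            active, tau, m = _adf_select(Xa, y, sf2, ls, d_active, refine_passes, bias=bias)
            if not optimize_hyperparameters or not free_idx.size:
                lml, _ = _pseudo_lml_and_grad(
                    np.concatenate([[np.log(sf2)], np.log(ls[free_idx])]) if free_idx.size
                    else np.array([np.log(sf2)]),
                    free_idx, np.log(ls), Xa[active], tau, m - bias,
                )
                break
            p0 = np.concatenate([[np.log(sf2)], np.log(ls[free_idx])])

            def negative(p, _act=np.asarray(active)):
                l, gr = _pseudo_lml_and_grad(p, free_idx, log_ls, Xa[_act], tau, m - bias)
                return -l, -gr

            res = optimize.minimize(negative, p0, jac=True, method="CG",
                                    options={"maxiter": 200, "gtol": 1e-6})
            sf2 = float(np.exp(np.clip(res.x[0], -30.0, 30.0)))
            log_ls[free_idx] = np.clip(res.x[1:], -30.0, 30.0)
            ls = np.exp(log_ls)
            lml = -res.fun
        if best is None or lml > best.approx_lml:
            best = GPCModel(
                signal_variance=sf2,
                length_scales=pd.Series(ls, index=names),
                fixed_mask=fixed_mask,
                X=Xa,
                y=y,
                active_set=list(active),
                site_precision=np.asarray(tau),
                site_mean=np.asarray(m),
                approx_lml=float(lml),
                prior_bias=bias,
            )
    # re-verify frozen scales survived optimization untouched
    for c, v in fixed_lengths.items():
        assert best.length_scales[c] == v
    best._validate()
    return best


def _latent_posterior(model: GPCModel, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    act = np.asarray(model.active_set)
    Xa = model.X[act]
    ls = model.length_scales.to_numpy()
    K = kernel(Xa, Xa, model.signal_variance, ls) + _JITTER * np.eye(act.size)
    B = K + np.diag(1.0 / model.site_precision)
    (c, lower) = cho_factor(B, lower=True)
    Ks = kernel(Xa, Xs, model.signal_variance, ls)
    alpha = cho_solve((c, lower), model.site_mean - model.prior_bias)
    mean = model.prior_bias + Ks.T @ alpha
    V = solve_triangular(c, Ks, lower=True)
    var = model.signal_variance - (V**2).sum(axis=0)
    return mean, np.maximum(var, 1e-12)


def predict_probability(model: GPCModel, x: np.ndarray | pd.DataFrame) -> np.ndarray:
    """P(success) under the approximate posterior: Φ(μ*/√(1+σ*²))."""
    Xs = np.atleast_2d(np.asarray(x, dtype=float))
    if Xs.shape[1] != model.X.shape[1]:
        raise ValueError(
            f"dimension mismatch: got {Xs.shape[1]} features, model has {model.X.shape[1]}"
        )
    mean, var = _latent_posterior(model, Xs)
    return ndtr(mean / np.sqrt(1.0 + var))


@dataclass
class ResponseCurve:
    additive: str
    grid: np.ndarray              # molarity (PEGs converted from % mass upstream)
    probabilities: np.ndarray
    p0: float | None = None
    p1: float | None = None
    p2: float | None = None
    curve_class: str | None = None
    excluded: bool = False


def default_grid(model: GPCModel, additive: str, n_points: int = 25) -> np.ndarray:
    """0 plus log-spaced points up to the 95th percentile of training use."""
    if model.additive_range is None or additive not in model.additive_range.index:
        raise ValueError(f"model has no recorded concentration range for {additive!r}")
    c_max = float(model.additive_range[additive])
    if c_max <= 0:
        raise ValueError(f"additive {additive!r} never appears in training data")
    return np.concatenate([[0.0], np.geomspace(c_max / 300.0, c_max, n_points - 1)])


def additive_response_curve(
    model: GPCModel,
    protein_features: pd.Series,
    additive: str,
    grid: np.ndarray | None = None,
) -> ResponseCurve:
    """Predicted crystallization probability vs concentration of one additive.

    For each concentration the cocktail is neutral pH with only this
    additive present; IS, HS± and DEP are recomputed from the additive's
    properties and the protein's radius of gyration. Concentrations above
    the training range trigger a warning (extrapolated probabilities are
    weakly constrained).
    """
    reg = ck.build_registry()
    reg.get(additive)  # raises KeyError for unknown species
    if grid is None:
        grid = default_grid(model, additive)
    grid = np.asarray(grid, dtype=float)
    order = np.argsort(grid)
    grid = grid[order]
    if model.additive_range is not None and additive in model.additive_range.index:
        c_max = float(model.additive_range[additive])
        if c_max > 0 and grid.max() > c_max * 1.0001:
            logger.warning(
                "response grid for %s extends beyond the training range (%.3g > %.3g M)",
                additive, grid.max(), c_max,
            )
    rg = float(protein_features["Rg"])
    rows = []
    for c in grid:
        conc = {additive: float(c)} if c > 0 else {}
        cvec = ck.cocktail_feature_vector(conc, ph=7.0, rg=rg)
        rows.append(pd.concat([protein_features, cvec]))
    joint = pd.DataFrame(rows)
    if model.scaler is None:
        raise ValueError("model has no scaler attached; cannot map raw features")
    Xs = model.scaler.apply(joint)
    probs = predict_probability(model, Xs.to_numpy())
    return ResponseCurve(additive=additive, grid=grid, probabilities=probs)


def fit_quadratic(curve: ResponseCurve) -> ResponseCurve:
    """Least-squares quadratic P ≈ p0 + p1·c + p2·c² and trend class.

    interior-max / interior-min when the parabola's vertex falls inside the
    grid range with the matching curvature sign; otherwise monotone by the
    slope sign across the range. Monotone-decreasing (and flat) curves are
    flagged excluded, mirroring the screening convention that only
    non-decreasing responses are candidates for additive optimization.
    """
    c = np.asarray(curve.grid, dtype=float)
    P = np.asarray(curve.probabilities, dtype=float)
    if c.size < 3:
        raise ValueError("need at least three grid points for a quadratic fit")
    if np.unique(c).size != c.size:
        raise ValueError("duplicate grid points make the quadratic design singular")
    A = np.column_stack([np.ones_like(c), c, c * c])
    coef, *_ = np.linalg.lstsq(A, P, rcond=None)
    p0, p1, p2 = (float(v) for v in coef)
    lo, hi = c.min(), c.max()
    span = max(hi - lo, 1e-12)
    # treat curvature/slope below numerical noise as zero (flat segments)
    tol = 1e-9 * max(np.abs(P).max(), 1.0)
    if abs(p2) * span**2 < tol:
        p2 = 0.0
    if abs(p1) * span < tol:
        p1 = 0.0
    vertex = -p1 / (2 * p2) if p2 != 0 else np.inf
    if p2 < 0 and lo < vertex < hi:
        cls = "interior-max"
    elif p2 > 0 and lo < vertex < hi:
        cls = "interior-min"
    else:
        slope_span = (p1 + 2 * p2 * lo) + (p1 + 2 * p2 * hi)
        cls = "monotone-increasing" if slope_span > 0 else "monotone-decreasing"
    curve.p0, curve.p1, curve.p2 = p0, p1, p2
    curve.curve_class = cls
    curve.excluded = cls == "monotone-decreasing"
    return curve


def optimal_condition(
    model: GPCModel,
    protein_features: pd.Series,
    additive: str,
    grid: np.ndarray | None = None,
    tolerance: float = 0.01,
) -> tuple[float, float, bool]:
    """(c*, P(c*), improves?) — best concentration of one additive.

    ``improves`` is True when the best probability beats the no-additive
    probability by more than ``tolerance`` (absolute).
    """
    curve = additive_response_curve(model, protein_features, additive, grid)
    i = int(np.argmax(curve.probabilities))
    p_best = float(curve.probabilities[i])
    p0 = float(curve.probabilities[np.argmin(np.abs(curve.grid))])
    return float(curve.grid[i]), p_best, p_best > p0 + tolerance
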