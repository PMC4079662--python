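"""Crystallization-mechanism analysis.

Four tools sit downstream of the propensity GP:

* quadrant assignment on the sGRAVY–sSCE plane (split at dataset means),
* a hot-spot search that walks the surface-composition space around the
  most crystallizable proteins and ranks grid points by predicted
  propensity,
* a 2-D projection of predicted propensity onto the sGRAVY–sSCE plane,
* two-sample Kolmogorov–Smirnov enrichment tables comparing easy- vs
  hard-to-crystallize proteins within quadrants.

Quadrant orientation follows the convention encoded in
:data:`QUADRANT_ORIENTATION` (printed in every report): Q1 is the
high-sSCE / low-sGRAVY corner where electrostatic complementarity drives
crystallization, Q2 high/high, Q3 the low-sSCE / high-sGRAVY corner
(entropic/hydrophobic mechanism), Q4 low/low. Points exactly on a
boundary take the lower quadrant index.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from .gpr import GPRModel, inverse_transform, predict, significant_variables
from .protein_features import composition_features_from_fractions
from .scales import AMINO_ACIDS, CATEGORIES

__all__ = [
    "QUADRANT_ORIENTATION",
    "assign_quadrants",
    "hotspot_search",
    "project_propensity",
    "ks_two_sample",
    "enrichment_tables",
]

logger = logging.getLogger(__name__)

#: (sGRAVY side, sSCE side) → quadrant label; "hi" means ≥ reference mean
QUADRANT_ORIENTATION: dict[tuple[str, str], str] = {
    ("lo", "hi"): "Q1",
    ("hi", "hi"): "Q2",
    ("hi", "lo"): "Q3",
    ("lo", "lo"): "Q4",
}


def assign_quadrants(
    features: pd.DataFrame,
    reference_means: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Assign each protein a quadrant from its (sGRAVY, sSCE).

    ``reference_means`` is (mean sGRAVY, mean sSCE); defaults to the means
    of ``features`` itself. Boundary points are resolved to the lowest
    quadrant index among the sides they touch.
    """
    if reference_means is None:
        reference_means = (float(features["sGRAVY"].mean()), float(features["sSCE"].mean()))
    g_ref, s_ref = reference_means
    if not (np.isfinite(g_ref) and np.isfinite(s_ref)):
        raise ValueError("reference means must be finite")
    labels = []
    for _, row in features.iterrows():
        g_sides = ["hi" if row["sGRAVY"] > g_ref else "lo"] if row["sGRAVY"] != g_ref else ["lo", "hi"]
        s_sides = ["hi" if row["sSCE"] > s_ref else "lo"] if row["sSCE"] != s_ref else ["lo", "hi"]
        candidates = {QUADRANT_ORIENTATION[(g, s)] for g in g_sides for s in s_sides}
        labels.append(min(candidates))
    out = pd.DataFrame(
        {
            "quadrant": labels,
            "sGRAVY": features["sGRAVY"].to_numpy(),
            "sSCE": features["sSCE"].to_numpy(),
        },
        index=features.index,
    )
    out.attrs["reference_means"] = {"sGRAVY": g_ref, "sSCE": s_ref}
    out.attrs["orientation"] = {f"{k[0]}-sGRAVY/{k[1]}-sSCE": v for k, v in QUADRANT_ORIENTATION.items()}
    return out


@dataclass
class HotspotGrid:
    n_points_significant: int = 4
    max_grid_size: int = 4096


def _composition_dependents(vec: pd.Series) -> pd.Series:
    frac = pd.Series({aa: vec[f"frac_{aa}"] for aa in AMINO_ACIDS})
    total = frac.sum()
    if total <= 0:
        raise ValueError("surface composition collapsed to zero")
    frac /= total
    out = vec.copy()
    for aa in AMINO_ACIDS:
        out[f"frac_{aa}"] = frac[aa]
    derived = composition_features_from_fractions(frac)
    for c in CATEGORIES:
        out[f"cat_{c}"] = derived[f"cat_{c}"]
    for k in ("sGRAVY", "sSCE", "sPOL"):
        if k in out.index:
            out[k] = derived[k]
    return out


def hotspot_search(
    model: GPRModel,
    observed_features: pd.DataFrame,
    observed_propensity: pd.Series,
    percentile: float = 95.0,
    grid: HotspotGrid | None = None,
) -> pd.DataFrame:
    """Search composition space for high-propensity regions.

    Proteins above ``percentile`` of observed propensity seed the search.
    Around each seed, the surface-composition features (the 20 coverage
    fractions) are laid on a grid: features the ARD analysis marks
    significant take four equidistant values across their observed range,
    the rest sit at their observed mid-range value. Each grid point is
    renormalized to the composition simplex; category fractions and
    sGRAVY/sSCE/sPOL are recomputed (they are uniquely determined by the
    composition); all other features keep the seed protein's values. The
    seed itself is included, so the best returned point is never worse
    than its start.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    grid = grid or HotspotGrid()
    if model.scaler is None:
        raise ValueError("model has no scaler; fit via the pipeline or attach one")
    cutoff = np.percentile(observed_propensity.to_numpy(), percentile)
    seeds = observed_propensity[observed_propensity >= cutoff].index.tolist()
    if not seeds:
        raise ValueError(f"no protein at or above the {percentile} percentile")

    sig = significant_variables(model)
    sig_set = set(sig.loc[sig["significant"], "feature"])
    comp_cols = [f"frac_{aa}" for aa in AMINO_ACIDS if f"frac_{aa}" in observed_features.columns]
    sig_comp = [c for c in comp_cols if c in sig_set]
    # keep the grid tractable: most relevant composition dims first
    order = {f: i for i, f in enumerate(sig["feature"])}
    sig_comp.sort(key=order.__getitem__)
    max_dims = max(int(np.log(grid.max_grid_size) / np.log(grid.n_points_significant)), 1)
    if len(sig_comp) > max_dims:
        logger.warning(
            "capping hot-spot grid to the %d most relevant of %d significant composition dims",
            max_dims, len(sig_comp),
        )
        sig_comp = sig_comp[:max_dims]

    lo = observed_features[comp_cols].min()
    hi = observed_features[comp_cols].max()
    mid = 0.5 * (lo + hi)

    records = []
    for pid in seeds:
        base = observed_features.loc[pid].copy()
        for c in comp_cols:
            if c not in sig_comp:
                base[c] = mid[c]
        axes = [np.linspace(lo[c], hi[c], grid.n_points_significant) for c in sig_comp]
        points = [observed_features.loc[pid].copy()]  # the untouched seed
        for combo in itertools.product(*axes) if sig_comp else [()]:
            vec = base.copy()
            for c, v in zip(sig_comp, combo):
                vec[c] = v
            points.append(_composition_dependents(vec))
        block = pd.DataFrame(points)
        Xs = model.scaler.apply(block[list(observed_features.columns)])
        mean, _ = predict(model, Xs.to_numpy())
        pi_hat = inverse_transform(mean)
        for (_, vec), f_hat, p_hat in zip(block.iterrows(), mean, pi_hat):
            records.append(
                {"seed": pid, "predicted_f": float(f_hat), "predicted_propensity": float(p_hat),
                 "sGRAVY": float(vec.get("sGRAVY", np.nan)), "sSCE": float(vec.get("sSCE", np.nan)),
                 **{c: float(vec[c]) for c in comp_cols}}
            )
    out = pd.DataFrame.from_records(records)
    return out.sort_values("predicted_propensity", ascending=False, ignore_index=True)


def project_propensity(
    hotspot_results: pd.DataFrame, bins: int = 20
) -> pd.DataFrame:
    """Bin-wise mean predicted propensity over the (sGRAVY, sSCE) plane."""
    if hotspot_results.empty:
        raise ValueError("no hot-spot results to project")
    g = hotspot_results["sGRAVY"].to_numpy()
    s = hotspot_results["sSCE"].to_numpy()
    v = hotspot_results["predicted_propensity"].to_numpy()
    g_edges = np.linspace(g.min(), g.max() + 1e-12, bins + 1)
    s_edges = np.linspace(s.min(), s.max() + 1e-12, bins + 1)
    gi = np.clip(np.digitize(g, g_edges) - 1, 0, bins - 1)
    si = np.clip(np.digitize(s, s_edges) - 1, 0, bins - 1)
    rows = []
    for bg in range(bins):
        for bs in range(bins):
            mask = (gi == bg) & (si == bs)
            if mask.any():
                rows.append(
                    {
                        "bin_sGRAVY": 0.5 * (g_edges[bg] + g_edges[bg + 1]),
                        "bin_sSCE": 0.5 * (s_edges[bs] + s_edges[bs + 1]),
                        "mean_propensity": float(v[mask].mean()),
                        "count": int(mask.sum()),
                    }
                )
    return pd.DataFrame(rows)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    D is the supremum ECDF difference; the p-value uses the asymptotic
    Kolmogorov distribution with the standard effective-sample-size
    correction (Stephens).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    values = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, values, side="right") / a.size
    cdf_b = np.searchsorted(b, values, side="right") / b.size
    d = float(np.abs(cdf_a - cdf_b).max())
    en = np.sqrt(a.size * b.size / (a.size + b.size))
    p = float(kolmogorov((en + 0.12 + 0.11 / en) * d))
    return d, min(max(p, np.finfo(float).tiny), 1.0)


def enrichment_tables(
    assignments: pd.DataFrame,
    predicted_propensity: pd.Series,
    feature_table: pd.DataFrame,
    easy_hard_quantiles: tuple[float, float] = (0.75, 0.25),
    alpha: float = 0.05,
    min_group_size: int = 10,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-quadrant KS enrichment of features between easy and hard proteins.

    Easy/hard membership comes from global quantiles of the predicted
    propensity (default top/bottom quartiles). Quadrants where either
    group is smaller than ``min_group_size`` are skipped with a notice.
    Only rows with p < ``alpha`` are reported; direction compares group
    medians (easy > hard → enriched).
    """
    hi_q, lo_q = easy_hard_quantiles
    hi_cut = predicted_propensity.quantile(hi_q)
    lo_cut = predicted_propensity.quantile(lo_q)
    cols = features if features is not None else list(feature_table.columns)
    rows = []
    for quad in sorted(assignments["quadrant"].unique()):
        members = assignments.index[assignments["quadrant"] == quad]
        pp = predicted_propensity.loc[members]
        easy = pp.index[pp >= hi_cut]
        hard = pp.index[pp <= lo_cut]
        if len(easy) < min_group_size or len(hard) < min_group_size:
            logger.info(
                "quadrant %s skipped: easy=%d hard=%d below minimum group size %d",
                quad, len(easy), len(hard), min_group_size,
            )
            continue
        for feat in cols:
            va = feature_table.loc[easy, feat].to_numpy()
            vb = feature_table.loc[hard, feat].to_numpy()
            d, p = ks_two_sample(va, vb)
            if p < alpha:
                rows.append(
                    {
                        "group_a": f"{quad}-easy",
                        "group_b": f"{quad}-hard",
                        "feature": feat,
                        "D": d,
                        "p_value": p,
                        "direction": "enriched" if np.median(va) > np.median(vb) else "depleted",
                    }
                )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "feature", "D", "p_value", "direction"])
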