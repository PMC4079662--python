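"""End-to-end orchestration: screen → features → GPR → mechanisms → GPC → reports.

`run_all` executes the full analysis deterministically from a single
config, writing versioned CSV outputs plus a provenance manifest (config
hash and input checksums). Each stage failure aborts with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cocktails as ck
from . import gpc as gpc_mod
from . import gpr as gpr_mod
from . import mechanisms as mech
from . import synthetic as syn

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "crystalgp_out"
    # input paths; when absent, a synthetic screen is generated
    proteins_csv: str | None = None
    cocktails_csv: str | None = None
    outcomes_csv: str | None = None
    # synthetic screen size (used when inputs are not supplied)
    n_proteins: int = 182
    n_cocktails: int = 1536
    seed: int = 0
    restarts: int = 20
    exposure_threshold: float = 2.5     # Å²
    neighbor_cutoff: float = 5.0        # Å
    contact_cutoff: float = 5.0         # Å
    hotspot_percentile: float = 95.0
    alpha: float = 0.05
    d_active: int | None = None
    n_experiments: int = 1500           # experiment subsample for the GPC stage
    feature_subset: str = "full"        # full | categories-only
    response_additives: list[str] = field(default_factory=lambda: ["sodium", "PEG 4000"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("exposure_threshold", "neighbor_cutoff", "contact_cutoff", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.hotspot_percentile < 100:
            raise ValueError("hotspot_percentile must be in (0, 100)")
        if self.feature_subset not in ("full", "categories-only"):
            raise ValueError("feature_subset must be 'full' or 'categories-only'")

    def config_hash(self) -> str:
        # outdir is where results land, not what they are — keep it out
        blob = dataclasses.asdict(self)
        blob.pop("outdir")
        return hashlib.sha256(json.dumps(blob, sort_keys=True).encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _category_columns(columns: list[str]) -> list[str]:
    keep = [c for c in columns if c.startswith(("cat_", "pair_", "w_cat_", "w_pair_"))]
    return keep


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("inputs")
def _load_inputs(config: RunConfig):
    if config.proteins_csv or config.cocktails_csv or config.outcomes_csv:
        for attr in ("proteins_csv", "cocktails_csv", "outcomes_csv"):
            p = getattr(config, attr)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing input file for {attr}: {p}")
        proteins = pd.read_csv(config.proteins_csv, index_col="protein_id")
        cocktails_tab = pd.read_csv(config.cocktails_csv, index_col="cocktail_id")
        long = pd.read_csv(config.outcomes_csv)
        outcomes = long.pivot(index="protein_id", columns="cocktail_id", values="outcome")
        truth = None
    else:
        spec = syn.SyntheticScreenSpec(
            n_proteins=config.n_proteins, n_cocktails=config.n_cocktails, seed=config.seed
        )
        proteins, cocktails_tab, outcomes, truth = syn.generate_screen(spec)
    return proteins, cocktails_tab, outcomes, truth


@_stage("gpr")
def _fit_gpr(config: RunConfig, proteins: pd.DataFrame, outcomes: pd.DataFrame):
    pi = outcomes.mean(axis=1)
    cols = list(proteins.columns)
    if config.feature_subset == "categories-only":
        cols = _category_columns(cols)
    X = proteins[cols]
    f = gpr_mod.transform(pi.to_numpy())
    Xs, scaler = gpr_mod.zscore_fit_apply(X)
    model = gpr_mod.train_restarts(Xs, f, n_restarts=config.restarts, seed=config.seed)
    model.scaler = scaler
    frac, residuals = gpr_mod.compare_with_linear(X, pi.to_numpy(), seed=config.seed, model=model)
    residuals.index = proteins.index
    loo = gpr_mod.loo_cv(model)
    loo.index = proteins.index
    sig = gpr_mod.significant_variables(model)
    return model, pi, frac, residuals, loo, sig


@_stage("mechanisms")
def _run_mechanisms(config, model, proteins, pi, loo):
    quads = mech.assign_quadrants(proteins)
    hotspots = mech.hotspot_search(
        model, proteins, pi, percentile=config.hotspot_percentile,
    )
    projection = mech.project_propensity(hotspots)
    predicted = pd.Series(gpr_mod.inverse_transform(loo["loo_mean"].to_numpy()),
                          index=proteins.index)
    enrichment = mech.enrichment_tables(
        quads, predicted, proteins, alpha=config.alpha,
    )
    return quads, hotspots, projection, predicted, enrichment


@_stage("gpc")
def _fit_gpc(config, model, proteins, cocktails_tab, outcomes):
    rng = np.random.default_rng(config.seed + 17)
    reg = ck.build_registry()
    species = reg.names()
    # joint experiment table on a subsample
    n_p, n_c = outcomes.shape
    total = n_p * n_c
    take = min(config.n_experiments, total)
    flat = rng.choice(total, size=take, replace=False)
    rows, labels = [], []
    cocktail_cache: dict[tuple[str, str], pd.Series] = {}
    for k in flat:
        i, j = divmod(int(k), n_c)
        pid, cid = outcomes.index[i], outcomes.columns[j]
        prot = proteins.loc[pid]
        key = (cid, pid)
        conc = {s: float(cocktails_tab.loc[cid, s]) for s in species if cocktails_tab.loc[cid, s] > 0}
        cvec = ck.cocktail_feature_vector(conc, ph=float(cocktails_tab.loc[cid, "pH"]),
                                          rg=float(prot["Rg"]))
        rows.append(pd.concat([prot, cvec]))
        labels.append(int(outcomes.iloc[i, j]))
    joint = pd.DataFrame(rows).reset_index(drop=True)
    y = np.asarray(labels)
    Xs, scaler = gpr_mod.zscore_fit_apply(joint)
    # freeze protein-feature length scales at their regression values
    fixed = {c: float(model.length_scales[c]) for c in model.length_scales.index if c in Xs.columns}
    gpc_model = gpc_mod.ivm_fit(
        Xs, y, fixed_lengths=fixed, d_active=config.d_active, seed=config.seed,
        n_restarts=3, prior_bias="auto",
    )
    gpc_model.scaler = scaler
    ranges = {}
    for s in species:
        nz = cocktails_tab[s][cocktails_tab[s] > 0]
        ranges[s] = float(nz.quantile(0.95)) if len(nz) else 0.0
    gpc_model.additive_range = pd.Series(ranges)
    return gpc_model


@_stage("response-curves")
def _response_curves(config, gpc_model, proteins):
    curves_rows, coef_rows, optimal_rows = [], [], []
    # characterize the lowest-propensity proteins' response to each additive
    for pid in proteins.index[: min(5, len(proteins))]:
        prot = proteins.loc[pid]
        for additive in config.response_additives:
            try:
                curve = gpc_mod.additive_response_curve(gpc_model, prot, additive)
            except ValueError:
                continue
            gpc_mod.fit_quadratic(curve)
            for c, p in zip(curve.grid, curve.probabilities):
                curves_rows.append({"protein_id": pid, "additive": additive, "c": c, "P": p})
            coef_rows.append(
                {"protein_id": pid, "additive": additive, "p0": curve.p0,
                 "p1": curve.p1, "p2": curve.p2, "class": curve.curve_class,
                 "excluded": curve.excluded}
            )
            c_star, p_star, improves = gpc_mod.optimal_condition(gpc_model, prot, additive)
            optimal_rows.append(
                {"protein_id": pid, "additive": additive, "c_star": c_star,
                 "P_star": p_star, "improves": improves}
            )
    return (pd.DataFrame(curves_rows), pd.DataFrame(coef_rows), pd.DataFrame(optimal_rows))


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns a map of report name → written path."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    proteins, cocktails_tab, outcomes, truth = _load_inputs(config)
    model, pi, frac, residuals, loo, sig = _fit_gpr(config, proteins, outcomes)
    quads, hotspots, projection, predicted, enrichment = _run_mechanisms(
        config, model, proteins, pi, loo
    )
    gpc_model = _fit_gpc(config, model, proteins, cocktails_tab, outcomes)
    curves, coefficients, optimal = _response_curves(config, gpc_model, proteins)

    written: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame, index=True):
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# crystalgp config={chash}\n")
            frame.to_csv(fh, index=index)
        written[name] = path

    emit("proteins", proteins)
    emit("cocktails", cocktails_tab)
    long = outcomes.stack().rename("outcome").reset_index()
    long.columns = ["protein_id", "cocktail_id", "outcome"]
    emit("outcomes", long, index=False)
    emit("propensity", pd.DataFrame({"pi": pi, "predicted": predicted}))
    emit("gpr_residuals", residuals)
    emit("significant_variables", sig, index=False)
    emit("quadrants", quads)
    emit("hotspots", hotspots, index=False)
    emit("projection", projection, index=False)
    emit("enrichment", enrichment, index=False)
    emit("curves", curves, index=False)
    emit("coefficients", coefficients, index=False)
    emit("optimal", optimal, index=False)

    manifest = {
        "config_hash": chash,
        "config": dataclasses.asdict(config),
        "gpr_vs_lr_fraction": frac,
        "gpr_lml": float(max(model.restart_lmls)) if model.restart_lmls else None,
        "quadrant_orientation": quads.attrs.get("orientation", {}),
        "outputs": {k: _checksum(v) for k, v in written.items()},
    }
    if truth is not None:
        manifest["synthetic_truth"] = {
            "relevant_features": truth.relevant_features,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    written["manifest"] = out / "manifest.json"
    return written
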