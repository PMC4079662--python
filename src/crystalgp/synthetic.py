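"""Synthetic crystallization screens with a planted ground truth.

Emulates the statistical structure of a high-throughput screen — by
default 182 proteins × 1,536 cocktails with binary outcomes — so that
every downstream stage (featurization, GP regression/classification,
relevance, hot-spot and enrichment analysis) can be tested against a known
truth without any external dataset.

The planted truth drives crystallization through two mechanisms:

* an *entropic* hot spot: proteins with low surface side-chain entropy and
  moderate hydropathy crystallize more readily, and respond mostly to PEG;
* an *electrostatic* hot spot: proteins with high sSCE and a polar-rich
  surface crystallize through charge/polar complementarity, and respond
  mostly to salts.

Each protein's true propensity is a squashed sum of two squared-exponential
bumps over (sSCE, sGRAVY, polar fraction) — exactly representable by the
ARD squared-exponential GP family, so parameter recovery is a fair test.
Per-experiment outcomes are Bernoulli with probit-linked latent values;
the per-protein baseline is calibrated by bisection so that the marginal
success fraction over the cocktail set equals the planted propensity
exactly (only binomial noise remains).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from . import cocktails as ck
from .protein_features import composition_features_from_fractions, feature_names
from .scales import AMINO_ACIDS, CATEGORY_PAIRS, THREE_TO_ONE

__all__ = [
    "SyntheticScreenSpec",
    "PlantedTruth",
    "generate_protein_table",
    "generate_cocktail_table",
    "generate_outcomes",
    "generate_screen",
    "generate_ard_recovery_problem",
    "ToyLayout",
    "generate_toy_structure",
    "helix_layout",
]

# ------------------------------------------------------------------ screens


@dataclass(frozen=True)
class SyntheticScreenSpec:
    """Study-scale defaults: 182 proteins × 1,536 cocktails."""

    n_proteins: int = 182
    n_cocktails: int = 1536
    seed: int = 0
    mechanism_weights: tuple[float, float] = (1.0, 1.0)  # (entropic, electrostatic)
    noise_sd: float = 0.1
    ph_mean: float = 6.8
    ph_sd: float = 1.3
    max_species: int = 4
    peak_propensity: float = 0.32
    baseline_propensity: float = 0.005
    interaction_scale: float = 0.35

    def validate(self) -> None:
        if self.n_proteins < 2:
            raise ValueError(f"n_proteins must be ≥ 2, got {self.n_proteins}")
        if self.n_cocktails < 1:
            raise ValueError(f"n_cocktails must be ≥ 1, got {self.n_cocktails}")
        if self.mechanism_weights[0] < 0 or self.mechanism_weights[1] < 0:
            raise ValueError("mechanism_weights must be nonnegative")
        if self.mechanism_weights[0] == 0 and self.mechanism_weights[1] == 0:
            raise ValueError("mechanism_weights must not both be zero")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if self.ph_sd < 0:
            raise ValueError(f"ph_sd must be nonnegative, got {self.ph_sd}")


@dataclass
class PlantedTruth:
    relevant_features: list[str]
    true_length_scales: dict[str, float]
    latent_fn: str
    true_propensity: dict[str, float]
    # per-protein activation of the two bumps, used by the outcome model
    entropic_activation: dict[str, float] = field(default_factory=dict)
    electrostatic_activation: dict[str, float] = field(default_factory=dict)

    def validate_against(self, columns: list[str]) -> None:
        missing = [f for f in self.relevant_features if f not in columns]
        if missing:
            raise ValueError(f"relevant features not in schema: {missing}")
        bad = {p: v for p, v in self.true_propensity.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"true propensities outside [0,1]: {list(bad)[:3]}")


# Bump geometry in raw feature units. The Dirichlet composition model puts
# sSCE at ≈0.88±0.15, sGRAVY at ≈−0.5±0.35 and the polar category fraction
# at ≈0.25±0.05; centres sit one-to-two sd off centre so both regimes are
# populated but not dominant.
_ENTROPIC_CENTRE = {"sSCE": 0.70, "sGRAVY": -0.45}
_ENTROPIC_WIDTH = {"sSCE": 0.10, "sGRAVY": 0.30}
_ELECTRO_CENTRE = {"sSCE": 1.02, "cat_P": 0.30}
_ELECTRO_WIDTH = {"sSCE": 0.10, "cat_P": 0.05}


def _bump(row: pd.Series, centre: dict[str, float], width: dict[str, float]) -> float:
    z = sum(((row[k] - centre[k]) / width[k]) ** 2 for k in centre)
    return math.exp(-0.5 * z)


def generate_protein_table(spec: SyntheticScreenSpec) -> tuple[pd.DataFrame, PlantedTruth]:
    """Sample ``n_proteins`` rows over the full 89-feature schema plus truth.

    Surface composition is Dirichlet on the 20-simplex; pair fractions come
    from a random contact graph on the 15-pair simplex; category fractions
    and sGRAVY/sSCE/sPOL are *recomputed* from the sampled composition, so
    the schema's internal consistency holds by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = feature_names()
    rows = []
    ids = [f"P{i:04d}" for i in range(spec.n_proteins)]

    # Dirichlet concentration tuned to plausible protein surfaces: common
    # residues (S, E, K, G, A, D, T, N, L, P) get higher pseudo-counts.
    base_alpha = {aa: 3.0 for aa in AMINO_ACIDS}
    for aa in "SEKGADTNLP":
        base_alpha[aa] = 5.0
    for aa in "CWM":
        base_alpha[aa] = 1.5
    alpha = np.array([base_alpha[aa] for aa in AMINO_ACIDS])

    for pid in ids:
        vec = pd.Series(0.0, index=names)
        frac = rng.dirichlet(alpha)
        for aa, f in zip(AMINO_ACIDS, frac):
            vec[f"frac_{aa}"] = f
        # SASA weighting: mild random re-weighting of the same composition
        wts = rng.gamma(25.0, 1.0, size=len(AMINO_ACIDS))
        wfrac = frac * wts
        wfrac /= wfrac.sum()
        for aa, f in zip(AMINO_ACIDS, wfrac):
            vec[f"w_frac_{aa}"] = f

        for prefix in ("", "w_"):
            sub = pd.Series(
                {aa: vec[f"{prefix}frac_{aa}"] for aa in AMINO_ACIDS}
            )
            derived = composition_features_from_fractions(sub)
            for c in "S+-PH":
                vec[f"{prefix}cat_{c}"] = derived[f"cat_{c}"]
            if prefix == "":
                vec["sGRAVY"] = derived["sGRAVY"]
                vec["sSCE"] = derived["sSCE"]
                vec["sPOL"] = derived["sPOL"]

        # pair fractions from a random contact graph: edge propensity
        # proportional to the product of endpoint category fractions
        cat = np.array([vec[f"cat_{c}"] for c in "S+-PH"])
        raw = np.outer(cat, cat) * rng.gamma(8.0, 1.0, size=(5, 5))
        raw = (raw + raw.T) / 2
        pair_vals = []
        for i in range(5):
            for j in range(i, 5):
                pair_vals.append(raw[i, j] * (1.0 if i == j else 2.0))
        pair_vals = np.asarray(pair_vals)
        pair_vals /= pair_vals.sum()
        wpair = pair_vals * rng.gamma(25.0, 1.0, size=pair_vals.size)
        wpair /= wpair.sum()
        for p, v, wv in zip(CATEGORY_PAIRS, pair_vals, wpair):
            vec[f"pair_{p}"] = v
            vec[f"w_pair_{p}"] = wv

        vec["pI"] = float(np.clip(rng.normal(6.3, 1.6), 3.5, 11.5))
        vec["Rg"] = float(np.clip(rng.normal(18.0, 3.0), 10.0, 32.0))
        vec["SASA"] = float(rng.lognormal(math.log(9000.0), 0.35))
        vec["GRAVY"] = vec["sGRAVY"] + rng.normal(0.35, 0.12)
        vec["SCE"] = vec["sSCE"] + rng.normal(-0.08, 0.04)
        vec["POL"] = vec["sPOL"] + rng.normal(-0.5, 0.2)
        rows.append(vec)

    table = pd.DataFrame(rows, index=pd.Index(ids, name="protein_id"))

    w_ent, w_ele = spec.mechanism_weights
    wsum = w_ent + w_ele
    truth = PlantedTruth(
        relevant_features=["sSCE", "sGRAVY", "cat_P"],
        true_length_scales={"sSCE": 0.10, "sGRAVY": 0.30, "cat_P": 0.05},
        latent_fn=(
            "pi = base + peak * (w_ent * exp(-0.5 d2_entropic) + "
            "w_ele * exp(-0.5 d2_electrostatic)) / (w_ent + w_ele); "
            "entropic bump at (sSCE=0.70, sGRAVY=-0.45), "
            "electrostatic bump at (sSCE=1.02, cat_P=0.30)"
        ),
        true_propensity={},
    )
    for pid in ids:
        row = table.loc[pid]
        b_ent = _bump(row, _ENTROPIC_CENTRE, _ENTROPIC_WIDTH)
        b_ele = _bump(row, _ELECTRO_CENTRE, _ELECTRO_WIDTH)
        pi = spec.baseline_propensity + spec.peak_propensity * (
            w_ent * b_ent + w_ele * b_ele
        ) / wsum
        truth.true_propensity[pid] = float(min(pi, 1.0))
        truth.entropic_activation[pid] = float(b_ent)
        truth.electrostatic_activation[pid] = float(b_ele)
    truth.validate_against(list(table.columns))
    return table, truth


def generate_cocktail_table(spec: SyntheticScreenSpec) -> pd.DataFrame:
    """Raw cocktails (pH + species molarities) in two condition families.

    Half the screen is moderate-to-high salt alone (0.5–3 M), half low salt
    (0.05–0.3 M) plus one PEG (5–30 % w/v, stored as molarity). pH is a
    truncated normal on [3, 11].
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    reg = ck.build_registry()
    cations = reg.names("cation")
    anions = reg.names("anion")
    pegs = reg.names("PEG")
    cols = ["pH"] + reg.names()
    a, b = (3.0 - spec.ph_mean) / spec.ph_sd, (11.0 - spec.ph_mean) / spec.ph_sd
    ph = truncnorm.rvs(a, b, loc=spec.ph_mean, scale=spec.ph_sd,
                       size=spec.n_cocktails, random_state=rng)

    rows = np.zeros((spec.n_cocktails, len(cols)))
    frame = pd.DataFrame(rows, columns=cols,
                         index=pd.Index([f"C{i:04d}" for i in range(spec.n_cocktails)],
                                        name="cocktail_id"))
    frame["pH"] = ph
    for i in range(spec.n_cocktails):
        salt_only = i % 2 == 0
        cat = cations[rng.integers(len(cations))]
        an = anions[rng.integers(len(anions))]
        zc = abs(reg.get(cat).charge)
        za = abs(reg.get(an).charge)
        if salt_only:
            m = rng.uniform(0.5, 3.0)
        else:
            m = rng.uniform(0.05, 0.3)
        # electroneutral stoichiometry
        frame.iloc[i, frame.columns.get_loc(cat)] = m * za / max(zc, za)
        frame.iloc[i, frame.columns.get_loc(an)] = m * zc / max(zc, za)
        if not salt_only:
            peg = pegs[rng.integers(len(pegs))]
            pct = rng.uniform(5.0, 30.0)
            frame.iloc[i, frame.columns.get_loc(peg)] = ck.peg_percent_mass_to_molarity(
                pct, reg.get(peg).peg_mass
            )
    return frame


def _cocktail_scores(cocktail_table: pd.DataFrame, rg: float = 18.0) -> pd.DataFrame:
    """Centred salt/PEG appeal scores per cocktail, used by the outcome model.

    The salt score peaks at intermediate-high ionic strength; the PEG score
    grows with the depletion coefficient and saturates.
    """
    reg = ck.build_registry()
    species = reg.names()
    is_vals, dep_vals = [], []
    for _, row in cocktail_table.iterrows():
        conc = {s: float(row[s]) for s in species if row[s] > 0}
        is_vals.append(ck.ionic_strength(conc))
        dep_vals.append(ck.depletion_coefficient(conc, rg))
    is_vals = np.asarray(is_vals)
    dep_vals = np.asarray(dep_vals)
    salt = np.exp(-0.5 * ((is_vals - 2.0) / 1.2) ** 2)
    peg = 1.0 - np.exp(-dep_vals / 0.5)
    out = pd.DataFrame(
        {"IS": is_vals, "DEP": dep_vals, "salt_score": salt - salt.mean(),
         "peg_score": peg - peg.mean()},
        index=cocktail_table.index,
    )
    return out


def _calibrate_baseline(target: float, g: np.ndarray) -> float:
    """Solve mean(Φ(a + g)) = target for a by bisection."""
    lo, hi = -12.0, 12.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if norm.cdf(mid + g).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_outcomes(
    protein_table: pd.DataFrame,
    cocktail_table: pd.DataFrame,
    truth: PlantedTruth,
    seed: int,
    noise_sd: float = 0.1,
    interaction_scale: float = 0.35,
) -> pd.DataFrame:
    """Binary outcome table (proteins × cocktails), probit latent model.

    latent(p, c) = a_p + s·[elec_p·salt(c) + ent_p·peg(c)] + ε, with a_p
    calibrated so the marginal success probability over the generated
    cocktails equals the planted propensity exactly.
    """
    if protein_table.empty or cocktail_table.empty:
        raise ValueError("protein and cocktail tables must be nonempty")
    missing = [p for p in protein_table.index if p not in truth.true_propensity]
    if missing:
        raise ValueError(f"truth lacks propensities for proteins: {missing[:3]}")
    rng = np.random.default_rng(seed)
    scores = _cocktail_scores(cocktail_table)
    salt = scores["salt_score"].to_numpy()
    peg = scores["peg_score"].to_numpy()
    out = np.zeros((len(protein_table), len(cocktail_table)), dtype=int)
    for i, pid in enumerate(protein_table.index):
        target = truth.true_propensity[pid]
        ent = truth.entropic_activation.get(pid, 0.0)
        ele = truth.electrostatic_activation.get(pid, 0.0)
        g = interaction_scale * (ele * salt + ent * peg)
        if noise_sd > 0:
            g = g + rng.normal(0.0, noise_sd, size=g.size)
        if target <= 0.0:
            probs = np.zeros_like(g)
        elif target >= 1.0:
            probs = np.ones_like(g)
        else:
            a = _calibrate_baseline(target, g)
            probs = norm.cdf(a + g)
        out[i] = rng.random(g.size) < probs
    return pd.DataFrame(out, index=protein_table.index, columns=cocktail_table.index)


def generate_screen(spec: SyntheticScreenSpec):
    """Convenience: (protein_table, cocktail_table, outcomes, truth)."""
    proteins, truth = generate_protein_table(spec)
    cocktails_tab = generate_cocktail_table(spec)
    outcomes = generate_outcomes(
        proteins, cocktails_tab, truth, spec.seed + 2,
        noise_sd=spec.noise_sd, interaction_scale=spec.interaction_scale,
    )
    return proteins, cocktails_tab, outcomes, truth


# ------------------------------------------------ ARD parameter recovery


def generate_ard_recovery_problem(
    n: int = 200,
    d: int = 20,
    n_relevant: int = 5,
    seed: int = 0,
    noise_sd: float = 0.1,
    length_scale: float = 1.0,
    signal_sd: float = 1.0,
):
    """Draw a regression problem exactly in the ARD-SE model family.

    X is standard normal; the latent function is a GP draw whose kernel
    depends only on the first ``n_relevant`` of ``d`` features (length
    scale ``length_scale`` each); white noise with sd ``noise_sd`` is
    added. Returns (X DataFrame, y, relevant feature names).
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    rel = X[:, :n_relevant] / length_scale
    sq = (
        (rel**2).sum(1)[:, None] + (rel**2).sum(1)[None, :] - 2 * rel @ rel.T
    )
    K = signal_sd**2 * np.exp(-0.5 * np.maximum(sq, 0.0))
    latent = rng.multivariate_normal(np.zeros(n), K + 1e-10 * np.eye(n), method="cholesky")
    y = latent + rng.normal(0.0, noise_sd, size=n)
    cols = [f"x{i}" for i in range(d)]
    return pd.DataFrame(X, columns=cols), y, cols[:n_relevant]


# ------------------------------------------------------- toy structures

_ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class ToyLayout:
    """Positions are CA positions (Å); residues are 3-letter codes."""

    residues: list[tuple[str, tuple[float, float, float]]]
    chain: str = "A"
    cell: tuple[float, float, float, float, float, float] | None = None
    # Cartesian symmetry operators (R, t in Å), written as REMARK 290 SMTRY
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]] | None = None


def helix_layout(sequence: str, rise: float = 1.5, radius: float = 2.3,
                 turn_deg: float = 100.0) -> ToyLayout:
    """Helix-like CA trace for a one-letter sequence."""
    residues = []
    for i, aa in enumerate(sequence):
        ang = math.radians(turn_deg * i)
        residues.append(
            (_ONE_TO_THREE[aa], (radius * math.cos(ang), radius * math.sin(ang), rise * i))
        )
    return ToyLayout(residues)


_SIDE_OFFSETS = {
    # atom name → offset from CA, enough geometry for SASA/contact code
    "N": (-1.20, 0.80, 0.00),
    "C": (1.20, 0.80, 0.00),
    "O": (1.80, 1.85, 0.00),
}


def generate_toy_structure(layout: ToyLayout) -> str:
    """Emit PDB-format text (ATOM, CRYST1, REMARK 290) for a toy layout.

    Every residue gets backbone N/CA/C/O plus a CB pseudo-side-chain atom
    (except glycine). Round-trips through :func:`crystalgp.pdb.parse_structure`.
    """
    lines = []
    if layout.cell is not None:
        a, b, c, al, be, ga = layout.cell
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} P 1           1"
        )
    if layout.symmetry_ops:
        for opno, (rot, trans) in enumerate(layout.symmetry_ops, start=1):
            for row in range(3):
                r = np.asarray(rot)[row]
                t = float(np.asarray(trans)[row])
                lines.append(
                    f"REMARK 290   SMTRY{row + 1} {opno:3d} "
                    f"{r[0]:9.6f} {r[1]:9.6f} {r[2]:9.6f} {t:14.5f}"
                )
    serial = 1
    for seq, (name3, ca) in enumerate(layout.residues, start=1):
        if name3 not in THREE_TO_ONE:
            raise ValueError(f"unknown residue code {name3!r}")
        atoms = [("CA", (0.0, 0.0, 0.0), "C")]
        for nm, off in _SIDE_OFFSETS.items():
            atoms.append((nm, off, nm[0]))
        if name3 != "GLY":
            atoms.append(("CB", (0.0, -1.53, 0.0), "C"))
        for nm, off, elem in atoms:
            x, y, z = (ca[k] + off[k] for k in range(3))
            lines.append(
                f"ATOM  {serial:5d}  {nm:<3s}{name3:>4s} {layout.chain}{seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {elem:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
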