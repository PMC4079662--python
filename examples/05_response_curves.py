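"""Predict how crystallization probability responds to one additive.

Fits a small per-experiment probit GP classifier on a synthetic screen,
then sweeps sodium concentration for one protein at neutral pH with all
other species absent. The curve is summarized by a quadratic
P ~ p0 + p1 c + p2 c^2: p0 estimates the no-additive probability and the
class says whether an intermediate concentration is optimal.
"""

import numpy as np
import pandas as pd

from crystalgp import cocktails as ck
from crystalgp import gpc, gpr
from crystalgp import synthetic as syn

spec = syn.SyntheticScreenSpec(n_proteins=30, n_cocktails=200, seed=3)
proteins, cocktails_tab, outcomes, truth = syn.generate_screen(spec)

# subsample experiments into a joint (protein + cocktail) feature table
rng = np.random.default_rng(0)
reg = ck.build_registry()
species = reg.names()
n_p, n_c = outcomes.shape
rows, labels = [], []
for k in rng.choice(n_p * n_c, size=1600, replace=False):
    i, j = divmod(int(k), n_c)
    pid, cid = outcomes.index[i], outcomes.columns[j]
    conc = {s: float(cocktails_tab.loc[cid, s]) for s in species if cocktails_tab.loc[cid, s] > 0}
    cvec = ck.cocktail_feature_vector(conc, ph=float(cocktails_tab.loc[cid, "pH"]),
                                      rg=float(proteins.loc[pid, "Rg"]))
    rows.append(pd.concat([proteins.loc[pid], cvec]))
    labels.append(int(outcomes.iloc[i, j]))

Xs, scaler = gpr.zscore_fit_apply(pd.DataFrame(rows).reset_index(drop=True))
model = gpc.ivm_fit(Xs, np.asarray(labels), d_active=250, seed=0,
                    n_restarts=2, selection_rounds=1, prior_bias="auto")
model.scaler = scaler
model.additive_range = pd.Series(
    {s: (cocktails_tab[s][cocktails_tab[s] > 0].quantile(0.95)
         if (cocktails_tab[s] > 0).any() else 0.0) for s in species}
)

pid = outcomes.mean(axis=1).idxmax()  # most crystallizable protein
curve = gpc.additive_response_curve(model, proteins.loc[pid], "sodium")
gpc.fit_quadratic(curve)
print(f"protein {pid}, additive sodium: {len(curve.grid)} grid points")
for c, p in zip(curve.grid[::6], curve.probabilities[::6]):
    print(f"  c = {c:6.3f} M  ->  P(crystal) = {p:.3f}")
print(f"quadratic: p0={curve.p0:.3f}, p1={curve.p1:.3f}, p2={curve.p2:.3f}")
print(f"class: {curve.curve_class} (excluded from optimization: {curve.excluded})")
c_star, p_star, improves = gpc.optimal_condition(model, proteins.loc[pid], "sodium")
print(f"optimal concentration {c_star:.3f} M with P = {p_star:.3f}; "
      f"beats no-additive by >0.01: {improves}")
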