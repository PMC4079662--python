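"""Featurize a crystallization cocktail.

A cocktail is a pH plus molar concentrations of species from the fixed
56-species registry (19 cations, 24 anions, 13 PEGs). Four derived
descriptors summarize it: ionic strength (IS), Hofmeister coefficients
for cations/anions (HS+/HS-, +1 = kosmotropic end), and the
depletion-attraction coefficient (DEP) from PEG excluded volume, which
depends on the protein's radius of gyration.
"""

from crystalgp.cocktails import build_registry, cocktail_feature_vector

registry = build_registry()
print(f"registry: {len(registry)} species "
      f"({len(registry.names('cation'))} cations, "
      f"{len(registry.names('anion'))} anions, {len(registry.names('PEG'))} PEGs)")

# 0.2 M magnesium sulfate + 5% (w/v) PEG 4000 at pH 6.5, for an 18 A protein
cocktail = {"magnesium": 0.2, "sulfate": 0.2, "PEG 4000": 0.0125}
vec = cocktail_feature_vector(cocktail, ph=6.5, rg=18.0)
print(f"feature vector length: {len(vec)}")
for key in ("pH", "IS", "HS+", "HS-", "DEP"):
    print(f"  {key:4s} = {vec[key]: .4f}")
print("IS is in molar; HS is concentration-weighted position on the "
      "kosmotropic(+1)->chaotropic(-1) ranking; DEP grows with PEG size and amount.")
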