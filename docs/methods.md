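# Methods

This note documents the models implemented in `crystalgp`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate.

## Featurization

**Protein features (89).** From a PDB structure we compute, over *exposed*
residues (residue SASA ≥ 2.5 Å², boundary inclusive): 20 per-residue
coverage fractions (count-based), 5 residue-category fractions — small
(G, A), positive (H, R, K), negative (D, E), polar (C, S, T, N, Q),
hydrophobic (L, I, V, F, Y, M, W, P) — and 15 unordered category-pair
fractions for neighbouring surface residues (minimal heavy-atom distance
≤ 5 Å, same chain, one count per residue pair). The same 40 composition
features are recomputed with SASA weighting (residue areas replace counts;
pair counts weighted by the mean exposed area of the two residues). Nine
globals complete the vector: pI, total SASA (Å²), radius of gyration (Å,
mass-unweighted over protein heavy atoms), and whole-chain / surface
means of Kyte–Doolittle hydropathy (GRAVY/sGRAVY), side-chain
conformational entropy (SCE/sSCE, kcal/mol, flexible residues high) and
Grantham polarity (POL/sPOL). The surface scale averages are *identically*
the coverage-weighted scale means; tests assert this to 1e-10.

SASA uses Shrake–Rupley with Bondi radii, a 1.4 Å probe and 960
deterministic Fibonacci-spiral points per atom (quadrature error < 1% on
isolated spheres; doubling the point count moves fixture totals < 0.5%).
The pI solves the Henderson–Hasselbalch net charge for zero by bisection
on pH ∈ [0, 14] with the EMBOSS pKa set, termini included. Altloc records
keep the highest-occupancy conformer (ties → 'A'); HETATM, waters and
hydrogens are excluded from all features.

**Cocktail features (61).** 56 species molarities (19 cations, 24 anions,
13 PEGs), pH, and four derived descriptors:

* ionic strength IS = ½ Σ c_i z_i² (M);
* Hofmeister coefficients HS± = Σ c_i h_i per ion class, where h maps the
  kosmotropic→chaotropic ranking linearly onto [+1, −1]; six anions
  absent from the printed ranking contribute 0 (the midpoint) with a
  logged warning;
* depletion coefficient DEP = Σ_PEG c_a (1 + R_dep,a/R_g)³, the
  Asakura–Oosawa overlap volume with Flory-scaled depletant radius
  R_dep = r0 (M_a/M0)^0.588, r0 = 7 Å at M0 = 1000 g/mol (PEG-in-water
  radius-of-gyration scaling). PEG % (w/v) converts to molarity via
  10 g/L per percent.

All four descriptors are homogeneous of degree one in concentrations
(property-tested). The exact functional forms used upstream of this
package are not recoverable; these standard forms are isolated behind one
interface and every constant is configurable.

## Propensity regression (GPR)

Response: f = √π with signed-square inverse, which treats low-propensity
proteins gently while keeping high-propensity proteins influential; small
negative predicted propensities are representable and should be read as
≈ 0. Features are z-scored (constant columns dropped with a warning).
Kernel: anisotropic squared exponential with signal variance σ_f², noise
variance σ_n², per-feature length scales l_d. Training maximises the
marginal log-likelihood with analytic gradients via conjugate-gradient
searches (max 500 iterations, gradient tolerance 1e-6, Cholesky jitter
ladder 1e-10…1e-6) from multiple restarts: the first restart is the
standard ARD init (every l = √d so typical scaled distances are order
one; σ_f² = var(y), σ_n² = 0.1 var(y)), the rest draw log-length-scales
from Beta(0.5, 0.5) stretched onto [log 0.05, log 20]. The informed first
restart reliably lands in the relevance-separating basin that random
extreme inits often miss; the random restarts guard against its failure
modes.

Reported length scales are saturated to [1e-3, 1e2] (z-scored units).
Features span only a few standard deviations, so any l ≳ 100 is
observationally flat; beyond that bound the likelihood is constant and
CG can drift arbitrarily far, which would poison the log-midpoint
significance rule below. This mirrors the bounded kernels of standard GP
software.

Relevance: a feature is significant when l ≤ √(l_min·l_max) — the
midpoint of the observed scales on a log axis. Reports include l/l_min
so the most relevant feature reads 1.00. LOO predictions use the
closed-form identities μ_i = y_i − [K_y⁻¹(y−ȳ)]_i/[K_y⁻¹]_ii,
σ_i² = 1/[K_y⁻¹]_ii (verified against explicit refits to 1e-8). The
linear baseline is OLS on the same z-scored features and transformed
response, with LOO residuals from the hat-matrix identity; per-protein
absolute-residual comparisons count ties half to each model.

## Per-experiment classification (GPC)

Outcomes y ∈ {0,1} are probit-linked to a latent GP over the 150-feature
joint space. Protein-feature length scales are frozen to their GPR
values; cocktail-feature scales and σ_f² are optimized. The sparse fit is
informative-vector-machine style: greedy inclusion of the point with the
largest posterior-entropy reduction, assumed-density-filtering site
updates maintained through a low-rank posterior representation, followed
by two expectation-propagation refresh sweeps over the active set (site
polishing; with the active set equal to the data this approaches full EP,
and tests bound the gap to a dense EP reference at 0.02). Hyperparameters
maximise the Gaussian pseudo-observation marginal likelihood of the
active-set site parameters by conjugate gradients from Beta(0.5, 0.5)
restarts, alternating selection and optimization (2 rounds). Default
active-set size: min(500, max(n/10, 10)).

The latent prior mean is configurable: 0 (classical formulation; far from
data P → ½) or the probit of the training base rate ("auto"). For
screens where successes are rare, the zero-mean prior makes extrapolated
probabilities drift upward toward ½, which masquerades as an additive
benefit; the pipeline therefore uses the base-rate anchor for response
curves, while the default stays zero-mean.

Additive response curves evaluate P at neutral pH with a single additive
present (IS/HS±/DEP recomputed, DEP from the protein's R_g) over a grid
of 25 points: 0 plus log-spaced values up to the 95th percentile of the
additive's training concentrations; out-of-range grids warn. Quadratic
summaries are ordinary least squares of P on (1, c, c²); curvature or
slope below 1e-9 (relative to the probability scale and grid span) is
treated as zero so flat curves do not classify by floating-point noise.
Classes: interior-max / interior-min when the vertex falls strictly
inside the grid with matching curvature sign, else monotone by the net
slope across the range; monotone-decreasing (including flat) curves are
flagged excluded. `optimal_condition` reports the grid argmax and whether
it beats the additive-free probability by more than 0.01 (absolute).

## Mechanism analysis

Quadrants split the sGRAVY–sSCE plane at reference means (dataset means
by default). Orientation is a single configuration constant printed in
every report: Q1 = high-sSCE/low-sGRAVY (electrostatic mechanism), Q2 =
high/high, Q3 = low-sSCE/high-sGRAVY (entropic/hydrophobic), Q4 =
low/low; the source convention is ambiguous between two readings, so it
is explicit rather than silently resolved. Boundary points take the
lowest quadrant index.

Hot-spot search seeds from proteins above the 95th propensity percentile
and grids the 20 surface-composition coordinates: significant features
(per the ARD rule) take 4 equidistant values across their observed range,
the rest sit at mid-range; each point is renormalized to the simplex and
the composition-determined features (category fractions, sGRAVY, sSCE,
sPOL) recomputed; other features keep the seed's values. The grid is
capped at 4096 points by keeping the most relevant dimensions (logged);
the untouched seed is always included, so the best returned point is
never worse than its start.

The two-sample KS statistic is the exact ECDF sup-difference (tested
against brute-force enumeration for all small samples); p-values use the
asymptotic Kolmogorov distribution with the Stephens effective-n
correction. Enrichment tables compare easy vs hard proteins (global
top/bottom propensity quartiles by default) within each quadrant, feature
by feature, reporting rows with p < 0.05 and direction by group medians.
No multiple-testing correction is applied by default (per-feature
reporting); Benjamini–Hochberg is available but off.

Crystal contacts: symmetry mates come from the Cartesian REMARK 290
operators plus lattice translations within ±1 unit cell, pruned when a
copy's bounding box lies beyond the 5 Å contact cutoff + 5 Å margin;
files lacking CRYST1 or operators are rejected rather than guessed.
Contact residues are surface residues with any heavy atom within 5 Å of
a neighbour copy; profiles report category fractions and *cross-chain*
category-pair fractions, compared between quadrants by KS.

## Synthetic screens

The generator emulates a screen of 182 proteins × 1,536 cocktails.
Protein surface compositions are Dirichlet draws on the 20-simplex with
pseudo-counts favouring common surface residues; pair fractions come from
a random contact-graph model on the 15-pair simplex; category fractions
and sGRAVY/sSCE/sPOL are recomputed from the composition, so the schema's
identities hold exactly. The planted propensity is a squashed sum of two
squared-exponential bumps — an *entropic* bump at low sSCE/moderate
sGRAVY and an *electrostatic* bump at high sSCE/high polar fraction —
peaking at 0.32 over a 0.005 baseline (a broad range with most proteins
crystallizing rarely, a few in ~30% of conditions). Cocktails fall into
two families: moderate-to-high salt alone (0.5–3 M) and low salt
(0.05–0.3 M) with one PEG (5–30% w/v); pH is truncated normal
(mean 6.8, sd 1.3 on [3, 11], configurable — the screen it emulates is
reported as slightly acidic without a printed mean).

Outcomes are Bernoulli with probit latent a_p + s·[ele_p·salt(c) +
ent_p·peg(c)] + ε: the electrostatic bump activation couples to a salt
appeal score (peaking at intermediate-high ionic strength) and the
entropic activation to a PEG/depletion score; s = 0.35, ε has sd 0.1.
The per-protein intercept a_p is calibrated by bisection so that the
*marginal* success fraction over the generated cocktail set equals the
planted propensity exactly — only binomial noise remains, which makes
the statistical contract (99% of proteins within 4σ binomial error)
testable without slack for model error.

A second generator draws ARD-recovery problems exactly in the GP model
family: X standard normal, latent a GP draw depending on the first k of
d features (length scale 1), plus noise (sd 0.1). For the default
recovery test (n = 200, 5 of 20 relevant) the effective complexity of
the latent is small enough for the problem to be identifiable — the
point of the test is the relevance rule, not sample-complexity limits.

What these tests do *not* show: real screens have replicate samples,
correlated cocktail chemistry across generations, imaging false
negatives, and protein features estimated from structures rather than
sampled from the schema — none of which the generator models. Passing
tests demonstrate the statistical machinery recovers planted structure
under the model's own assumptions, not field performance.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen to keep the full run in minutes on one core: GP oracle checks at
n ≤ 20; parameter recovery at n = 200, d = 20 over 10 (tests) or 5
(script) seeds with 15 restarts; GPR-vs-LR comparisons at n = 120,
d = 12 over 10/5 seeds with 8 restarts; GPC fidelity on a 60-point toy
with the active set equal to the data; pipeline smoke runs at 30–40
proteins × 80–300 cocktails. The per-regime response-curve contrast uses
40 proteins × 300 cocktails with 2,400-experiment subsamples per regime.

## Known limitations

* ADF/IVM with a small active set degrades gracefully but is not
  variance-calibrated; fidelity is only guaranteed (and tested) near the
  full-active-set limit.
* The pseudo-likelihood hyperparameter objective conditions on site
  parameters from the previous selection round; two alternation rounds
  are a pragmatic truncation, not convergence.
* Hot-spot grids treat non-composition features as fixed at the seed;
  maxima that require moving globals (e.g. pI) are invisible.
* The per-additive response contrast between planted mechanisms is a
  small interaction effect; at desk scale it is only reliably visible
  with per-regime models (mirroring the per-quadrant model design), and
  the corresponding test asserts direction aggregated across seeds, not
  per-seed significance.
* mmCIF input, biological-assembly (REMARK 350) logic and space-group
  libraries are out of scope; operators must be present in the file.
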