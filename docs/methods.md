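# Methods

`metabofe` re-implements, as a tested and reusable pipeline, a
metabolite-biomarker discovery analysis for broiler feed efficiency (FE): two
divergently selected lines (a lean, high-FE line and a fat, low-FE line) are
profiled by untargeted plasma LC-MS in two ion modes, metabolites that differ
between the lines are screened multivariately, their genetic parameters are
estimated under a pedigree animal model, and a four-criterion threshold gate
selects candidate selection biomarkers. Because the original cohort is not
publicly deposited, a synthetic-cohort generator with known genetic
architecture stands in for the raw data; the published per-metabolite genetic
parameter tables ship as fixtures so the gate can also be replayed exactly.

## Feed-efficiency traits

For each bird with 4-week weight BW4, 7-week weight BW7 and total 4–7-week
feed intake FI (all grams):

- BWG = BW7 − BW4
- MMBW = ((BW4 + BW7)/2)^0.75 (metabolic mid-test body weight, g^0.75)
- FCR = FI / BWG
- RFI = FI − (b0 + b1·MMBW + b2·BWG), with (b0, b1, b2) the OLS fit of FI on
  [1, MMBW, BWG]

RFI therefore sums to zero over the fitted cohort and is orthogonal to both
predictors; these identities are asserted at 1e−8 relative tolerance. The
regression is fitted pooled across lines and sexes — the downstream genetic
model absorbs line and sex as fixed effects — with a per-group switch for
sensitivity checks. Birds with BWG ≤ 0 have undefined FCR/RFI; they are
flagged and excluded from the regression rather than silently dropped (no
published rule exists for them).

## Metabolome preprocessing

Each sample's feature intensities are normalized to the sample's total
spectral intensity, read here as the row total over the available (matched)
features, so normalized rows sum to 1. Features without an HMDB accession are
then dropped; the order is fixed as normalize → annotate. Peak picking,
alignment and database matching are upstream of this package and out of
scope. A log10 transform is provided for heatmap-style display only. Whether
the original t-tests ran on linear or log10 intensities is not documented;
the package defaults to the normalized linear scale everywhere and exposes
`use_log10` switches in the screening and REML layers.

Note one consequence of total-intensity normalization: a large line shift in
one feature perturbs every other relative abundance in that sample
(compositional leakage), so small panels with huge planted effects show
slightly elevated differential counts among nulls. This mirrors how the
normalization behaves on real data.

## PLS-DA screening

Two-class PLS-DA is fitted by NIPALS on the class label coded ±1 after
autoscaling (column mean 0, unit variance, sample SD with denominator n−1;
constant columns are dropped with a warning). Per component a: w_a ∝ X'y
(unit norm), t_a = X w_a, loadings p_a = X't_a/(t_a't_a), y-loading
b_a = y't_a/(t_a't_a), then X and y are deflated. R²X and R²Y are cumulative
explained sums of squares; the default is A = 2 components (score plots are
two-dimensional), configurable. The implementation agrees with scikit-learn's
`PLSRegression` to machine precision on shared inputs; sklearn is used only
as a cross-check in the tests, never as the implementation.

Q²Y uses sevenfold cross-validation with class-stratified, seeded folds; the
entire model, including the autoscaling, is refitted per training fold, and
Q² = 1 − PRESS/TSS with TSS about the training-fold mean of the class code.

VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) with
SSY_a = b_a²·t_a't_a, which satisfies Σ_j VIP_j² = p exactly (asserted at
1e−8). A feature is differential when VIP > 1 and the two-sided
pooled-variance Student's t-test (df = n₁+n₂−2) gives P < 0.05 — both strict,
with no multiplicity correction, matching the published rule; a
Benjamini–Hochberg switch exists but is off by default.

## Pedigree animal model

The numerator relationship matrix A is built by the tabular method in
topological order (A_ii = 1 + ½A_{sire,dam}; A_ij = ½(A_{j,sire}+A_{j,dam});
unknown parents contribute 0), equal to twice the coancestry matrix, with
inbreeding F = diag(A) − 1. The test suite checks it against an independent
recursive-kinship oracle on random pedigrees at 1e−12.

Each trait is modelled as Y = Xb + Za + e with fixed effects (intercept, sex,
line; reference-level coding), a ~ N(0, A·g) and e ~ N(0, I·r); h² = g/(g+r).
For two traits on the same animals, Var(a) = G⊗A and Var(e) = R⊗I with 2×2 G
and R, giving r_g = G₁₂/√(G₁₁G₂₂) and r_p = (G₁₂+R₁₂)/√((G₁₁+R₁₁)(G₂₂+R₂₂)).

REML is computed in the eigenbasis of M, the relationship matrix restricted
to the phenotyped animals (one record per animal): with M = UDU′, rotating
the records by U′ makes the covariance diagonal (univariate) or 2×2
block-diagonal (bivariate), so each likelihood, gradient and
average-information evaluation is O(n); the single O(n³) eigendecomposition
is reusable across traits on the same cohort. The optimizer runs
parameter-scaled EM-form gradient steps (15 warm-up iterations) followed by
average-information steps, all under a step-halving safeguard so the accepted
restricted log-likelihood never decreases (this monotonicity is a tested
invariant). Convergence requires relative log-likelihood change < 1e−8 and
relative parameter change < 1e−6 within 200 iterations. Variances are floored
at 1e−10 of the phenotypic variance; working correlations are clamped to
±0.999; a stall against a boundary counts as converged only when the
first-order (KKT) conditions hold. Standard errors of h², r_g and r_p come
from the delta method on the inverse average-information matrix.
Non-convergence is a first-class outcome: the flag propagates, non-converged
cells are written as "-", and metabolites with no converged fit are excluded
from the parameter table, mirroring how such rows are omitted from published
tables. If M is numerically the identity (no genetic links), the fit is
flagged unidentifiable instead of returning arbitrary estimates; tiny
negative eigenvalues are clipped (diagonal bending) before use.

## Biomarker gate

Four criteria, evaluated in order with all evaluable flags recorded:

1. differential between lines (VIP > 1 and P < 0.05 upstream);
2. max over available FE indices of |r_g| ≥ 0.30 (inclusive). Missing
   estimates are ignored, not treated as zero; a metabolite with one missing
   and one qualifying value passes. The qualifying coefficient is the larger
   |r_g| among FCR/RFI, ties toward FCR — this convention reproduces every
   published stage count, including rows whose FCR and RFI correlations
   disagree in sign;
3. line-mean direction: positive qualifying r_g requires the lean (high-FE)
   line to have the lower concentration, negative the reverse; equality
   fails, and r_g = 0 exactly is flagged undefined;
4. h² ≥ 0.20 (inclusive — load-bearing for a row with r_g exactly 0.30).

Raising either threshold can only shrink pass counts (tested property). The
final literature-based physiological-function curation (14 → 10 in the
original analysis) is supported only as a user-supplied exclusion list, never
computed.

## Synthetic cohort generator

The generator emulates the study conditions: two closed lines, a nested
mating design (each sire with `dams_per_sire` dams, `offspring_per_dam`
offspring per dam), 441 phenotyped birds by default (24 founders per line,
one bred generation of 234 birds per line, truncated to 441 — the original
family structure is unpublished, so the design is exposed in full in
`SimulationConfig`), and 284/272 annotated features in the positive/negative
panels.

Genetics: each metabolite and a latent feed-intake deviation carry additive
effects a ~ N(0, A⊗G) generated by gene dropping — founders N(0, G),
non-founders the parental mean plus a Mendelian-sampling deviation with
covariance G/2. The inbreeding correction (½ − ¼(F_s+F_d)) is deliberately
omitted: simulated pedigrees are shallow and non-inbred, and the
inbreeding-aware component under test is the A-matrix builder, not the
simulator. G is arrow-shaped — metabolites mutually uncorrelated, each
optionally correlated with the intake deviation — and is validated positive
semi-definite at configuration time (Σ r_g² ≤ 1).

Phenotypes: metabolite j = baseline + line effect + sex effect + a_j + e_j,
floored at 1e−6 of baseline so the log10 display stays defined. Per-feature
genetic variance is σ²_a = residual_sd²·h²/(1−h²) (residual_sd = 150
intensity units on a baseline of 1000, i.e. 15% CV, typical of normalized
LC-MS features). FI = b0 + b1·MMBW + b2·BWG + line shift + deviation with
(b0, b1, b2) = (100, 4, 1.65) chosen so a ~1200 g-gain broiler eats ~2900 g
(FCR ≈ 2.4); the deviation (phenotypic SD 150 g, h² 0.35 — the range reported
for RFI in meat-type chicken) is the generative RFI, so configured
metabolite–RFI genetic correlations are exact. Keys against FCR are mapped
onto the same intake deviation and are therefore approximate. Body weights
(600/1900 g means, fat line and males heavier) carry line, sex and
environment only; no selection across generations, no LC-MS peak shapes,
batch effects or missingness are simulated — so passing tests demonstrate
estimator correctness under the stated model, not robustness to those
real-data features. Line assignment is a fixed effect over independent
founder pools (no divergent-selection history is simulated, matching how line
enters the estimation model).

Determinism: the pedigree is a deterministic function of the configuration;
breeding values and environmental draws derive from a single seed via
spawned substreams, so identical configurations reproduce byte-identical
output files.

## Problem sizes in the test suite

The REML recovery study uses a deep two-generation design (36 founders per
line, 3 dams per sire, 8 offspring per dam, all 3096 animals phenotyped) with
one pedigree shared across 20 replicates — the eigendecomposition is computed
once and replicates differ in genetic and residual draws. At this size the
Monte-Carlo SDs are ≈0.036 for ĥ² and ≈0.062 for r̂_g, so the recovery
tolerances (mean ĥ² ±0.05, per-replicate ±0.1; r̂_g ±0.15) sit at 2.5–3
replicate SDs. Screening operating characteristics use a 300+100-feature null
panel (no line effects, h² = 0) for t-test calibration and a 40-feature panel
with five planted 900-unit line shifts (6 residual SDs) for sensitivity.

## Known limitations

- The bivariate model supports exactly two traits; no maternal or
  permanent-environment effects, and no genomic relationship matrices.
- FCR-targeted genetic correlations in the generator are approximate (see
  above); only RFI-targeted ones are exact.
- Real-data quantities that depend on the unavailable cohort (counts of
  differential features, R²/Q² values of the published models) are not
  reproduction targets; the stochastic suite covers those behaviours
  qualitatively on synthetic cohorts.
- The per-sample normalization is compositional; strong single-feature
  effects leak into other features' relative abundances, which is inherent to
  the method rather than an implementation artifact.
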