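# Methods

## The surface family

All surfaces are built from scaled doses mᵢ = dᵢ / (EC50ᵢ · δ_m50ᵢ),
where δ_m50ᵢ is the (multiplicative) EC50 perturbation, 1 when inactive.
For a mixture model with curves (E0ᵢ, Emaxᵢ, EC50ᵢ, αᵢ):

* null surface: u = u_min + (u_max − u_min)/(1 + S₀^(−γ₀)) with
  S₀ = Σ mᵢ, γ₀ = Σ αᵢmᵢ / Σ mᵢ, u_max = Σ Emaxᵢmᵢ / Σ mᵢ, and unshifted
  mᵢ (δ_m50 never applies to the null reference).
* full surface: the bracket becomes
  S = Σ mᵢ + Σ_S δ_m,S gS with gS = (Π_{i∈S} mᵢ)^(1/|S|) over every
  subset S of 2..n compounds, and γ / u_max gain the fraction
  (Σ δαᵢmᵢ + Σ δ_slope,S gS) / D  resp. (Σ δaᵢmᵢ + Σ δ_emax,S gS) / D,
  where the denominator D = Σ mᵢ + Σ_S gS contains *every* subset root
  term regardless of which δ are active.  Shifted mᵢ are used throughout
  the full surface, including its unperturbed leading terms, matching the
  dose-domain form of the model.

Sign convention: the bracket is raised to −γ, so effects increase with
dose for positive slopes (the log-domain and dose-domain prints of the
family differ on this sign and on one slope-numerator index; the
implementation uses the symmetric, monotonicity-consistent choice
throughout, with each compound's slope perturbation weighting its own
dose term).

u_min is a constant by default (the response with no drug on board cannot
depend on which drug was withheld); curves with differing baselines
require an explicit `umin_value`, and the dose-weighted "mixed" baseline
is available as `umin_mode="mixed"` for completeness.

Every member of the family solves the governing PDE identically in the
parameters: the diagonal derivative operator Σ∂/∂xᵢ acts as the identity
on every subset root term e^{(Σ_{i∈S}Xᵢ)/|S|}, so the weight ratios γ,
u_max are invariant along the diagonal and the one-dimensional Riccati
argument goes through unchanged.  `pde_residual` verifies this with
central differences (step 1e-5 in log-dose; residuals ≲1e-8 in practice,
asserted below 1e-6).

Structural facts worth knowing:

* On a single-compound axis all interaction terms vanish automatically;
  active perturbations do not, so the axis limit is the *perturbed* Hill
  curve.  Fits therefore include single-drug rows whenever perturbations
  are free (see below).
* The interaction δ_emax terms are not capped by the per-compound
  constraint Emaxᵢ + δ_emaxᵢ ≤ 1, so u_Ricc can exceed 1 slightly along
  high-dose rays (the anesthetics propofol+alfentanil fit reaches ≈1.04
  at doses far above the data).  Outputs are never clamped; such
  excursions are visible, not hidden.
* The null surface is monotone in every dose when slopes and maxima are
  shared, and monotone along fixed-ratio rays always; with unequal slopes
  it is *not* per-dose monotone everywhere (raising the steeper drug's
  dose below the combined EC50 raises the mixed slope γ and can lower the
  response by ~1e-4).  This is a property of the m-weighted slope mixing,
  not a numerical artifact.
* A sufficiently negative δ_m,S makes the dose bracket negative; this
  raises `BracketError` naming the offending subset rather than returning
  a complex/NaN surface.  Fit bounds keep δ_m,S ≥ −1.9.

## Reference models

GCA (slope-1, zero-baseline drugs), the median-effect surfaces with
shared slope and maximum (mutually exclusive and the product-term
non-exclusive variant), the implicit Loewe/concentration-addition
equation (solved by bracketed Brent iteration to |lhs−1| ≤ 1e-10, with
zero doses short-circuiting to the other drug's Hill curve), and the
linear truncation of the polynomial mixed-slope/mixed-maximum expansion.
In their stated regimes these coincide with the null surface to 1e-12
(asserted): the exclusive median-effect surface for any shared slope and
maximum; GCA for *full* agonists.  For partial agonists the GCA form as
written and the null surface differ in the denominator — the equivalence
is exact only at Emax = 1, and the implementation makes no attempt to
rescale partial agonists into agreement.

## Fitting conventions

* **Pure curves first.**  Hill parameters come from the single-drug rows
  (multi-start bounded least squares; EC50 estimated in the log domain;
  e0/emax fixable, as in quantal assays).  They are then frozen: mixture
  fits estimate only perturbation/interaction parameters.
* **Fit set.**  A mixture fit uses every row of the table it is given —
  for a pair, the pair's single-drug rows plus its mixture rays
  (`table.restrict(pair)`); for the ternary model, the whole table.
  Single-drug rows are what identify (and, here, eliminate) the
  perturbation parameters; interaction-only fits are unaffected by their
  presence since interaction terms vanish on the axes.  `FitResult.rmse`
  is over the fit set; per-subset RMSEs (pure / mixture / each ray) are
  reported alongside.
* **Reference scoring.**  `null_reference_rmse` scores the no-fit
  reference on mixture rows only and, within each ray, drops rows after
  the first fully saturated response (effect = 1): further escalation
  steps replicate the ceiling and carry no information about where the
  surface rises.  This matters for exactly one ray in the packaged data
  (midazolam+propofol, whose last three rows are ceiling replicates);
  pass `drop_saturated_tail=False` to score everything.  Fits always use
  all rows.
* **Bounds.**  δ_emax per compound ∈ [−1, 1−Emaxᵢ] (hard physical cap),
  interaction δ_emax ∈ [−1, 1], δ_slope ∈ [−20, 20], δ_m50 ∈ [0.01, 100],
  δ_m ∈ [−1.9, 50].  Multi-start: the inactive point, an optional warm
  start, and seeded Latin-hypercube points in narrower windows
  (δ_m50 log-uniform in [0.1, 10]); 16 starts by default.  The best-RSS
  solution wins; standard errors come from the Gauss–Newton covariance
  σ̂²(JᵀJ)⁻¹ with σ̂² = RSS/(N−k).
* **Statistics.**  RMSE = √(RSS/N).  AIC uses the Gaussian MLE variance:
  AIC = 2k + N(ln 2πσ̂² + 1), σ̂² = RSS/N, k = active surface parameters
  (the variance is excluded from k; any other fixed convention shifts all
  comparisons equally).  A perfect fit returns AIC = −∞ with a warning.
  The Wilcoxon–Mann–Whitney test (observed vs modelled effects) uses
  exact permutation enumeration for combined N ≤ 12 — valid under the
  heavy ties of quantised effect data, where the exact distribution is
  conditioned on the pooled values — and the tie-corrected normal
  approximation otherwise.  Shapiro–Wilk checks residual normality.

## Backward elimination

`reduce_model` starts from the full mask (or any given one).  Each step
refits the model with every single active parameter removed (warm-started
from the current estimate) and considers the lowest-AIC candidate, ties
broken by the smallest |estimate − inactive|/SE.  Two acceptance rules:

* `criterion="aic"` (default): accept any removal that lowers the AIC.
  Standard stepwise selection; on synthetic data from a known truth it
  prunes most superfluous parameters while always retaining genuinely
  active ones.  Caveat: the retained survivors' conditional
  likelihood-ratio statistics are inflated by the greedy search, so a few
  noise-fitting parameters can survive on null data — ordinary stepwise
  overfitting, and independent of the noise level.
* `criterion="conservative"`: accept a removal only when it costs
  essentially no likelihood, i.e. the AIC improves by the full 2-unit
  parameter penalty (within `likelihood_tol`, default 0.05).  Only
  parameters the data make exactly redundant are dropped.  On the
  anesthetics pairs this reproduces the published 9 → 3 reduction for all
  three binary mixtures: the six perturbation estimates sit exactly at
  their inactive values (zero likelihood cost), while every interaction
  parameter — even the statistically weak δ_emax of
  midazolam+alfentanil — carries measurable likelihood and survives.
  Under plain AIC descent two of the three pairs prune further (the
  removals improve AIC by 1.4–1.95 units), i.e. the published
  3-parameter models are not AIC-optimal; keeping all three interaction
  channels is a structural choice the conservative rule formalises.  On
  noisy data this rule retains noise-fitting parameters and is therefore
  not the default.

Either way the accepted AICs decrease strictly along the recorded trail,
and refitting with the final mask reproduces the final AIC.

## Synergy analysis

Surfaces are evaluated on per-compound log-spaced grids (201 points per
axis for binary, 81 for ternary mixtures — sizes chosen so a full
analysis runs in seconds — plus an exact-zero node so the single-drug
edges are represented exactly).  Search bounds default to each compound's
experimental dose range (lowest nonzero to highest dose anywhere in the
table): extrapolated synergy outside the covered box is not reported.
The best in-box grid node seeds a Nelder–Mead refinement in log-dose
space with the box imposed by coordinate reflection; the refined extremum
can only improve on the grid value, and doubling the grid changes refined
extrema by <1e-6.  Iso-effect and iso-synergy level sets use marching
squares (2-D) / marching cubes (3-D) on the evaluated grid, returned as
dose-coordinate polylines/vertex meshes and exportable as JSON.  For the
null model with maxima 1 the 50% level set is exactly the classical
linear isobole Σ mᵢ = 1 (planar in dose space); other levels are planar
only for equal slopes.

## Synthetic data

`generate` draws effect = u_Ricc(truth) + N(0, σ²), clipped to [0, 1],
from factorial, fixed-ratio-ray or single-drug designs.  It emulates the
additive, homoscedastic noise the fitting assumes — not the features of
real assay data (quantised or binomial endpoints, dose-dependent
variance, plate effects, high-dose activity declines), so recovery and
coverage results bound what the estimator can do under its own
assumptions, not performance on arbitrary real data.  Clipping makes the
noise asymmetric near the effect bounds; the packaged recovery and
coverage studies use partial-maximum compounds (Emax 0.8) and mid-range
designs so the clipped mass is negligible.  Under those designs, 2-SE
coverage of the interaction triple is 36/36 across the seeded grid of
three truth triples × σ ∈ {0.01, 0.05} × two seeds.

## Known limitations

* The family is explanatory, not mechanistic: parameters describe the
  surface, not receptor states, and extrapolation beyond the fitted dose
  box is unreliable (hence the bounded extremum search).
* Small mixture designs (5–8 rows per ray here) cannot discriminate
  sharply between interaction channels: the joint-slope and joint-potency
  terms partially compensate, which is why stepwise rules disagree near
  the 2-3-parameter boundary (see above) and why standard errors on
  δ_slope are wide.
* Effects must live on [0, 1]; percent data are rescaled on read.
  Heteroscedastic or binomial error models are out of scope.
* The Mann–Whitney exact path enumerates C(N, n) assignments and is
  restricted to combined N ≤ 12 by design.
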