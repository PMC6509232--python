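# Methods

This note documents the statistical models implemented in `phyloxylem`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Data model

The package analyses a species-level table of xylem tissue fractions —
vessel (VF), fiber (FF), ray (RF), axial parenchyma (AF) and total
parenchyma (RAF = RF + AF), all in percent of stem cross-sectional area —
together with mean vessel lumen area `A` (mm²), vessel density `N`
(mm⁻²), midpoint latitude/longitude, and thirteen climate indices in
three groups: thermal (MAT, ABT, PET, WI, CI, MTWM, MTCM), moisture (MAP,
PWQ, PCQ) and integrative (AET, Im, NPP). A rooted, time-calibrated
ultrametric phylogeny (branch lengths in My) links the species.

Tissue fractions are square-root transformed (on the percent scale) before
modelling; the vessel composition metrics `F = A·N` (unitless lumen
fraction) and `S = A/N` (mm⁴) are log10-transformed. `F·S = A²` and
`F/S = N²` hold algebraically, so `log F + log S = 2 log A` is an exact
identity used as a self-check. Fractions are validated independently
against [0, 100] and never forced onto a simplex: published fraction
ranges can exceed 100 jointly because measurement bases differ between
cell types. `RAF` is recomputed as `RF + AF` when absent and checked
against their sum within 0.5 percentage points (table rounding) when
present. Species missing from either the tree or the table are dropped
with a logged count; missing climate cells exclude a species listwise per
model, not globally.

## Phylogenetic covariance and Pagel's λ

Under Brownian motion the covariance of trait values between species i and
j is proportional to `C[i,j]`, the shared root-to-MRCA branch length;
`C[i,i]` is the root-to-tip depth. Pagel's λ rescales the off-diagonal of
`C`: λ = 1 is pure Brownian motion, λ = 0 a star phylogeny. λ is
restricted to [0, 1] because the transformed matrix can lose positive
semi-definiteness above 1 on ultrametric trees.

λ is estimated by profile maximum likelihood for the model
`y ~ MVN(μ·1, σ²·C(λ))`: at each λ, μ and σ² have closed-form GLS
solutions, leaving a one-dimensional profile maximized with a 21-point
grid pre-scan followed by a bounded Brent search (tolerance 1e-8); the
pre-scan guards against local optima. On an ultrametric tree `C(λ)`
shares eigenvectors for all λ, so one symmetric eigendecomposition makes
each profile evaluation O(n); a Cholesky-per-λ fallback covers
non-constant diagonals. Significance is a likelihood-ratio test of λ̂
against λ = 0 on χ²(1); this choice (rather than a randomization test) is
recorded in the output metadata.

## PGLS

Regressions of (transformed) tissue fractions on climate use generalized
least squares with residual covariance proportional to `C` ("simple
Brownian" correlation; λ is not re-estimated inside the regression).
Estimation is by Cholesky whitening — solve `L z = y`, `L W = X` with
`C = L Lᵀ`, then ordinary least squares of `z` on `W` — never by explicit
inversion. Maximum likelihood (not REML) is used throughout so that AIC
values are comparable across fixed-effect structures;
`AIC = −2 logL + 2(k + 1)` counts the residual variance as a parameter.
Per-term significance uses marginal (type-III-style) single-df F tests in
the whitened space, i.e. `F = t²` with the unbiased residual variance.

The pseudo-R² for a phylogenetic model is operationalized as

    R²_phy = 1 − RSS_w(model) / RSS_w(intercept-only null),

with both residual sums of squares taken in the whitened space under the
same correlation structure, clipped to [0, 1]. Verbal definitions of this
quantity in the comparative literature are ambiguous; this concrete form
reduces to the ordinary R² when `C = I` and is recorded in output
metadata. With `C = I` the whole machinery reproduces OLS exactly, which
is how the non-phylogenetic companion models (the dashed/solid regression
pairs) are produced.

## Three-step climate-variable selection

The thirteen candidate indices are strongly inter-correlated, so one top
model per tissue fraction is reached in three steps:

1. **Screen** — drop indices whose bivariate PGLS R²_phy against the trait
   is below a threshold (default 0.02). The screen uses the phylogenetic
   R² because the bivariate analysis itself is phylogenetic.
2. **Within-group elimination** — AIC-based backward elimination run
   separately inside the thermal, moisture and integrative groups.
3. **Pooled elimination** — all survivors enter one model; backward
   elimination runs once more.

Backward elimination accepts the best single-variable removal whenever the
resulting AIC is within `parsimony_delta` (default 2.0) of the current
model, encoding a "most parsimonious model" preference: a smaller model
nearly as good is taken. Setting the slack to 0 gives strict AIC descent,
in which case the final AIC is the exact minimum over all candidates
examined. AIC ties below 1e-6 are broken by dropping the variable that
appears later in the canonical index ordering (the listing above), which
makes selection deterministic and invariant to column order. An empty
survivor set yields an intercept-only model with a warning.

## Independent contrasts

Felsenstein's pruning pass computes at each internal node, for child
values x₁, x₂ on adjusted branches b₁, b₂: the standardized contrast
`(x₁ − x₂)/√(b₁ + b₂)`, the ancestral value `(x₁/b₁ + x₂/b₂)/(1/b₁ +
1/b₂)`, and the parent-edge adjustment `b + b₁b₂/(b₁ + b₂)`. Polytomies
(common in supertrees) are folded pairwise in a fixed order — children
sorted by their smallest descendant tip label — through zero-length
internal edges, so any tree yields exactly n − 1 contrasts and the result
is reproducible. Contrast sign follows the first-listed-minus-second
convention.

Trait–trait association is the Pearson correlation of standardized
contrasts with a two-sided t test (n − 2 df), reported as primary; the
through-origin variant (r₀ = Σxy/√(Σx²Σy²), t test on n − 1 df), under
which the arbitrary contrast sign is irrelevant, is always emitted
alongside because the two conventions can differ slightly in practice.

## Phylogeny/climate variance partition

Phylogeny enters as a categorical factor whose levels are the clades
obtained by cutting the ultrametric tree at a divergence time; two tips
share a clade iff their MRCA is at or more recent than the cut (ties at
the cut are grouped — an inclusive cut; a pendant edge spanning the cut
gives a singleton). The default cut times are 59 and 28 My. With ordinary
(not REML) least squares the sums of squares are additive, giving the
commonality identities

    phylo_only   = SS_E(groups + climate) − SS_E(climate)
    climate_only = SS_E(groups + climate) − SS_E(groups)
    shared       = SS_E(groups) + SS_E(climate) − SS_E(groups + climate)
    unexplained  = SS_total − SS_E(groups + climate)

whose four terms sum to the total exactly. The shared term is the
variation jointly carried by clade membership and climate (clades occupy
different parts of the climate space); it can be negative under
suppression and is reported as computed, flagged rather than clipped.
F ratios for the two unique components use rank-increment degrees of
freedom over the full-model residual mean square; the shared component is
not testable. The climate covariates entering a trait's partition are the
predictors of that trait's selected top model (an all-13 sensitivity mode
is available); an empty selection reduces the partition to the one-way
clade ANOVA. A climate column exactly constant (or constant within
clades) would make the design singular: constant columns are dropped with
a warning, exact clade/climate aliasing raises an error naming the block.

The per-trait decomposition is univariate (sums of squares); decomposing
the covariance between two different traits is out of scope.

## Synthetic data

The generator produces the statistical structure the analysis assumes, so
every stage has a known-truth test bed:

* **Tree** — a Yule (pure-birth) process, simulated forward with
  exponential waiting times, run one further waiting time past the n-th
  birth so pendant edges are strictly positive (a nonsingular covariance),
  then rescaled to exactly 100 My depth. Extinct lineages are not needed
  for an extant-species table, hence no death rate.
* **Climate** — latitude ~ Uniform(18°, 54°N); each index is linear in
  latitude plus equicorrelated Gaussian noise (default correlation 0.5
  across indices). Slopes and noise levels approximate an eastern-
  monsoonal gradient from tropical to cold-temperate conditions (e.g.
  MAT = 34 − 0.67·lat ± 1.2 °C), so thermal and moisture indices co-vary
  strongly with latitude and each other, which is precisely the
  collinearity the three-step selection exists to handle.
* **Traits** — generated on the √-percent scale as
  `√CF = intercept + Σ β·climate + ε`, `ε ~ MVN(0, σ²·C(λ))`, then squared
  back to percent, so the downstream regression model is exactly true and
  recovery tests are sharp. Default λ per fraction (0.85, 0.73, 0.67,
  0.90 for VF, FF, RF, AF) and Brownian rates give realistic marginal
  ranges; vessels gain and fibers lose area toward colder conditions, and
  axial parenchyma carries no climate effect. Cross-trait residual
  correlations (VF/FF −0.7 by default) mimic the vessel–fiber space
  trade-off: i.i.d. tip noise is mixed across traits by the Cholesky
  factor of the trait correlation, then each column is structured along
  the tree by its own λ-transformed covariance — exact at equal λ,
  approximate otherwise. RAF is derived as RF + AF on the percent scale,
  as in real tables. √-scale values are clipped to [0, 10] with a logged
  count (a warning above 5%); recovery tests use configurations clipping
  < 1%. `A` and `N` are log-normal with opposing latitude trends so `F`
  rises and `S` falls with latitude.
* Everything derives from one integer seed; a dataset regenerates
  bit-identically, and the full ground truth is stored beside it.

What the generator does **not** emulate: spatially explicit climate
surfaces, range-size effects, observation error in anatomical
measurements, non-Brownian (OU/early-burst) evolution, and extinct
lineages. Passing recovery tests therefore show that the estimators are
correct under their own assumptions, not that real xylem data satisfy
those assumptions.

## Numerical choices and degenerate inputs

* Ultrametricity: relative tolerance 1e-6 on root-to-tip depth; tree cuts
  refuse non-ultrametric trees (the grouping is ill-defined).
* Newick parse errors report the reader's line/column; duplicate tips,
  missing or negative branch lengths are validation errors.
* Covariance factorizations failing PSD raise with the condition number;
  zero-variance traits and rank-deficient designs (with the aliased
  columns named) are explicit errors.
* Problem sizes in the test and acceptance batteries (n = 300 for
  recovery, 100 replicates per λ grid point, 500 replicates for the
  type-I calibration at n = 100) were chosen to keep Monte-Carlo error
  comfortably below the asserted bands while a full run stays in the
  minutes range on one core.

## Known limitations

* PGLS supports only the Brownian correlation structure (no OU or
  λ-correlation inside the regression) and no interaction terms.
* The λ optimizer's fast path assumes an ultrametric tree; general trees
  fall back to O(n³) per profile evaluation.
* Tree-cut groups use MRCA (crown) ages; a stem-age reading of "cutting
  the tree" would shift group counts slightly.
* The contrast correlation between traits with unequal λ in the generator
  is approximate by construction (see above).
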