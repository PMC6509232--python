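# phyloxylem

Phylogenetic comparative analysis of xylem tissue fractions along
latitudinal and climatic gradients.

Woody angiosperm xylem divides a limited cross-sectional area between
vessels (water transport), fibers (mechanical support) and parenchyma
(storage), so tissue fractions trade off against each other — and both
shared evolutionary history and climate shape how that space is
allocated. `phyloxylem` implements the full comparative toolchain needed
to quantify those two influences for a species × trait table and a
time-calibrated phylogeny:

* **Pagel's λ** — profile maximum-likelihood phylogenetic signal of each
  tissue fraction under `y ~ MVN(μ·1, σ²·C(λ))`, with a likelihood-ratio
  test against λ = 0;
* **PGLS** — generalized least squares with a Brownian correlation
  structure (`cov ∝ C`), fitted by Cholesky whitening and ML, with
  marginal per-term F tests, AIC, and the pseudo-R²
  `R²_phy = 1 − RSS_w(model)/RSS_w(null)`;
* **Three-step climate model selection** — a bivariate R²_phy screen
  (default threshold 0.02), AIC backward elimination within thermal /
  moisture / integrative index groups, then pooled elimination to one top
  model per tissue fraction;
* **Independent contrasts** — Felsenstein's pruning recursion (with
  deterministic polytomy folding) and the contrast correlation matrix
  among fractions, in both plain and through-origin conventions;
* **Variance partition** — clades from cutting the tree at a divergence
  time (default 59 and 28 My) enter an ordinary-least-squares analysis of
  covariance whose additive sums of squares split trait variance into
  phylogeny-only, climate-only, shared and unexplained percentages with
  F ratios;
* **Vessel composition metrics** — `F = A·N` and `S = A/N` from mean
  vessel area `A` and density `N`, log10-transformed;
* a **synthetic-data generator** (Yule tree, latitude-structured climate,
  λ-scaled Brownian traits with known β, λ, σ²) so every stage is
  testable against ground truth, and a **CLI** that runs the pipeline
  end-to-end or stage by stage.

The estimators follow scikit-learn conventions (`PagelLambda`, `PGLS`,
`ClimateModelSelector`, `IndependentContrasts`, `VariancePartition`, each
with `fit` and trailing-underscore attributes); module-level functions
(`fit_lambda`, `pgls_fit`, `select_model`, `contrasts`, `partition`, …)
wrap them. See `docs/methods.md` for the statistical details.

## Worked example

Run the whole analysis on a simulated 150-species dataset (or pass
`--tree`/`--traits` for your own Newick + CSV):

```bash
phyloxylem run-all --out demo --seed 1 \
  --cut-times 59,28 --r2-threshold 0.02
```

(equivalently `RunConfig(simulate=SimConfig(n_tips=150), out_dir="demo",
seed=1)` with `run_all` from Python). `demo/lambda.csv` then holds the
phylogenetic signal of each fraction:

```
trait  lambda  p_value    n
VF      0.689      0.0  150
FF      0.712      0.0  150
RF      0.541      0.0  150
AF      0.859      0.0  150
RAF     0.613      0.0  150
```

Every fraction carries significant signal (the generator's λ values are
0.85/0.73/0.67/0.90 for VF/FF/RF/AF; single-replicate estimates at
n = 150 scatter around them). `demo/partition.csv` splits the
vessel-fraction variance at the two tree cuts:

```
cut_time  n_groups  pct_phylo_only  pct_climate_only  pct_shared  pct_unexplained
      59         7             7.1              33.2         1.4             58.2
      28        32            41.3              29.3         5.4             24.0
```

— with only 7 clades the 59-My cut explains little on its own here, while
the finer 28-My grouping attributes 41% of the variance to phylogeny
alone; the four percentages sum to 100 by construction. The selected top
model and its per-term F tests are in `demo/top_models.csv`, the contrast
correlations (the trade-off structure, e.g. VF vs FF strongly negative)
in `demo/pic_correlation.csv`, and `demo/manifest.json` records the
config hash, seed and per-stage status so a rerun is byte-identical.

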