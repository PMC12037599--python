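# Methods

`covnet` implements a two-group structural covariance network (SCN)
analysis of regional cortical morphometrics — surface area (CSA, mm²) or
thickness (CT, mm) on the 68-region Desikan-Killiany parcellation — with
graph-topological comparison via sparsity-curve AUC permutation tests, the
accompanying clinical statistics, and a synthetic cohort generator that
reproduces the statistical structure the analysis assumes.

## Pipeline

1. **Covariate correction.** Network construction uses *corrected* values:
   per-region OLS residuals of `value ~ 1 + age + sex`, fitted on the
   pooled sample (both groups together). Pooled fitting is the default
   because group-specific centering can itself create or destroy
   covariance; per-group fitting is available (`pooled=False`). Which
   covariates define "corrected" values is a genuine design choice — age
   and sex are the covariates used for the group-level morphometric GLMs in
   studies of this kind, so they are the default (`correction.covariates`).
   Residuals are not re-standardized; Pearson correlation is
   scale-invariant.

2. **Covariance networks.** Per group, the 68×68 matrix of absolute
   Pearson correlations between regional residuals across subjects
   (diagonal 0). Negative correlations are folded by absolute value, not
   zeroed.

3. **Thresholding.** At sparsity `s`, the `k = round(s·R(R−1)/2)` largest
   entries become edges (round-half-up; the rounding convention is a
   package choice). Because `k` depends only on `s` and `R`, any two groups
   have identical node and edge counts at each density. Ties in |r| are
   broken by lexicographic node-index order, so thresholding is
   deterministic and edge sets are nested along the default grid
   0.10–0.40, step 0.01.

4. **Graph metrics** (binary, undirected conventions throughout):
   clustering coefficient Cp (Watts–Strogatz), characteristic path length
   Lp (BFS distances; for disconnected graphs the mean is over finite
   pairs only, the dominant toolbox convention), global/local/nodal
   efficiency (Latora–Marchiori, 1/∞ = 0), unnormalized betweenness
   (unordered pairs, endpoints excluded; a 5-node star's hub scores 6),
   and Newman modularity Q from the best of 10 seeded Louvain restarts.
   γ = Cp/⟨Cp_rand⟩ and λ = Lp/⟨Lp_rand⟩ are normalized against
   Maslov–Sneppen degree-preserving rewired ensembles (default 100
   networks, 10 accepted swaps per edge, seeded); σ = γ/λ. Ensemble size
   and swap intensity are package defaults — the choice of null model is
   not pinned down by common usage, so both are configurable.

5. **Inference.** Each global metric's curve over the sparsity grid is
   summarized by its trapezoidal AUC. The group difference (A − B) is
   tested against a permutation null: subjects are randomly reassigned to
   two groups of the original sizes (default 2,000 repetitions) and the
   *entire* pipeline — correlation, thresholding, metrics, AUC — is re-run
   per relabeling. The p-value is the two-tailed add-one estimator
   `(1 + #{|null| ≥ |obs|})/(reps + 1)`, never exactly 0; the 95% band is
   the 2.5th–97.5th percentile interval of the null differences.
   Two-tailed is the default because the reference bands are symmetric.
   For γ/λ/σ the rewired ensemble inside each permutation is reduced
   (`inference.null_per_perm`, default 20, vs 100 for the observed
   statistic) to bound runtime; this inflates the null slightly and is
   therefore conservative. Nodal metrics (degree, nodal efficiency,
   betweenness) are compared per region at a single sparsity (default
   0.10) with Benjamini–Hochberg step-up correction across the 68 regions.

6. **Clinical statistics.** Group comparisons are gated by per-group
   Shapiro–Wilk at α = 0.05 (α is a package assumption): both normal →
   pooled-variance unpaired two-tailed t-test, else two-tailed
   Mann–Whitney U (exact for small tie-free samples, otherwise the
   normal approximation with tie correction). Pooled variance rather than
   Welch is the default because published demographic tables of this kind
   reproduce under pooled t; a summary-level pooled t-test is provided and
   is exactly equivalent to the data-level test on any data with the same
   summaries. Morphometric–clinical associations use partial correlation:
   both variables residualized on age and sex, r of residuals, two-tailed
   p from `t = r·√(df/(1−r²))` with `df = n − 2 − k`; exploratory, so
   uncorrected.

## Synthetic cohorts

The generator draws regional values from a multivariate normal with a
three-factor latent correlation structure:

* a **global factor** (`r_global`, default 0.25) shared by all regions —
  the overall-size covariance that makes empirical |r| matrices of
  cortical morphometrics pervasively positive;
* **module factors** (`r_in`, default 0.35 extra within-block correlation)
  over `n_blocks` = 6 contiguous blocks of regions;
* a **graded integration factor** whose per-region hub weights vary
  linearly over `1 ± hub_spread` (default 0.6) within each block,
  contributing on average `r_out` = 0.15 extra between-block correlation.
  Typical implied totals: ~0.60 within blocks, ~0.40 (range ~0.30–0.55)
  between.

The two-group **integration effect** is a single multiplier on group B's
integration factor (module loadings rebalanced so within-block
correlations change by at most a few percent). The graded structure is
essential, not cosmetic: matched-density thresholding sees only the
*ranking* of |r| values, and uniformly scaling a homogeneous between-block
pool leaves that ranking almost unchanged — simulations with a flat
two-level block model showed no detectable topological group difference at
any plausible effect size. With hub-graded loadings, weakening integration
demotes strong cross-block hub pairs below weak within-block pairs, which
is exactly the kind of difference fixed-edge-count binarization can
express (longer normalized path length in the fragmented group).

On top of the latent structure: linear age (uniform 45–80 years) and sex
(Bernoulli ½) effects with per-region random slopes, i.i.d. measurement
noise (SD 5% of the region mean vs 10% structured SD, i.e. correlations
attenuated by ≈ 0.8), and region profiles — log-uniform means
500–10,000 mm² (CSA-like) or uniform 1.5–4.5 mm (CT-like). Group sizes
default to 50/49. Everything is deterministic given the spec seed, and
`write_fixture` emits the TSV pair plus a ground-truth JSON manifest that
regenerates the cohort bit-for-bit.

What the generator does **not** emulate: spatial autocorrelation on the
cortical sheet, hemispheric asymmetry, site/scanner effects, non-linear
age trajectories, outliers and heavy tails, and any genuine
disease-lateralization mechanism. Passing tests therefore demonstrate
correctness and calibration of the *machinery* under the assumed
covariance model, not sensitivity on real MRI-derived tables.

## Numerical choices

* Shortest paths by boolean matrix-power BFS (fast for R = 68); brute
  force Floyd–Warshall only in test oracles.
* Rewiring rejects self-loops and duplicate edges and counts only
  accepted swaps; it stops early (logged) if 100× the target attempts are
  exhausted — rigid graphs (e.g. a triangle) are returned unchanged.
* Permutation statistic comparisons use a 1e-12 absolute guard so that
  bit-equal |null| values count as exceedances; with an observed
  difference of exactly 0 the p-value is 1.
* Zero-variance regions, empty edge budgets (`k = 0`), singular covariate
  designs, and non-PSD implied correlation matrices raise validation
  errors naming the offending entity.
* Degenerate graphs: Lp over an edgeless graph raises; efficiency of an
  isolated node is 0; clustering of degree < 2 nodes is 0; modularity of
  an edgeless graph raises.

## Problem sizes used in the test suite

The suite exercises full-size (68-region, 50/49-subject) cohorts for
structural contracts and small-world checks, and reduced scales chosen for
desk-class hardware elsewhere: type-I calibration at n = 20/group with 6
regions and 199 permutations over 200 replicates; integration-effect
recovery at n = 50/group over 50 seeded replicates — the direction check
on the full 0.10–0.40 grid with 12-network ensembles, the permutation
check on a coarser grid (step 0.05) with 100 relabelings and 2 rewired
nulls per permutation. The reduced ensemble settings make the
normalized-metric permutation test conservative (wider null bands), which
should be kept in mind when interpreting its power.

## Known limitations

* Lp on disconnected graphs averages finite pairs only; at the sparsest
  densities this can make a *more* fragmented graph look better
  integrated. Efficiency metrics do not share this artifact.
* The Louvain optimizer returns the best Q over seeded restarts, a lower
  bound on the true optimum (verified exact on ≤ 8-node graphs against
  exhaustive search).
* The permutation test assumes exchangeability of subjects under H₀ after
  pooled covariate correction; per-group correction would break this.
* Sigma depends on the null ensemble; values are comparable only between
  runs with the same ensemble configuration.
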