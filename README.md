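# covnet

Structural covariance network (SCN) analysis of regional cortical
morphometrics, for neuroimaging groups comparing two cohorts (e.g.
patient subgroups) on FreeSurfer-style ROI tables of cortical surface
area (CSA) or thickness (CT).

A structural covariance network treats brain regions as nodes and the
across-subject correlation of a morphometric measure between region pairs
as edges. `covnet` builds, per group, the 68×68 matrix of absolute Pearson
correlations |r| between covariate-corrected regional values on the
Desikan–Killiany parcellation, thresholds it into binary graphs across a
sparsity range *s* ∈ [0.10, 0.40] (step 0.01, keeping the
`k = round(s·R(R−1)/2)` strongest edges so both groups always have matched
edge counts), and computes on every graph:

* **global metrics** — clustering coefficient C, characteristic path
  length L, global efficiency E_glob, local efficiency E_loc, modularity
  Q, and the normalized quantities γ = C/⟨C_rand⟩, λ = L/⟨L_rand⟩ and the
  small-world index σ = γ/λ, where ⟨·_rand⟩ averages an ensemble of
  degree-preserving (Maslov–Sneppen) rewired networks;
* **nodal metrics** — degree, nodal efficiency, betweenness centrality.

Group differences are summarized by the trapezoidal area under each
metric's sparsity curve (AUC) and tested with a subject-relabeling
permutation test (default 2,000 repetitions, two-tailed add-one p-value,
95% permutation bands); nodal comparisons are Benjamini–Hochberg
FDR-corrected across regions. The package also covers the surrounding
clinical statistics (Shapiro–Wilk-gated t / Mann–Whitney comparisons,
summary-level pooled t-tests, partial correlations adjusted for age and
sex) and ships a synthetic cohort generator with a controllable
integration effect, so the entire pipeline is testable without access to
MRI data.

## Worked example

```python
import covnet

# a synthetic two-group cohort: 50 + 49 subjects x 68 Desikan regions,
# group B's cross-module covariance halved (a fragmented-integration effect)
spec = covnet.SyntheticSpec(group_effect=0.5, seed=1)
cohort = covnet.generate_cohort(spec)

corrected = covnet.residualize(cohort, covariates=("age", "sex"))
net_a = covnet.correlation_matrix(corrected, "A")
print(net_a.matrix.shape)                      # (68, 68)
print(covnet.binarize_at_sparsity(net_a, 0.10).n_edges)   # 228

result = covnet.global_permutation_test(
    corrected, "lambda", repetitions=100, seed=0,
    n_random=12, null_per_perm=2,
)
print(f"lambda AUC A={result.auc_a:.4f} B={result.auc_b:.4f} "
      f"diff={result.observed:+.4f} p={result.p:.3f}")
```

Output from this exact snippet:

```
(68, 68)
228
lambda AUC A=0.3187 B=0.3257 diff=-0.0071 p=0.465
```

The normalized path length's AUC is higher in group B — the group whose
between-module correlations were halved shows the more fragmented, less
integrated covariance topology. The direction is systematic across
simulated cohorts, but as the permutation p-value shows, a single cohort
of this size rarely yields an individually significant difference at
these reduced settings.

A command-line interface wraps the same library:

```
covnet simulate --out fixtures/demo --seed 1
covnet run --config analysis.yaml
covnet compare --morph fixtures/demo/morphometrics.tsv \
               --meta fixtures/demo/metadata.tsv --metric sigma
```

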