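# hyperfc

High-order functional connectivity via hypergraphs, for resting-state
fMRI studies of neurodegeneration and related group comparisons.

Conventional functional-connectivity analyses describe the brain as a
graph of pairwise Pearson correlations between parcellated regional BOLD
time series. Groups of regions that synchronise *jointly* — local
functional subnetworks that cut across the canonical seven networks — are
invisible to pairwise edges. `hyperfc` models them with a hypergraph
`HG = (V, E, W)`: each hyperedge gathers three or more regions, encoded by
a binary incidence matrix `H ∈ {0,1}^{N×M}` with node degrees
`d(v_n) = Σ_m w(e_m) H(n,m)`, hyperedge degrees `δ(e_m) = Σ_n H(n,m)`, and
similarity `S = H W D_e⁻¹ Hᵀ`.

The toolkit implements the full analysis chain:

1. **Structure inference** — a shared backbone is learned from a reference
   cohort of healthy controls: each region `n` in turn is the *centroid* of
   a candidate hyperedge, and its z-scored series `x_n` is regressed on all
   other regions with a non-negativity-constrained LASSO,

       min_α  1/(2P) ‖x_n − X_n α‖₂² + λ‖α‖₁ ,   α ⪰ 0 ,

   where column `n` of the design is zeroed. Per subject, the resulting
   `N×N` coefficient matrix is thresholded at the fifth percentile of its
   positive entries, binarized, restricted to hyperedges with ≥ 3 regions
   (centroid included), and the per-subject structures are fused by
   majority vote (cell = 1 when ≥ 50% of subjects agree). λ can be fixed or
   selected by 5-fold cross-validation over timepoints on a grid
   0.01–0.30. Structure stability under truncated acquisitions is measured
   by Jaccard index and Pearson correlation of the voted backbones.

2. **Hyperedge weighting** — the headline scheme weights hyperedge `m` for
   each subject by the **algebraic connectivity** (Fiedler value) `a(𝒢)` of
   the subgraph its members induce: edge weights are absolute Pearson
   correlations, and `a(𝒢)` is the second-smallest eigenvalue of the graph
   Laplacian `L = D − A`. `a(𝒢) = 0` iff the subgraph is disconnected and
   `a(K_k) = k`, so the weight captures joint synchronisation and
   robustness of integration without averaging over pairs. Baselines:
   Gaussian similarity kernel (median-heuristic bandwidth), mean pairwise
   Pearson correlation, squared L2 norm of the centroid's LASSO
   coefficients, and mean within-network correlation for the seven
   canonical functional networks.

3. **Group statistics** — per hyperedge: Shapiro–Wilk normality screen
   (informational), Kruskal–Wallis omnibus test across groups,
   Benjamini–Hochberg FDR across hyperedges, absolute Cliff's δ averaged
   over group pairs as a global effect size, and Mann–Whitney post-hoc
   tests (FDR within each group pair) on the omnibus survivors.

4. **Classification** — stratified 80/20 split, random-forest tuning by
   5-fold CV accuracy, hold-out accuracy / weighted precision / recall /
   F1, and impurity-based feature importances over the significant
   hyperedge weights.

5. **Mediation** — the three-equation decomposition
   `y = i₁ + c z`, `w = i₂ + a z`, `y = i₃ + c′ z + b w` (optional
   covariates in all three), with total = c, direct = c′, indirect = a·b,
   and a percentile bootstrap (1000 case resamples) for the indirect
   effect.

A synthetic-data module generates z-scored panels with planted
hyperedge-community structure (latent-factor coupling, group-dependent),
clinical tables and mediation triples, so the entire pipeline is testable
without any imaging data.

## Worked example

Two planted hyperedges over 12 regions; hyperedge 0 loses coupling in the
"AD" group (latent-factor loading 0.8 → 0.5). A 30-subject reference
cohort defines the backbone; 20 + 20 analysis subjects are compared:

```python
from hyperfc import (SimulationConfig, simulate_panels, build_backbone,
                     compute_weight_table, run_group_stats, hyperedge_degrees)

coupling = {(h, g): 0.8 for h in range(2) for g in ("HC", "AD")}
coupling[(0, "AD")] = 0.5          # hyperedge 0 loses coupling in AD
cfg = SimulationConfig(
    n_regions=12, n_timepoints=192,
    n_subjects_per_group={"HC": 20, "AD": 20},
    planted_hyperedges=[[0, 1, 2, 3], [4, 5, 6]],
    coupling=coupling, noise_sd=0.2, seed=3,
)
panels, groups, _ = simulate_panels(cfg)

ref_cfg = SimulationConfig(**{**cfg.__dict__, "n_subjects_per_group": {"HC": 30},
                              "coupling": 0.8, "seed": 103})
ref_panels, _, _ = simulate_panels(ref_cfg)
backbone = build_backbone(ref_panels, lam=0.05)
print("hyperedges:", backbone.n_hyperedges,
      "| mean degree:", round(float(hyperedge_degrees(backbone).mean()), 2))

table = compute_weight_table(panels, backbone, "algebraic", groups)
stats = run_group_stats(table)
print(stats.omnibus[stats.omnibus["significant"]])
```

Output:

```
hyperedges: 7 | mean degree: 3.57
             H   p_raw   p_fdr  effect_size
hyperedge
e0        29.3 6.3e-08 1.1e-07            1
e1        29.3 6.3e-08 1.1e-07            1
e2        29.3 6.3e-08 1.1e-07            1
e3        29.3 6.3e-08 1.1e-07            1
```

The backbone recovers one hyperedge per member centroid — the four
centroids of the affected hyperedge (`e0`–`e3`) are exactly the ones the
omnibus stage flags, with FDR-corrected p ≈ 1e-7 and a Cliff's-δ global
effect size of 1 (complete separation). The group means make the
direction concrete: mean `a(𝒢)` of `e0` is 3.91 in HC versus 3.54 in AD —
the planted loss of within-hyperedge coupling shows up as reduced
algebraic connectivity.

The same stages are available from the shell:

```sh
hyperfc simulate --config sim.yaml --out-dir study/
hyperfc build-structure --manifest study/manifest.tsv --lambda 0.05 --out H.tsv
hyperfc compute-weights --method algebraic --structure H.tsv \
        --manifest study/manifest.tsv --out weights.tsv
hyperfc stats --weights weights.tsv --out stats.tsv
hyperfc classify --weights weights.tsv --task HC:AD --significant stats.tsv \
        --seed 1 --out report.json
hyperfc mediate --weights weights.tsv --clinical study/clinical.tsv \
        --significant stats.tsv --covariates age,sex,education,apoe4 \
        --out mediation.tsv
hyperfc run --config pipeline.yaml --out-dir artifacts/   # all of the above
```

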