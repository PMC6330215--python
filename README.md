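# dynsubgraphs

Dynamic subgraph decomposition of time-varying functional connectivity.

Resting-state brain activity is not static: coupling between regions
strengthens and weakens on the scale of tens of seconds, and different
constellations of regions — *subgraphs* — wax and wane together.  This
package implements a pipeline for recovering those subgraphs and
quantifying their dynamics:

1. **Dynamic networks.** Each subject's region × time series is cut into
   sliding windows (20 samples, 90% overlap), and the band-limited
   (0.02–0.08 Hz) Morlet wavelet coherence between every pair of regions
   is averaged within each window, giving a multilayer network
   `A (N × N × T)`.  Layers are normalized by their mean edge weight,
   unfolded to the `N(N−1)/2` unique edges, corrected for subject motion
   by across-subject regression (negatives clipped at zero), and
   concatenated over subjects into a nonnegative cohort matrix
   `X (edges × T·S)`.
2. **Sparse NMF.** `X` is factorized into a nonnegative subgraph basis `W`
   (edges × k) and time-dependent expression coefficients `H`
   (k × T·S) by minimizing

   ```
   ½‖X − WH‖²_F + η‖W‖²_F + β Σ_j ‖H_:j‖₁²,   W, H ≥ 0
   ```

   with deterministic NNDSVD initialization and alternating exact
   nonnegative least squares (block principal pivoting), so the objective
   decreases monotonically and results are reproducible without a random
   state.  η defaults to `max(X)²`; (k, β) can be chosen by masked-holdout
   cross-validation.
3. **System mapping.** Each subgraph is folded back to an `N × N` matrix
   and summarized over an a-priori partition of nodes into cognitive
   systems: within-system connectivity `R_s = Σ_{i,j∈P_s} V_ij / |P_s|²`,
   between-system connectivity `I_st = Σ_{i∈P_s, j∈P_t} V_ij /(|P_s||P_t|)`,
   locality skewness, and a node-label permutation test for which systems
   a subgraph expresses.
4. **Expression dynamics.** Per subject and subgraph, the coefficient
   series is summarized by energy `Σ S_n²`, histogram entropy
   `−Σ P log P` (10 equal-width bins), and the mean absolute temporal
   derivative; coefficients can be standardized by their per-subject,
   per-subgraph mean.  Inference uses Wilcoxon rank-sum group comparisons,
   an element-shuffle permutation null for the energy–entropy
   correlation, motion-correlation checks, and an age-residualized,
   permutation-tested behavior association.
5. **Synthetic cohorts.** Because suitable imaging data are
   access-restricted, a first-class generator plants known ground truth:
   subgraphs supported on one or two systems, two-state (high/low) Markov
   coefficient chains with silent transition windows, an "executive-like"
   subgraph whose energy and switching are elevated in the adult group,
   and an optional motion confound.  Every downstream claim is tested
   against this known answer.

## Worked example

```python
import numpy as np
from dynsubgraphs import (simulate_cohort, regress_motion, concatenate,
                          fit_sparse_nmf, match_components,
                          summarize_dynamics, group_compare)

cohort = simulate_cohort(n_regions=40, n_subjects=40, n_windows=51,
                         k_true=4, noise_sd=0.05, motion_slope=0.5, seed=7)
edges = regress_motion(cohort.connectivity, cohort.motion)
X = concatenate(edges)
res = fit_sparse_nmf(X.values, k=4, beta=0.01, max_iter=100)

gt = cohort.ground_truth
perm, corrs = match_components(res.W.T, gt.basis_true.T)
effect = int(perm[gt.effect_subgraph])
print("matched-subgraph correlations:", np.round(corrs, 3))

summary = summarize_dynamics(res.H, X.column_map,
                             group_labels=cohort.group_labels)
sub = summary[summary.subgraph == effect]
z, p = group_compare(sub["standardized_energy"].to_numpy(),
                     sub["group"].to_numpy(), group_order=("child", "adult"))
print(f"standardized energy: z = {z:.2f}, p = {p:.4f}")
```

Output:

```
matched-subgraph correlations: [0.996 0.991 0.988 0.989]
standardized energy: z = -2.88, p = 0.0040
```

The four learned subgraphs match the planted basis at correlation ≥ 0.98,
and the executive-like subgraph's standardized expression energy is
higher in the adult group (negative z under the (child, adult) ordering),
recovering the planted developmental effect.

There is also a CLI mirroring the pipeline stages:

```bash
dynsubgraphs simulate --n-regions 40 --n-subjects 40 --k-true 4 --seed 7 --out cohort.h5
dynsubgraphs build-networks --cohort cohort.h5 --out networks.h5
dynsubgraphs decompose --networks networks.h5 --k 4 --beta 1e-2
dynsubgraphs map-systems --networks networks.h5 --partition cohort.partition.tsv --out-dir systems/
dynsubgraphs analyze --networks networks.h5 --cohort cohort.h5 --out-dir dynamics/
dynsubgraphs run --config pipeline.yaml        # all stages + manifest
```

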