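# schybridnmf

Hybrid clustering of single cells from paired gene-expression and spatial
location data.

Spatially resolved single-cell technologies (STARmap, seqFISH+, and kin)
profile where each cell sits in a tissue alongside its expression of a
few hundred to a few thousand genes.  Neither modality alone identifies
cell types reliably: gene panels are small and noisy, while locations
only reflect type where the tissue is spatially organized.  This package
implements **scHybridNMF**, a consensus method that clusters cells by
combining sparse nonnegative matrix factorization (sparse NMF) of the
expression matrix with k-means clustering of the 2-D cell coordinates.

## Model

Let `A ∈ R₊^{m×n}` be the normalized expression of `m` genes in `n`
cells and `L ∈ R^{2×n}` their coordinates.  Sparse NMF factors
`A ≈ W_A H_A` (`W_A`: m×k cluster representatives, `H_A`: k×n
memberships) under

```
min_{W_A, H_A ≥ 0}  ‖A − W_A H_A‖²_F + β‖W_A‖²_F + γ Σᵢ ‖H_A(:,i)‖₁²
```

with data-driven defaults `β = m/‖A‖²_F`, `γ = n/‖A‖²_F`.  K-means on
`L` is the matrix problem `min ‖L − W_L H_L‖²_F` over binary one-hot
`H_L` (its objective is the within-cluster sum of squares).  The
location clustering is summarized by a *confidence matrix* `Ĥ_L`: for
each cell only its two nearest centroids receive mass,
`Ĥ_L(j,i) = d(j,i) / (d(j₁,i) + d(j₂,i))`, so each column has two
nonzeros summing to one.  The hybrid stage then minimizes

```
min_{W_A, H_A ≥ 0}  ‖A − W_A H_A‖²_F + α ‖H_A − H_A ∘ Ĥ_L‖²_F
```

where `∘` is the elementwise product and the consensus term equals
`‖H_A ∘ C‖²_F` with `C = 1 − Ĥ_L`.  The weight `α` sets how strongly
location clusters steer the expression-based memberships.  Optimization
is two-block coordinate descent with *exact* nonnegative least-squares
half-steps (block principal pivoting), so the objective is monotonically
non-increasing and limit points are stationary; iteration stops on a
normalized KKT residual (`tol`, default 0.01) or after `max_iter`
(default 500) sweeps.  Final hard labels are the per-cell argmax of
`H_A`.

## Worked example

```python
from schybridnmf import (SCHybridNMF, SimulationConfig, adjusted_rand_index,
                         make_benchmark, normalize_expression)

ds = make_benchmark(SimulationConfig(
    n_cells=200, n_genes=100, k=4, sigma=0.45,
    pattern="strong", noise_fraction=0.2, seed=11,
))
A = normalize_expression(ds.counts, ds.cell_ids)

model = SCHybridNMF(n_clusters=4, alpha=50.0, tol=0.02, random_state=11)
model.fit(A.T, locations=ds.locations.T)

print(f"termination: {model.termination_} after {model.n_iter_} iterations")
for name, labels in [("hybrid", model.labels_),
                     ("sparse NMF", model.nmf_labels_),
                     ("location k-means", model.kmeans_labels_)]:
    print(f"ARI({name} vs truth) = {adjusted_rand_index(ds.true_labels, labels):.3f}")
```

prints

```
termination: max_iter after 500 iterations
ARI(hybrid vs truth) = 1.000
ARI(sparse NMF vs truth) = 0.575
ARI(location k-means vs truth) = 0.533
```

The simulated tissue has four cell types in well-separated spatial
regions, but 20% of cells are placed in the wrong region and the
expression heterogeneity dial `sigma = 0.45` makes expression-only
clustering unreliable.  Each single-modality method plateaus (sparse NMF
at ARI 0.58, k-means capped by the location noise at 0.53) while the
consensus recovers the true types exactly.  The same pipeline is
available from the shell:

```
schybridnmf simulate --n-cells 200 --n-genes 100 -k 4 --sigma 0.45 --seed 11 --out sim/
schybridnmf run --expr sim/counts.mtx --genes sim/counts.genes.txt \
    --cells sim/counts.cells.txt --loc sim/locations.csv -k 4 --alpha 50 \
    --tol 0.02 --seed 11 --out run/
schybridnmf evaluate --truth sim/truth.tsv --pred run/labels.tsv
```

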