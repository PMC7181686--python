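# celldecon

Cell-type decomposition of bulk RNA-seq using single-cell and
single-nucleus references.

Bulk RNA-seq of a tissue sample measures a mixture of cell types.
`celldecon` estimates, for every bulk sample, what fraction of the
signal each cell type contributes. It is aimed at studies that pair a
large bulk cohort with a small single-cell/single-nucleus experiment on
a subset of the same tissue — the common design in which cell
composition itself is a phenotype of interest (e.g. adipose immune-cell
fractions vs. insulin resistance, or cortical neuron loss vs. dementia
severity).

## The model

Given a reference profile **Z** ∈ R^{m×k} (mean CPM of m genes in k
cell types, averaged over all annotated cells) and a bulk expression
vector x, proportions are estimated by least squares on the probability
simplex:

    p̂ = argmin ‖Z p − x‖₂   s.t.   p ≥ 0,  Σ p = 1

solved exactly by an active-set quadratic program (not NNLS followed by
renormalization).

Because bulk and single-nucleus platforms measure each gene with
systematic, gene-specific offsets, the bulk data are first mapped onto
the reference scale by a per-gene linear transformation, learned in one
of two ways from the pseudo-bulk **Y = Zp** of the n′ single-cell
individuals:

* **overlap**: OLS of Y_j on the overlapping individuals' bulk X′_j
  (`Y_j = β_j X′_j + ε_j`), applied to all bulk samples;
* **moment matching**: `X_j → (X_j − X̄_j)/σ_{X_j} · σ̂_j + Ȳ_j`, where
  σ̂_j² is the shrinkage variance `Σᵢ(Y_ij − Ȳ_j)²/(n′+1)` — deliberately
  below the unbiased estimate, since with few single-cell samples the
  observed spread of Y_j overstates the target spread.

A second, reference-free mode estimates *relative* abundances from
marker genes alone: for each cell type, the first principal component
of the standardized marker submatrix weighted by log-fold change
(weighted PCA), with the marker count chosen by maximizing the
first-to-second eigenvalue ratio over 25–200 markers (FDR < 0.05).

A simulation module generates synthetic annotated single-cell data and
bulk mixtures with gene-specific cross-platform bias (β_j ~ HN(σ)+1,
α_j ~ HN(σ) applied to summed counts), and an evaluation module
provides global Pearson-R/RMSD scoring, leave-one-out cross-validation
over reference individuals, and marker-ablation sweeps. See
`docs/methods.md` for the full model description, parameter defaults,
and what the synthetic checks do and do not demonstrate.

## Worked example

Simulate a tiny dataset (4 individuals, 3 cell types) with
cross-platform bias σ = 5, decompose it with the moment-matching
transform, and score against the generating proportions:

```sh
celldecon simulate --preset tiny --sigma 5 --seed 7 --out-dir sim
celldecon decompose-ref \
    --bulk sim/bulk.tsv --sc-matrix sim/sc_matrix.mtx \
    --features sim/features.tsv --barcodes sim/barcodes.tsv \
    --sc-annotations sim/annotations.tsv --markers sim/markers.tsv \
    --mode moment --out props.tsv
celldecon evaluate --estimates props.tsv --truth sim/true_proportions.tsv \
    --out eval.json
```

which prints

```
wrote synthetic dataset (tiny, sigma=5.0) to sim
wrote proportions to props.tsv
R = 0.9798, RMSD = 0.0392 -> eval.json
```

`props.tsv` holds the estimates (cell types × samples, columns on the
simplex) plus a per-sample residual norm ‖Zp̂ − x‖₂, elevated values of
which flag cell populations missing from the reference:

```
cell_type  ind1     ind2     ind3     ind4
type3      0.31834  0.20518  0.25652  0.31996
type1      0.37691  0.19156  0.21336  0.38066
type2      0.30475  0.60326  0.53012  0.29937
residual_norm  16978.5  9911.8  11651.4  13842.7
```

R = 0.98 means the 12 estimated proportions track the fractions
actually realized in the simulated annotations nearly linearly despite
the injected gene-specific bias; RMSD = 0.039 is the typical absolute
error per proportion. The same pipeline is available as library calls
(`celldecon.simulate_sc`, `celldecon.decompose_pipeline`,
`celldecon.global_metrics`, …).

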