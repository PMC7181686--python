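# Methods

## The decomposition model

Bulk RNA-seq of a solid tissue measures a mixture: the expression of
sample *i* is (approximately) a convex combination of cell-type-specific
expression profiles, weighted by the cell-type proportions in that
sample. Given a reference profile **Z** ∈ R^{m×k} (m genes, k cell
types) derived from single-cell or single-nucleus RNA-seq, `celldecon`
estimates the proportion vector **p**_i for each bulk sample by solving

    minimize  ‖Z p_i − x_i‖₂   subject to   p_i ≥ 0,  Σ_c p_{ic} = 1,

where x_i is the (transformed) bulk expression vector. Both constraints
are enforced jointly by a primal active-set quadratic program on the
non-negativity bounds, with the sum-to-one equality kept in the working
KKT system throughout; the KKT tolerance is 1e-10, appropriate for the
small k (≤ ~15) this problem ever sees. A penalty fallback (heavily
weighted sum-to-one row appended to Z, ordinary NNLS, renormalization)
is retained only as a cross-check, because renormalizing an NNLS
solution is not in general the constrained optimum. With linearly
dependent reference columns the objective minimum is still unique but
the minimizer may not be; the solver warns and returns one valid
minimizer.

### Reference construction

Genes are filtered before any normalization: only marker genes present
in both matrices are kept, minus genes with zero variance across single
cells, genes with zero total bulk expression, and mitochondrial genes
(ID prefix match, default `MT-`, case-insensitive; mitochondrial reads
in nucleus-sequencing data are extra-nuclear contamination and behave
inconsistently across platforms). The surviving counts are scaled to
counts-per-million (CPM) per sample. The reference column for cell type
c is the arithmetic mean of per-cell CPM vectors over every cell
labeled c, pooled across individuals with equal per-cell weight.
"Averaging relative abundances" admits a second reading — pool raw
counts per type, then CPM the pooled column — which is exposed as
`averaging="pooled_cpm"`; the per-cell mean is the default because it
weights each cell, not each read, equally. Z is not rescaled after gene
filtering.

Observed proportions **p** come from counting annotated cells per
individual, and the pseudo-bulk is **Y = Zp** — the expression each
individual's bulk would show if the reference and proportions were
exact.

### Cross-platform transformation

Bulk and single-nucleus measurements of the same gene differ
systematically (nuclear vs. whole-cell transcript capture, library
chemistry), and the discrepancy is gene-specific. Both correction modes
are per-gene affine maps of bulk expression onto the pseudo-bulk scale:

* **overlap** — when n′ ≥ 2 individuals have both bulk and single-cell
  data, each gene's pseudo-bulk values are regressed (OLS, with
  intercept) on the overlapping bulk values, and the fitted line is
  applied to all bulk samples. Genes with zero variance in the
  overlapping bulk fall back to moment matching (the slope is
  undefined).
* **moment matching** — otherwise, each gene is z-scored across bulk
  samples (unbiased, n−1 SD) and rescaled to the pseudo-bulk's mean and
  a *shrunken* SD: the variance target divides squared deviations by
  n′+1 rather than n′−1. With few single-cell individuals the sample
  variance of Y_j overstates the spread of the goal distribution; the
  n′+1 divisor is the classical MSE-minimizing shrinkage for a normal
  mean-unknown variance and is always below the unbiased estimate.
  The denominator of the z-score is the unbiased sample *SD* (not
  variance — units require it).

Transformed values can be negative; they are passed to the solver
unclipped by default (`clip_negative` exists for sensitivity analysis)
because the solver accepts arbitrary real responses and clipping would
bias the fit. Mode `auto` uses overlap when ≥ 2 shared sample IDs
exist, else moment matching. Fewer than three single-cell individuals
triggers a warning rather than an error: transforms remain defined at
n′ = 2 but their targets are noisy.

### Residual diagnostics

The per-sample residual norm ‖Zp − x‖₂ is attached to every estimate. A
cell population present in the bulk but missing from the reference
inflates residuals in the affected samples; across a cohort this shows
up as a multimodal residual distribution. `residual_diagnostics` fits
one- and two-component 1-D Gaussian mixtures and flags bimodality when
the two-component model wins on BIC *and* its means are separated by
more than the pooled within-component SD (the separation guard stops
micro-jitter around a single value from being called bimodal). Fewer
than four samples, or exactly constant residuals, are never flagged.

## Marker-based (reference-free) mode

When only marker genes and their differential-expression statistics are
available, relative abundances are estimated per cell type by weighted
PCA: markers significant at FDR < 0.05 are ranked by p-value; the
expression matrix (CPM → log1p) is optionally residualized against its
first global PC; marker columns are standardized and multiplied by
their log-fold-change weights; and the first PC of that weighted matrix
is the score. The score's sign is fixed by requiring the weight-weighted
mean marker–score correlation to be positive, and the score is
standardized (mean 0, SD 1). Scores are comparable across samples
within a cell type only — there is no absolute scale, and no
cross-cell-type calibration is attempted.

The marker count is selected by maximizing the ratio of the first to
second eigenvalue of the weighted PCA over counts 25–200 (step 5, a
speed choice; ties go to the smaller count; fewer than 25 available
markers are used in full with a warning). A large ratio indicates a
single dominant factor — the abundance signal — rather than several
competing ones. Log-fold-change weights are used exactly as supplied
(natural-log convention assumed; any positive rescaling of the weight
vector leaves the score unchanged). Markers shared between cell types
are kept in both lists by default (`drop_shared_markers` removes them).
Without weights the same pipeline runs with W = I.

The global-PC correction targets dataset-wide *technical* variation. On
synthetic mixtures there is none: the first global PC of simulated data
is itself composition signal, and residualizing against it removes real
signal (mean |Spearman| with truth drops from ~0.99 to ~0.8 on the
50-sample fixture). End-to-end synthetic checks therefore disable the
correction, and the correction operation is validated separately against
an explicit SVD projection. Passing those checks consequently says
nothing about how well the correction separates technical from
compositional variation in real data, where the two are entangled.

## The synthetic-data generator

`simulate_sc` emulates the data regime the method targets, at the scale
of a six-individual single-nucleus study of adipose tissue (6
individuals, 5 cell types, 1800 cells per individual by default; a
`dlpfc_like` preset scales the 8-individual, 11-cell-type cortex design
down to 800 cells per individual). Desk-scale choices: 1000 genes and
25 markers per cell type — enough genes for per-gene transform
statistics to average out, small enough that a full bias sweep runs in
minutes on one CPU.

* Per-gene baseline rates are log-normal around `base_rate` = 0.5
  counts/cell (≈ a 500-UMI cell over a 1000-gene panel, matching
  typical droplet-based nucleus data on a reduced panel), SD 1 log
  unit.
* Each cell type elevates its own disjoint marker set by a per-marker
  fold drawn uniformly in [0.5, 1.5] × (`marker_fold` − 1) + 1, with
  `marker_fold` = 5 (strong markers, ~1.6 natural-log fold change, the
  regime Seurat-style marker calling retains). At `marker_fold` = 1 the
  construction collapses exactly to no elevation, making marker and
  background genes exchangeable.
* Counts are negative-binomial with dispersion 2 (variance ≈ μ + μ²/2,
  the over-dispersion scale of droplet UMI counts).
* Composition per individual is Dirichlet(3, …, 3): all types usually
  present, with realistic person-to-person variation.
* The returned "truth" is the *realized* label fractions, not the
  Dirichlet draw, so downstream comparisons are against exactly what
  the annotation records.
* Marker-table p-values are assigned analytically, monotone decreasing
  in the simulated fold (p = e^(−8·lfc), FDR = min(1, 2p)) — rank
  information only, not a calibrated test.

Cross-platform bias is simulated per gene as out = β_j·in + α_j with
β_j ~ |N(0, σ²)| + 1 and α_j ~ |N(0, σ²)| (half-normal parameterized by
the underlying normal's σ), applied on the count scale before any
normalization, with one (β_j, α_j) shared across individuals. σ = 0 is
exactly the identity. The sweep grid is σ ∈ {0, 5, 10, 20} with 10
replicates, scored by leave-one-out cross-validation (moment-matching
transform vs. raw CPM), with 1000-resample percentile bootstrap CIs on
the replicate means.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects beyond the gene-linear bias model, gene–gene correlation beyond
shared composition, library-size confounding with cell type, or any
real dataset's expression distribution. Passing the synthetic checks
demonstrates the estimator's algebra and its robustness to the modeled
bias class, not performance on real tissue.

## Evaluation harness

Global Pearson R and RMSD pool all (cell type, sample) pairs;
per-sample metrics are computed within each sample's k pairs and
reported as mean ± SD — both are emitted because both conventions
appear in deconvolution benchmarking, and they answer different
questions (overall calibration vs. per-sample profile recovery;
per-sample R is computed across cell types within a sample). RMSD
between two simplex columns is bounded by √2. Leave-one-out CV rebuilds
the reference, proportions, and transform from the remaining
individuals for every fold; holding out an individual that is the sole
carrier of a cell type is an error rather than a silent k-change.

The marker-ablation harness removes a growing fraction of one cell
type's markers, in decreasing or increasing log-fold-change order, and
re-runs an arbitrary decomposition metric (on synthetic data, Spearman
correlation with the true proportions; default removal grid
{0, 0.25, 0.5, 0.75, 0.9}; fraction 1 is skipped). The robustness
checks use a 20-individual, 11-cell-type fixture targeting the rarest
type: with only 5 cell types the sum-to-one constraint lets the
remaining types' markers reconstruct the ablated type almost
perfectly, whereas the 11-type rare-target design — mirroring a
microglia-among-cortical-types scenario — exposes the expected
degradation at heavy removal.

Phenotype-association replication (mixed-model regression of estimates
on clinical traits) is out of scope; on synthetic data the generator's
ground-truth proportions serve as the association target instead.

## Numerical and degenerate-input conventions

* Active-set solver: feasibility/KKT tolerance 1e-10; safeguarded
  (Lawson–Hanson-style) partial steps guarantee monotone descent;
  estimates are asserted on-simplex (≥ 0, Σ = 1 within 1e-8) on every
  call.
* All-zero bulk column: decomposed normally (p = argmin ‖Zp‖ on the
  simplex), never an error; all-zero columns are rejected only by CPM
  normalization, where they are genuinely undefined.
* Zero-variance genes: dropped at filtering (single-cell side); at
  transform time, zero bulk SD under moment matching produces the
  constant target mean with a warning.
* Duplicate gene rows on input are summed (gene-name-level counting
  convention); duplicate sample IDs are a hard error.
* Proportion columns are validated to sum to 1 within 1e-8 (estimates)
  and 1e-12 (observed single-cell proportions).
* Seeds: every stochastic operation takes an explicit integer seed;
  compound procedures (bias sweep, acceptance script) derive child
  seeds via `numpy.random.SeedSequence` spawning, keeping all derived
  seeds below 2³¹.

## Known limitations

* The reference-based model assumes cell types are equally represented
  in single-cell and bulk sampling of the tissue; violations shift
  absolute estimates (rank order is preserved under moderate reference
  perturbation, as the robustness checks show).
* Moment matching needs several bulk samples to estimate per-gene bulk
  moments; it is undefined for a single bulk sample and unreliable for
  very few.
* The active-set solver is designed for small k; it is exact but not
  engineered for hundreds of cell types.
* Marker-based scores are relative; converting them to absolute
  proportions requires external calibration that this package does not
  attempt.
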