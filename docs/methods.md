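# Methods

## The model

`mvmwgl` predicts breast-cancer survival time (months) from gene expression
by chaining three learning paradigms over two graph views of a cohort.

**Feature selection.** Each gene *j* is scored on the training patients by
its Pearson correlation ρ<sub>j</sub> with survival time, converted to the
F-statistic F<sub>j</sub> = ρ<sub>j</sub>² / (1 − ρ<sub>j</sub>²) · (n − 2),
and the top-k genes by F are retained (k = 2000 by default; ties broken by
gene id). F is strictly increasing in |ρ|, so ranking by F equals ranking by
absolute correlation; the F scale is kept because it is the conventional
univariate-regression statistic. |ρ| = 1 maps to +∞ and ranks first;
zero-variance genes score 0 with a warning.

**Patient-similarity graphs.** Selected expression values are z-scored
column-wise with statistics fit on training patients only, then patients
*p*, *q* are connected when the cosine similarity of their feature vectors
reaches a threshold η (default 0.8): A<sub>pq</sub> = 1 iff
s<sub>pq</sub> ≥ η, p ≠ q. The graph built from raw standardized expression
is the BBSG; after representation learning the same construction applied to
the learned features yields the RBSG. The diagonal is forced to zero — the
self-contribution enters only through the GNN's closed-neighborhood
aggregation, avoiding double self-loops.

**Spectral pseudo-labels.** The BBSG's unnormalized Laplacian L = D − A is
eigendecomposed; the n_clusters smallest eigenvectors are clustered either
by the deterministic cluster-qr procedure (pivoted QR of the eigenvector
matrix followed by an orthogonal rotation towards the pivot rows; Damle,
Minden & Ying 2019) or by seeded k-means. Labels are canonicalized by first
occurrence. Two numerical choices make runs reproducible: each eigenvector's
largest-magnitude entry is made positive, and cluster indices are relabeled
deterministically. Isolated patients (degree 0) are excluded from the
eigenproblem — each isolated node adds a spurious zero eigenvalue, and once
the null space grows beyond n_clusters the retained eigenbasis is an
arbitrary rotation that no clustering step can decode — and are then
assigned to the cluster with the highest mean continuous similarity.
Pseudo-labels are a function of the graph alone; survival never enters.

**Self-supervised stage (gene view).** All patients share one undirected
gene-interaction graph; patient *i*'s copy carries node inputs
h⁰ = standardized expression. Two message-passing layers (GCN or GAT),
global mean pooling and a linear-softmax head are trained with Adam
(lr 0.001) for a fixed 40 epochs to classify each training patient's
pseudo-label (cross-entropy plus λ·‖Θ‖²). The GCN propagation operator is
Â = D̂^(−1/2)(M + I)D̂^(−1/2) with self-looped degrees; the GAT layer uses
single-head attention α<sub>ij</sub> = softmax<sub>j∈N(i)∪{i}</sub>
LeakyReLU(aᵀ[Wh<sub>i</sub> ‖ Wh<sub>j</sub>]) with negative slope 0.2.
ReLU follows every layer, including the last. After training, the
final-layer gene representations (dimension 4 per gene by default) are
concatenated into one patient feature H of length k·4, for **all** patients.

**Semi-supervised stage (patient view).** H is z-scored (training-patient
statistics) and the RBSG rebuilt from it at the same η. A node-level model
(two GCN or GAT layers into hidden width 64, then an MLP head 64→32→1) is
trained transductively on the full graph: aggregation draws on train,
validation and test neighbors, but the MSE loss (plus λ·‖Θ‖²) uses training
nodes only. Validation loss is recorded every epoch from detached
predictions and the model state at its argmin is returned (patience 50
within a 2000-epoch budget; an earlier 500-epoch budget was still improving
at the cap, so the budget was widened until the selection rule, not the
budget, decides).

The four configurations GCN/GCN, GAT/GCN, GCN/GAT, GAT/GAT are tagged
MVMWGL-GCNCN/-GATCN/-GCNAT/-GATAT. Single-view baselines reuse the same
machinery: GIG-GCN/GAT regress survival directly at the graph level on the
gene graph (no pseudo-labels, no patient graph); BSG-GCN/GAT run the node
regression on the raw-expression BBSG (no gene graph).

## Numerical core

No GPU framework is used: the layers, heads and Adam optimizer run on a
small reverse-mode automatic-differentiation engine over numpy arrays
written for this package (`mvmwgl.autodiff`). Its gradients are verified
against central finite differences, and each layer's matrix form against
brute-force per-node sums, in the test suite. Softmax uses max-subtraction;
attention masking adds −∞ outside the closed neighborhood before the shift.
Cross-entropy clamps probabilities at 1e-12 with a warning. All randomness
flows from seeded `numpy` generators, so repeated runs with one seed are
byte-identical.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `k_genes` | 2000 | genes kept by univariate F-ranking |
| `eta` | 0.8 | cosine threshold of both patient graphs; below ~0.8 the graph densifies into near-uniformity |
| `n_clusters` | 6 | spectral pseudo-label count |
| `repr_dim` | 4 | learned per-gene representation size |
| `n_layers` | 2 | message-passing depth of both stages |
| `ssl_epochs` | 40 | fixed self-supervised epochs (optional plateau stop: relative validation change < 1e-3 over 5 epochs) |
| `learning_rate` | 0.001 | Adam, both stages |
| `lambda_gig`, `lambda_bsg` | 1e-4 | squared-L2 penalty on all trainable parameters, added explicitly to each loss |
| `ssl_batch_size` | 32 | patients per self-supervised batch |
| `semi_epochs_max`, `patience` | 2000, 50 | budget and early stop for validation-based epoch selection |
| `hidden_dim`, `mlp_hidden` | 64, 32 | patient-level layer width and MLP head width |

## The synthetic cohort generator

Real cohorts of this kind are not redistributable, so the generator creates
cohorts with the statistical structure the model assumes, and the test suite
treats the generator's planted structure as ground truth.

* Patients are assigned uniformly to latent groups; survival time is the
  group's mean (defaults 10/30/70/120 months) plus Gaussian noise (sd 5
  months), clipped at zero with a warning. Group→survival is a mean-shift
  model, matching the pipeline's plain regression target; there is no
  censoring.
* The gene-interaction graph is a stochastic block model over gene modules
  (edge probabilities 0.3 within, 0.02 between by default).
* Informative genes (defaults: 45 of 60) carry a ±effect_size mean shift per
  group. The sign patterns are "thermometer" contrasts: groups are ordered
  by survival mean, each interaction **module** is assigned one contiguous
  split point along that order plus a random module-wide sign flip, and
  every informative gene inherits its module's pattern. This has three
  consequences the pipeline depends on: every informative gene is genuinely
  survival-informative (its mean tracks a monotone survival contrast);
  module-mates are co-regulated, so neighborhood averaging on the gene graph
  denoises instead of cancelling — the co-expression structure real
  interaction networks exhibit; and groups carry pairwise-distinct binary
  codes, i.e. they are separable in expression space.
* Expression noise sd defaults to 1.0 against effect size 2.0. This
  operating point is deliberate: with much less noise the raw-feature
  patient graph is already essentially perfect and the single-view node
  regression sits at the survival-noise floor, leaving representation
  learning nothing to add; with much more noise the cosine-0.8 graph
  underlying the whole method becomes empty. At 2:1 signal-to-noise the raw
  graph is informative but imperfect, which is the regime a multi-view
  method addresses.
* Splits are 60/20/20 train/validation/test, stratified by group to within
  one patient.

What the generator does **not** emulate: heavy-tailed expression marginals,
gene-gene correlation beyond block structure, censored follow-up, batch
effects, or any real cohort's marginal distributions. Passing tests
demonstrate that the pipeline recovers structure it is designed for when
that structure is present; they say nothing about performance on any
particular clinical dataset.

Two fixed fixtures support unit tests: `two-cliques` (10 patients in two
antipodal expression groups whose standardized cosine graph at η = 0.8 is
exactly two 5-cliques) and `four-groups-small` (80 patients, 24 genes, 4
groups).

## Degenerate inputs and edge cases

Zero-variance features standardize to all-zeros (warning); zero-norm rows
get cosine 0 to everything, never NaN; an edgeless graph at high η is a
warning, not an error, since the threshold sweep explores that regime; an
empty interaction list yields the identity propagation operator; survival
term boundaries are short ≤ 12 < medium ≤ 60 < long (months), with both
boundary values unit-tested.

## Known limitations

* Interaction types are loaded and stored but not used by any model
  operation; the gene graph is symmetrized and binary.
* Single-head attention; no dropout or batch normalization.
* The spectral stage fixes n_clusters; no eigengap or other automatic
  selection.
* When the thresholded graph has more connected components than clusters,
  a cluster necessarily spans several components; clustering quality then
  depends on the eigensolver's basis within the Laplacian null space.
* CPU-only by design; the intended scale is hundreds-to-thousands of
  patients and up to a few thousand genes.
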