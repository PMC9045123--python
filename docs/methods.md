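# Methods

## Model

Expression changes are modelled by a discrete-time linear state-space
system: hidden state x (length r), inputs u (experimental conditions),
observed log expression y over G genes,

    x(t+1) = A x(t) + B u(t),      y(t) = C x(t) + D u(t).

For a treated/control contrast the expression difference
Δy = y*(t) − y(t) is a linear image of the input contrast u* − u, so the
matrix of Δy columns collected over many contrasts has rank at most r plus
noise.  The degree of freedom (DOF) — the minimum number of state variables
representing all observed changes — is therefore the number of significant
dimensions of the SVD Δy = UΣVᵀ.  This is a model-based reading: the
variance not captured by the retained dimensions is attributed to
observation/system noise, not to additional regulatory components, which is
the key interpretive difference from model-free PCA.

## Degree-of-freedom estimation

The retained dimension is chosen by gene-split cross-validation:

1. Randomly split genes into a training set (default 4,000) and a held-out
   set; center every experiment by its training-gene mean and impute
   missing entries to 0 (the post-centering mean, a rank-neutral fill).
   Held-out genes are centered with the *training* means so no information
   leaks across the split.
2. Take the right singular vectors V of the training block.  For candidate
   rank k, P = V[:, :k] spans the experiment-space model and the held-out
   genes are scored by

       E_approx(k) = Σ_i ‖row_i · M‖²,  M = I − PPᵀ + diag(PPᵀ),

   where diag(·) keeps the diagonal of PPᵀ as a diagonal matrix.  The
   diag(PPᵀ) term is the leave-out correction of cross-validatory
   component-number selection: without it E would decrease monotonically in
   k.  M is symmetric, so applying it on the experiment axis of gene-row
   blocks is the canonical orientation used throughout.
3. Minimise E_approx over integer k by a golden-section search (below) and
   repeat over 15 random splits (repeat r uses seed + r).  The DOF estimate
   is the mean selected k; min/max/SD are reported alongside.

**Endpoint behaviour and the search bracket.**  E_approx(0) and
E_approx(full rank) both equal the held-out block's squared Frobenius norm,
so for *unstructured* data the error is maximal mid-bracket and flat-equal
at the endpoints.  The search bracket must therefore sit well below the
rank bound — the default is [1, min(800, rank bound) − 1], mirroring a
search initialised at 800 against corpora of several thousand experiments.
With the bracket in that regime, pure-noise data selects k at the bottom of
the bracket and structured data selects the interior minimum.

**Golden-section search on integers.**  Probe points are rounded to the
nearest integer (nudged by one on collision), evaluations are memoised, and
once the bracket width is ≤ 3 every remaining integer is evaluated
exhaustively.  Ties break toward smaller k (parsimony).  Unimodality is
assumed, not verified; the oracle tests compare against exhaustive scans.

**Data-size dependence.**  `dof_vs_datasize` re-estimates the DOF on seeded
subsamples (without replacement) of experiments or genes at several sizes —
one cross-validation per subsample by default, so the cost stays linear in
the number of subsamples — and reports per-size means, SDs and successive
increments.  `extrapolate_quadric` fits an OLS parabola to (size, mean DOF)
and returns its vertex (requiring a negative leading coefficient);
`extrapolate_linear_increments` fits a line to the increments and returns
its zero crossing.  Both are exact-fit-tested on analytic inputs.

## QC and centering

Three corpus filters, all strict inequalities, applied genes → coverage →
mean-abs: genes unobserved in more than 250 experiments; experiments
observing fewer than 4,000 genes; experiments whose mean absolute observed
value exceeds 0.5 (a normalisation-bias guard).  Centering is per
experiment (column) across genes, making each experiment a contrast among
genes — the orientation under which the left singular vectors describe
per-gene contributions.  Row-centering is deliberately not performed; the
choice is recorded here because only "centralized" is conventionally
specified for such corpora.  Whether gene missingness is counted before or
after experiment filtering is a free choice; the canonical order above is
fixed and the pipeline records counts removed per rule.

## Feature mapping

With X = U(m)Σ(m) (genes × m; columns orthogonal by construction), any
per-gene feature vector f maps to the state variables by least squares,
V̂ = (XᵀX)⁻¹Xᵀf, restricted to genes with observed values (requiring at
least m of them).  Features are mean-centered over observed genes by
default, consistent with the centered corpus; `center=False` is available
because the absolute weight scale depends on this choice.  The normal
equations are solved through an SPD factorisation with a tiny ridge
(1e−10 · trace(XᵀX)/m) that only guards degenerate observation masks.

Promoters are the 500 bp upstream of the annotated gene start (plus
strand) or downstream of the annotated end, reverse-complemented (minus
strand), truncated — never padded — at contig edges.  Both GFF3 (1-based
inclusive) and BED6 (0-based half-open) dialects are read and converted to
one internal convention.  Motif presence is binary over the 4⁸ = 65,536
8-mers, scanned on the promoter's own 5′→3′ sense only (no
reverse-complement collapsing), windows containing N skipped, multiplicity
ignored.  The motif index is base-4 big-endian with A=0, C=1, G=2, T=3, so
index order equals lexicographic string order.

## Information capacity

Per state variable, the ⌈1% N⌉ largest-weight motifs get +1 and the
⌊1% N⌋ smallest get −1 (656 + 655 = 1,311 for the full universe; the
ceiling/floor split is chosen to make the total exact; ties break by motif
string).  Rows of the resulting {−1, 0, +1} matrix are grouped by identical
configuration; the capacity of the system is H = −Σ pᵢ log₂ pᵢ over group
frequencies, with maximum log₂ 65,536 = 16 bits when every row is distinct.
Per promoter, qᵢ is the fraction of variables selecting motif i; with k
selected motifs present, H(j) = −(1/k) Σ qᵢ log₂ qᵢ.  Genes with k = 0
have undefined capacity and are excluded from the ranking (not assigned 0).
The ranking is ascending in H(j) — shared, low-information promoters
first — and is written as a header-free two-column `.rnk` file for
preranked enrichment tools; running those tools is out of scope.

## Coordinate system

`build_tcsy` truncates the corpus SVD to its top m dimensions (m = 450 by
convention for a full-scale corpus; any m up to the available rank) and
serializes X with a provenance fingerprint (hash of gene list + build
parameters) so projections against a mismatched basis fail loudly.
Projection solves the same masked normal equations as feature mapping and
reports the residual fraction; per-dimension variance explained is the
squared orthogonal projection onto each (normalised) basis direction over
the data's total sum of squares.  State comparison uses Pearson correlation
on raw expression-change vectors (coordinate-space correlation is the
alternative mode); zero-variance vectors yield missing entries rather than
errors.  The parallel-coordinate export writes raw coordinates plus
per-group, per-dimension SDs and leaves any normalisation to the caller.

## Synthetic data

The generator emulates the three inputs the analysis consumes:

- **Expression**: Δy = U diag(s) Vᵀ + ε with U, V random orthonormal
  frames (QR of seeded Gaussians, Haar-direction), a non-increasing
  singular profile, i.i.d. Gaussian noise, and a uniform
  missing-at-random mask applied after the noise.  Gaussian observation
  noise and uniform missingness are modelling assumptions of the
  generator, not properties derived from any real corpus.
- **Promoters**: uniform ACGT background; each planted 8-mer overwrites a
  seeded uniform position with probability = enrichment × rank scale on
  its target variable's loadings, where the top decile of genes receives
  the full enrichment and the remainder declines linearly to zero.  The
  promoters are embedded in a toy genome (one contig per 1,000 genes,
  alternating strands, 60-nt gene bodies) laid out so extraction inverts
  generation exactly.
- **GO annotations**: membership probability
  sigmoid(logit(0.15) + coupling · z) with z the standardized loading on
  the term's designated variable; coupling 0 gives independence at a 15%
  base rate.

What passing tests on this data do *not* show: real promoter composition
(GC content, nucleosome positioning, motif clustering), structured
missingness, inter-experiment correlation, or heavy-tailed noise.  The
generator validates the estimation machinery, not biological conclusions.

## Numerical choices and problem sizes

- SVD sign convention: the largest-|entry| of each left singular vector is
  positive, so serialized bases are bit-reproducible.
- All randomness flows from one user seed; repeat r of the CV uses
  seed + r; nested sweeps derive child seeds from `(seed, size, repeat)`
  seed sequences.
- DOF summaries use the sample SD (ddof = 1).
- The test and acceptance workloads use scaled-down corpora chosen to
  exercise the same signal-to-noise regime as a full compendium: the
  parameter-recovery benchmark plants rank 20 in 2,000 genes × 500
  experiments with singular values 50→10 against noise SD 0.1 (smallest
  structured singular value ≈ 2.4× the noise floor of the training
  block), and detection benchmarks use 800-gene worlds with one planted
  motif per variable of interest.

## Known limitations

- The CV error's unimodality in k is assumed by the golden-section search;
  heavily non-unimodal error curves (possible at very low SNR) can return
  a local minimum.
- `map_all_motifs` materialises a dense 65,536 × m weight matrix
  (~236 MB at m = 450); per-motif streaming would be needed far beyond
  that.
- Strict-inequality QC thresholds and the ceiling/floor selection split
  are fixed conventions; equivalent readings (e.g. round(2% N)) differ
  only in degenerate tie cases.
- The real-corpus reference behaviour (DOF near 390 for a ~6,300
  experiment yeast compendium, ~89% variance explained at m = 450, group
  entropy ≈ 5.5 bits) requires the external corpus and is not recomputed
  here; the package documents the procedure and validates it on synthetic
  ground truth.
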