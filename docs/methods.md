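# Methods

## Model and assumptions

Each single cell of a cell type is treated as one noisy binary vote on
which genomic peaks are open. Binarization (open iff ≥ 1 read) removes
depth differences between datasets at the cost of quantitative signal; all
downstream statistics are built for binary data. The quality model is
agreement-based: a cell whose open-peak set resembles the other cells of
its type is trusted more. With Jaccard matrix J (n × n, diagonal 1), the
weight of cell i is

    w_i = Σ_{j≠i} J_ij / Σ_{j≠k} J_jk ,

the denominator running over all ordered pairs j ≠ k, which is the unique
normalization under which Σ w_i = 1 and the consensus score
S(i) = Σ_j w_j S_j(i) stays in [0, 1]. The index constraint on the
denominator could also be read as excluding pairs involving i; that
variant destroys the sum-to-one property, so the ordered-pair reading is
used.

Exact invariances of this estimator, all tested: permutation of cells
(with weights), uniform weights reducing to the plain open fraction, and
linearity (duplicating cells with halved weights). Duplicating cells and
*recomputing* weights is invariant only asymptotically — each copy has
Jaccard 1 with its twin, a perturbation decaying ~ n⁻² (measured
1.8 × 10⁻⁴ at n = 100); tests assert 10⁻³ at that size.

## Signal null

The null asks how large a consensus score arises when each cell keeps its
depth (open-peak count) but loses all positional information: per
shuffle, every cell's open entries move to uniformly random peaks and the
consensus is recomputed with the same weights. All shuffled per-peak
scores are pooled into a single distribution (a global rather than
per-peak threshold — per-peak nulls would be identical anyway, as the
shuffle is exchangeable over peaks); a peak passes iff its observed score
is *strictly* greater than the 95th percentile (ties fail, which makes
the rule reproducible). Defaults: 100 shuffles, percentile 95, seed
required and logged. On exchangeable noise the pass fraction is ~5% by
construction; this calibration is asserted in the acceptance suite.

## Region filters

Candidate enhancers must be distal: any ≥ 1 bp overlap with an exon, a
promoter window, or a known silencer excludes a peak. The promoter window
defaults to TSS − 1000 bp to TSS + 100 bp, strand-aware (a conventional
choice; no canonical definition exists), and is configurable. Promoter
peaks excluded from candidacy still participate as connection endpoints —
otherwise the promoter-connection requirement would be unsatisfiable.

## Co-accessibility

Sparse binary matrices do not support direct covariance estimation, so
the matrix is TF-IDF normalized (TF: columns divided by column sums; IDF:
log(1 + n_cells / rowSums), natural log), reduced by truncated SVD with
the first component dropped (it tracks read depth), and cells are summed
into metacells: seed cells are sampled without replacement in random
order, each uncovered seed adopts its k = 50 nearest neighbors in LSI
space, and sampling stops when every cell is covered. The SVD is computed
densely (LAPACK): the matrices handled here are at most a few thousand
cells, and a dense decomposition is deterministic, which end-to-end
byte-identical reproducibility requires. Component signs are fixed by
making each component's largest-magnitude peak loading positive. A 2-D
UMAP (`embed_2d`) is provided for visualization only; aggregation runs in
the full LSI space, because kNN in two dimensions discards information
and adds a heavy stochastic dependency on the critical path.

Within overlapping 500 kb windows (50% overlap, peaks assigned by
midpoint), metacell counts are z-scored per peak and a graphical lasso is
fit to the correlation matrix (a small diagonal ridge, 10⁻³, guards
conditioning). The penalty on pair (i, j) is affine in genomic distance:

    ρ_ij = 0.4 + 0.25 · d_ij / window_bp .

The distance term encodes the prior that regulatory contacts decay with
distance. The constant floor is a small-sample necessity: with ~50–70
overlapping metacells the sampling noise of a correlation is ~0.16 sd, so
a penalty floor ≈ 2.5 sd is needed to keep noise partial correlations
from crossing the 0.1 connection cutoff; a purely distance-proportional
penalty is near zero at short range and floods the output with
short-range false links. Both terms are configurable
(`penalty_base`, `distance_penalty_scale`).

Peaks open in fewer than `min_open_frac` (default 5%) of cells are
excluded from estimation (in aggregated units: mean metacell count
< 0.05 k). At that sparsity an aggregated count vector is essentially an
indicator of which metacells contain the few open cells, and two
unrelated rare peaks that happen to co-open in one cell show raw
correlations approaching 1. This mirrors standard scATAC practice of
minimum-accessibility feature filtering before covariance estimation.

The graphical lasso itself is a block coordinate descent on the
covariance estimate with an elementwise L1 penalty matrix (the scalar-
penalty implementations in common libraries cannot express the distance
prior); the inner lasso is solved by coordinate descent, numba-compiled.
Tests verify it against direct minimization of the penalized negative
log-likelihood and against matrix inversion at zero penalty. The
co-accessibility score of a pair is the negated, rescaled partial
correlation −Θ_ij/√(Θ_ii Θ_jj), clamped to [−1, 1]; pairs appearing in
several windows get the mean. The connection cutoff is ≥ 0.1 (the
boundary is included; configurable).

## Evaluation

Sensitivity/specificity/AROC are computed per base pair by exact interval
arithmetic: positives are universe bp covered by the gold set, a bp is
predicted positive at threshold t iff covered by a prediction scoring
≥ t, and partial overlaps contribute partial true positives. The
threshold sweep covers every distinct score with sentinels at ±∞, so the
curve spans (0,0)–(1,1) and the trapezoidal area is invariant under
strictly monotone score transforms. The universe defaults to the peak
space under consideration; a universe with no negative bp (fully covered
by gold) is rejected rather than reported as a degenerate area.

## Synthetic fixtures

The generator emulates exactly the structure the method assumes: one
synthetic chromosome ("chrS", admitted by the default chromosome
allow-pattern) with non-overlapping, evenly spaced peaks; per cell type a
planted set of enhancer peaks opening at `p_open_enhancer` (default 0.4)
against `p_open_background` (0.02); synthetic genes whose TSSs sit at a
configurable fraction of peaks (promoter peaks); and planted
distal/promoter pairs that co-open through a shared latent Bernoulli —
with probability `pair_correlation` (0.8) both peaks copy one latent
draw of rate `p_open_pair` (0.3), otherwise they draw independently,
giving pairwise correlation equal to `pair_correlation`. A per-cell depth
multiplier (uniform on 0.7–1.3) scales all open probabilities. The
default configuration is 2 cell types × 200 cells × 1000 peaks on 3 Mb,
20 planted enhancers per type and 20 pairs at 10–250 kb separation.

`p_open_pair` exists because planted pairs need an open rate well above
background to carry a recoverable co-accessibility signal; it is distinct
from the enhancer rate so pair peaks and signal peaks remain separately
identifiable.

At these simulated depths a cell opens ~40 peaks, far below the
real-data QC default of 200 open peaks per cell;
`FixtureConfig.suggested_min_peaks_per_cell()` (half the expected count
at minimum depth, 13 under defaults) supplies the depth cutoff matched
to the simulation, while all other thresholds keep their operating
values. What the fixtures do not emulate: fragment-level counts, GC or
Tn5 bias, doublets, overlapping peak calls across datasets, chromatin
domain structure, or distance-decaying background co-accessibility —
so passing tests demonstrate correctness of the estimators under the
stated model, not performance on any particular tissue.

## Numerical and degenerate-input conventions

- Coordinates are 0-based half-open everywhere; abutting intervals do not
  overlap. Peak ids default to `chrom:start-end`; `chrom:start-end` and
  `chrom_start_end` sidecar dialects are both parsed.
- Strand is ignored for peaks and overlaps; it matters only for promoter
  windows.
- Jaccard of two empty cells is undefined and raises; a whole matrix of
  pairwise-disjoint cells falls back to uniform weights with a warning.
- Cell weights require n ≥ 2 cells.
- QC iterates cell-depth and zero-peak filters to a fixed point (each can
  trigger the other), making the result order-independent and the filter
  idempotent; an empty result raises rather than propagating.
- Merging datasets unifies peaks by interval union (book-ended intervals
  merge; `merge_gap` default 0) with OR-projection of cell signals; a
  dataset with < 200 distinct peaks is rejected as irregular.
- All randomness flows from one run seed through stage-name-derived
  sub-seeds (`derive_seed`), so any stage can be rerun in isolation and
  full runs are byte-identical.
- Problem sizes: the shipped benchmark and test suite run on the default
  fixture (400 cells, 1000 peaks), where the full pipeline completes in
  seconds; windows of several hundred peaks remain comfortably within
  the graphical lasso's range.

## Known limitations

- Weights assume within-type homogeneity; strong subpopulation structure
  makes agreement weighting favor the majority subpopulation.
- The global (pooled) null threshold treats peaks exchangeably; peaks
  with atypical mappability or width are not modeled.
- Co-accessibility estimates degrade when metacells are few or heavily
  overlapping; the penalty floor trades recall of weak links for
  precision, and scores are not comparable across datasets of very
  different sparsity without re-tuning `penalty_base`.
- The evaluation universe choice materially affects specificity; results
  should always state the universe used.
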