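# Methods

## Problem and model

`clusterfold` compares groups of cells (clusters, cell types, states)
across two or more independent single-cell datasets without integrating
them into a joint embedding. The only requirement is a set of features
shared by all datasets (genes, transcripts, ATAC-derived gene activities,
or proteins — matched by exact identifier; cross-species ortholog mapping
is the user's responsibility upstream).

The unit of comparison is the **frame of reference** of a group: for a
focal group *i* in a dataset with *k* groups, the k−1 vectors of log2
fold changes of *i* against every other group *j* of the *same* dataset.
Because every fold change is a within-dataset contrast, library-size and
platform batch effects cancel, which is what makes the cross-dataset
comparison possible without batch correction.

### Empirical-Bayes fold changes

Per-group mean raw counts Cn, Cm of a feature are treated as Poisson
means with a gamma prior, so additive pseudocounts α (numerator group)
and β (denominator group) arise naturally and keep fold changes finite at
zero counts. The prior is fitted empirically per ordered group pair:

- **Informative features** — strictly positive mean in *both* groups —
  give raw fold changes log2(Cn) − log2(Cm). With at least three of
  them, the prior mean μ is their average (the mean, not the median, to
  let low-abundance extremes inform the prior) and the prior sd is the
  larger one-sided spread of the 0.84 / 0.15 quantiles around μ (one sd
  under normality); σ² is its square. Quantiles use linear interpolation
  between order statistics (numpy's default, "type 7"); the choice is
  fixed and documented because different quantile rules move σ² slightly.
- **Fallback** (fewer than three informative features): every feature
  enters after a per-entry pseudocount p = sqrt(C² + 1) — an asinh-style
  value proportional to the entry itself — and σ² is the plain sample
  variance (ddof = 1).
- σ² is floored at ε = 1e−6: the trigamma equation below needs σ² > 0.

The pseudocounts solve the moment equations

    ψ(α) − ψ(β)  = μ · ln 2
    ψ₁(α) + ψ₁(β) = σ² · ln² 2

(ψ, ψ₁: digamma, trigamma), implemented as a least-squares minimization
of the two residuals over (log α, log β) — the log parameterization
enforces positivity — starting from α = β = 1 (Levenberg–Marquardt,
converged when the objective is below 1e−10 or the gradient norm below
1e−8; otherwise a `PseudocountSolverError` carries the last iterate).
Minimizing the squared residuals is exactly the stated objective; the
solution is recovered to ~1e−15 relative error on a log grid over
[0.1, 10]² (see `scripts/acceptance.py`).

The posterior fold change per feature is then

    FC = (ψ(Cn + α) − ψ(Cm + β)) / ln 2 ,

and each contrast vector is median-centred ("median to zero") so its
distribution sits at 0.

### Subsampling stabilization

Low-count noise produces spuriously large fold changes. Each contrast is
therefore recomputed over `n_subsamples` random draws (default 30) of
⌈fraction × group size⌉ cells per group (default fraction 1/3, without
replacement, minimum one cell) and averaged element-wise. The prior and
pseudocounts are re-estimated inside every draw, since the subsampled
means change. Averaging median-zero draws leaves a tiny residual median,
so the averaged columns are re-centred once more; with a single draw at
fraction 1 this is a no-op and the pipeline reduces exactly to the
un-subsampled computation.

Sampling details the method statement leaves open were fixed as: ceiling
rounding, no replacement, and one global seed expanded into independent
per-(draw, group) substreams (`numpy` `SeedSequence` spawn keys), with
cells indexed by sorted cell id so results do not depend on the column
order of the input matrix. `expected_permutations(n) = 3·Σ_{j=1..n}
1/(j+1)` is exposed as a utility for choosing the draw count.

The acceptance suite verifies the intended behaviour: on null features
(identical rates, mean ≤ 2 counts) the mean |FC| after 30 draws falls
well below the single-draw value (ratio ≈ 0.65 in the shipped run),
while planted |log2FC| = 3 markers keep essentially all of their
magnitude (ratio ≈ 1.0).

### Similarity score

For groups i (dataset A, p = k_A−1 contrasts) and j (dataset B, q =
k_B−1 contrasts), all p·q pairwise products of contrast columns are
formed per feature and averaged into the **SC score**; positive SC means
the feature changes concordantly in both frames of reference. With
d = #{SC > 0.2} − #{SC < −0.2}, the concordance weight is ω =
ln(|d|)·sign(d) (0 at d = 0, where ln is undefined and there is no
concordance evidence; natural log — the base is not prescribed and the
score is used for ranking). The similarity is

    similarity = (sqrt(|Σ SC|) + ω) · sign(Σ SC) ,

0 when the sum is 0. The |SC| > 0.2 cut is exposed as a parameter
(`sc_threshold`); 0.2 is the default regardless of modality. Features
ranked by SC are reported as the markers driving each match (default top
10, ties broken lexicographically). Σ SC, ω, and hence the similarity
value are symmetric in the two groups; direction in the output graph
records only which dataset was the source.

With more than two datasets, similarities are computed for every ordered
dataset pair (pairwise (k_a−1)(k_b−1) products) rather than multiplying
contrast counts across all datasets simultaneously; the output covers
every group combination.

### Graph and communities

Per source node and external dataset the `top_n` (default 1) highest
similarities become directed edges, negative values kept as-is. For
community detection the graph is symmetrized (max of the two directions)
and weights shifted by −min(0, min weight) so they are nonnegative —
Leiden objectives assume nonnegative weights; exports keep raw
similarities. Communities use the Leiden algorithm (local moving,
refinement, aggregation; `leidenalg`), modularity objective with a
resolution parameter (default 1.0) and a fixed seed; community ids are
relabelled 0-based by size. Whether the original procedure ran on the
directed or symmetrized graph is not specified; symmetrization is this
package's documented choice. Graph drawing is a convenience PNG with a
deterministic force-directed layout, not part of the tested surface.

## Synthetic data generator

`clusterfold.synthetic` emulates multi-dataset experiments with known
ground truth. Counts are negative binomial with variance
mean + dispersion·mean² (dispersion 0.5), per-feature base means
log-normal around `base_mean` (default 2 counts/cell) and shared across
datasets; each group owns a disjoint block of `n_markers_per_group`
features whose mean is multiplied by 2^`marker_log2fc` inside that
group. Marker assignment is conserved across datasets while sampling and
an optional per-dataset library-size factor (`batch_scale`) are
independent. The mixture generator adds one query group drawn from
several reference group profiles at fixed proportions.

Default study conditions follow the method's validation setting: two
datasets, 10 groups × 200 cells, 2000 features, marker log2FC = 3,
subsampling n = 30. What the generator does **not** emulate: zero
inflation beyond NB sampling, gene–gene correlation (real-data copulas),
ambient RNA, doublets, or cluster-size imbalance. Passing tests
therefore demonstrate correctness of the statistical machinery and
robustness to overdispersed counts and library-size batch effects — not
performance on arbitrary real tissues.

## Problem sizes used in tests and acceptance runs

Chosen as the package's own desk-scale validation conditions:

- self-match / label transfer: the full default config above, at planted
  log2FC = 3 and at 0 (null; accuracy should sit at the 1/10 chance
  level);
- shrinkage: one dataset, 2 groups × 150 cells, 800 features (40
  planted), base mean 2;
- mixture monotonicity: 5 groups × 120 cells, 600 features, markers
  log2FC = 2.5, proportions (0.6, 0.3, 0.1), 20 seeded replicates,
  6 subsample draws.

## Numerical choices and degenerate inputs

- All logs in fold changes are base 2; digamma arithmetic is natural-log
  and converted by ln 2 factors.
- Groups need ≥ 2 cells (1/3 subsampling must be able to vary); features
  and cells must have unique ids — duplicate feature symbols are
  rejected, not aggregated.
- Counts may be fractional (gene-activity scores); they are never
  rounded.
- Constant fold-change vectors floor σ² to ε rather than failing.
- sign(0) = 0 throughout; ties in top-feature and top-edge selection
  break lexicographically; records are emitted in sorted key order, so
  every output is deterministic for a fixed seed and independent of the
  `--jobs` setting (draws are reduced in draw-index order).

## Known limitations

- Similarity values have no significance calibration (by design: the
  method ranks matches rather than testing hypotheses).
- The |SC| > 0.2 concordance cut is a heuristic constant in log2²
  product units; for modalities with compressed dynamic range it may
  need adjusting via `sc_threshold`.
- Pairwise dataset handling means k-way information is aggregated
  through the graph, not through a single k-way product.
- The prior is fitted per ordered pair from the subsampled means; with
  very few shared features (< 3 informative) the asinh fallback makes
  the prior noticeably wider.
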