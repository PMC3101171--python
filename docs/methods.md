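# Methods

## Model and procedure

The pipeline treats TF coordination as a *shared-nearest-neighbor*
property of a coexpression network rather than a pairwise-correlation
property. Given a preprocessed expression matrix over genes
G = {x₁…x_q} and a designated TF subset T = {y₁…y_p} (p ≥ 2, m ≥ 2
samples):

1. **Association.** For each TF, its association with every other gene is
   computed. The default is Spearman's ρ, implemented as the
   product-moment correlation of average ranks; with no ties this equals
   1 − 6Σd²/(m(m²−1)). Alternatives: Pearson's r, and the two-sided
   p-value of the slope in the simple regression gene ~ tf (identical to
   the Pearson correlation-test p-value; ranked ascending). Association
   with a constant profile is undefined: constant TFs are skipped with a
   warning, constant genes receive NaN scores and sort last.
2. **Neighborhoods.** The top-Ω genes per TF form its neighborhood G_i.
   The TF itself is excluded (its self-correlation would waste a slot);
   ties at the Ω boundary break lexicographically by gene id so results
   are deterministic. Ranking uses signed ρ descending by default
   ("most coexpressed" read as positive coordination); an absolute-value
   mode is available. Scoring is streamed one TF at a time against a
   precomputed rank basis, so no q×p score matrix is ever held.
3. **SCCM.** a_ij = |G_i ∩ G_j| as a pure set intersection (rank order
   inside neighborhoods is irrelevant). Zero entries are never stored;
   the matrix is sparse upper-triangular with symmetric lookup, and the
   diagonal is undefined. Neighborhoods may contain other TFs — the gene
   universe is the whole matrix.
4. **Significance.** μ and δ are the mean and *sample* (n−1) standard
   deviation of the non-zero connectivities; with a single entry δ := 0.
   A link is significant at stringency θ when n_c > μ + θδ, **strictly**.
5. **Triple-Link.** Seed = available pair with maximal n_c, required
   > τ₁ = μ + θ₁δ (ties: lexicographic). A third member's two strongest
   links must beat (τ₁, τ₂); every later member's three strongest links
   must beat (τ₁, τ₂, τ₃). Among the candidates qualifying in a round,
   the one with the greatest total connectivity to the current members
   joins (ties lexicographic). Growth stops when no candidate qualifies;
   the cluster's members leave the pool and seeding repeats; the
   procedure ends when no available pair exceeds τ₁. Because τ₁ is fixed
   and availability only shrinks, seed connectivities are non-increasing
   across clusters: extraction order is a significance order.

### Threshold-to-link mapping

How three stringencies map onto individual link checks is a genuinely
open design point. This implementation guards the *strongest required
link with the strictest threshold*: (τ₁, τ₂) for the third member,
(τ₁, τ₂, τ₃) afterwards. This uses all three θ, respects the mandated
θ₁ > θ₂ > θ₃ ordering, and degenerates sensibly when δ = 0 (all τ equal
μ). An alternative single-θ-per-pass reading exists; the audit records
(below) make the applied rule fully transparent either way.

### Fixed vs recomputed statistics

μ and δ are computed once from the full SCCM, not after each cluster
removal: they are properties of the matrix, and freezing them keeps
extraction order well defined. `decompose(..., recompute_stats=True)`
re-derives them from the surviving entries each round for comparison.

### Auditability

Every join stores the witnessing links and the thresholds they beat;
`JoinAudit.replay()` re-evaluates the stored decision, and the test
suite replays all audits of randomized decompositions against the
matrix. The run log records μ, δ, every τ, and each cluster's seed pair
so any number in it can be recomputed from the written tables.

## Parameters

| name | default | meaning |
|------|---------|---------|
| Ω (`omega`) | 100 | neighborhood size; 50/100/150 are the vetted menu, 100 balances discovery rate against the false positives a top-150 list admits. Other values warn. |
| method | spearman | association measure; rank-based, appropriate for the non-Gaussian marginals typical of compendia |
| direction | positive | rank by signed ρ; `absolute` ranks by \|ρ\| |
| ψ (`min_samples`) | 50 | empirical floor on samples for meaningful coexpression; m < ψ warns (compendia ≤ 30 chips are generally unusable), never errors |
| θ₁, θ₂, θ₃ | 2.0, 1.5, 1.0 | stringency multipliers, midpoints of the empirical envelopes [1.5, 2.5], [1.0, 2.0], [0.5, 1.5]; strict ordering enforced, out-of-envelope values warn |
| workers | 1 | per-TF scoring parallelism; results are byte-identical for any value |

Missing-value policy on load is `error` (default) or `drop-gene`; ranks
are undefined with holes, so no imputation is offered. Identifiers are
opaque case-sensitive strings. All tabular output is TSV, '.' decimal,
Unix newlines, 6 significant digits — bit-stable across runs.

## Synthetic data: what it emulates and what it does not

`SyntheticSpec` plants B modules, each driven by one standard-normal
latent factor per sample; the module's TFs *and* its target genes load
on the factor as α·f_b + noise_sd·ε, so module TFs genuinely share
coexpressed targets — the mechanism the SCCM detects — rather than
merely correlating with one another. Background TFs/genes are
independent standard normal. The default lognormal marginal
exponentiates the latent values, reproducing the skewed,
normality-rejecting distributions of real compendia (Spearman is
invariant to this transform; Pearson is not, which is what
`compare_methods` demonstrates). Defaults: 3 modules × 8 TFs × 40
targets, 100 background TFs, 500 background genes, m = 60, α = 1.0,
noise_sd = 0.5.

Not emulated: probe effects, batch/platform structure, correlated
background modules, heteroscedastic noise, or genome-scale gene counts.
The last point matters for interpreting results: at desk scale
Ω/q = 100/744 ≈ 13% (against well under 1% on a real genome), so two
*unrelated* TFs share ≈ Ω²/q ≈ 13 neighborhood genes by chance, and at
m = 60 a background TF can reach |ρ| ≈ 0.3 with a latent factor by
chance alone, flooding its top-100 with that module's genes. Such TFs
are, in the drawn data, genuinely coordinated with the module — so
recovery is scored over the module TFs (a background TF recruited into
a module cluster is not penalized; an unclustered module TF is). Chains
of factor-tracking background TFs can also bridge two modules'
clusters; with default thresholds this merges a module pair in roughly
half of the seeds, which is the dominant failure mode visible in the
benchmark (a merged pair yields ARI ≈ 0.55 instead of 1.0). The
noiseless Gaussian variant recovers the planted modules exactly
(ARI = 1.0). Passing synthetic tests therefore demonstrates correctness
of the machinery and behavior under the stated conditions — not
genome-scale performance, where the chance-overlap floor is far lower.

## Recovery scoring

`score_recovery` computes the adjusted Rand index between predicted
cluster labels (cluster id, or "unclustered") and planted module labels
over the module TFs; `include_background=True` widens the basis to all
TFs with "background" as their true label, a stricter score that also
penalizes background recruitment. Per-module precision/recall are
reported against each module's best-matching cluster. The ARI itself is
delegated to scikit-learn; the test suite checks it against the
closed-form contingency formula on a hand-built table.

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1] before the regression t-transform;
  exactly collinear profiles get p = 0.
- All significance comparisons are strict (>); a link exactly equal to a
  threshold never qualifies, and a seed pair exactly at τ₁ terminates
  decomposition.
- Tie-breaks are lexicographic everywhere (neighborhood boundary, seed
  pair, join order), making every stage deterministic; parallel scoring
  merges in TF-list order.
- Empty SCCM (no shared genes at all) is an error with remediation
  advice; a single non-zero entry is handled (δ = 0, all τ = μ).
- ψ and the Ω menu are guidance, not validity conditions: both warn.

## Known limitations

- The Triple-Link link-mapping is one defensible reading of an
  under-specified rule (see above).
- Greedy growth is order-dependent in its *join sequence* but not in
  final membership: once a candidate qualifies it remains qualified as
  the cluster grows, so membership is the closure of the seed under the
  qualification predicate.
- No thresholding of the SCCM before decomposition (weak TFs are kept
  deliberately); no MCL/affinity-propagation comparators; no plotting —
  the GraphML export is the hook for external network viewers.
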