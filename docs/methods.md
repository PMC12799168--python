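# Methods

This note records the models, defaults, and numerical choices behind
`trdp`, what the synthetic generator does and does not emulate, and the
limitations a user should keep in mind when reading a green test.

## Fold-change definition

All log fold changes are log2 of a ratio of group-mean library-size
normalized expression (pseudobulk), with a pseudocount applied at rate
`pseudocount / norm_scale` (defaults 1.0 and 1e4).  We deliberately do
not average per-cell logs: the mean-of-normalized-counts estimator is
robust to dropout and coincides with the bulk definition, so the
single-cell screen and bulk tissue branches produce commensurable
vectors.  No shrinkage or moderation is applied — the downstream
reversal statistic is a plain correlation of LFC vectors, and moderation
would reweight genes in a way the correlation is not defined for.
A gene is *detected* when it has nonzero counts in at least 5% of the
cells of either group (`detect_fraction`); bulk tables mask genes with
zero mean in both groups.

Because expression is observed compositionally (each cell is normalized
to a fixed total), any perturbation that changes total transcriptional
output shifts every gene's measured LFC by a common constant.  Pearson
correlations are invariant to this shift; estimators of the *per-gene*
effect are not, and the synthetic-truth bookkeeping therefore records
effects on the measurement scale (nominal effect minus the total-content
shift).

## Reversal statistic and its test

R_rej is the Pearson correlation (Spearman available) between the aging
LFC vector and a perturbation LFC vector over the intersection of their
detected gene sets, requiring at least 20 genes.  The default gene
universe is all genes detected in both contrasts; a DE-restricted subset
can be passed explicitly and is tagged in the output so the two variants
are never silently mixed.

Significance is a one-sided permutation test toward negative
correlation: gene labels of the perturbation vector are permuted
(preserving both marginal distributions), and
p = (1 + #{r_perm ≤ r_obs}) / (1 + n_perm).  This is the simplest
exchangeable null for a correlation; it assumes genes are approximately
exchangeable under the null, which heteroscedasticity across genes can
violate.  In calibration runs on the generator (400 independent null
perturbations) the raw type-I error at α = 0.05 lands inside
[0.03, 0.07].  One practical caveat found during calibration: null
perturbations scored against a *shared* control group have correlated
LFC noise (the control's sampling error is common to every contrast),
so the empirical rejection rate across TFs of one screen is not an
estimate of the marginal type-I error; calibration must use independent
replicates.  Hits require R_rej ≤ −0.3 (inclusive) and a
Benjamini–Hochberg-adjusted p ≤ α within each screen mode.

## TF prioritization

The quantifiable half of candidate selection is a one-sided
hypergeometric tail test of each TF's target set against the signed DE
gene set, with BH adjustment reported and ranking by raw p (the
adjustment is monotone, so ranks are identical); ties break by larger
overlap, then TF name.  A signed bias (fraction up minus fraction down
among DE targets) descriptively separates activators from repressors.
Curation/literature input to candidate selection is out of scope; target
maps are inputs (any motif resource, or the synthetic network).

## Regulons and module scores

Regulon inference prunes an input TF→target map by Spearman correlation
with the TF across cells (|r| ≥ 0.1 by default, regulons under 10 genes
dropped; the sign of the mean retained correlation sets the
activating/repressive mode).  This is a deterministic, desk-scale
stand-in for ensemble-regression network inference; it preserves the
motif-evidence-plus-covariation spirit but will not reproduce
tree-ensemble regulons.

Per-cell activity is the area under the recovery curve of regulon genes
within the top `aucell_top_fraction` (default 0.05) of the cell's
gene ranking, normalized by the maximum attainable area; ties in
expression break by a fixed gene-order key so scores are deterministic.
The module score comparing two cell groups is the Welch z statistic of
the two activity samples.  A z scale makes the conventional
differential-module threshold (|score| > 5) interpretable and lets the
repartition null (pool the groups, re-split at original sizes) serve as
a direct calibration: its SD should be ≈ 1 and |score| > 5 essentially
never occurs under the null.

A caveat discovered in truth-recovery testing: because AUCell is
rank-based, a strong expression shift in one gene set displaces the
ranks of *unaffected* genes too, so with many cells per group even
untouched modules can drift to |z| of a few units between states.  The
|score| > 5 cut is therefore meaningful for contrasts of screen-typical
size, but module scores should not be read as per-module effect sizes
independent of the rest of the transcriptome.

Row clustering uses 1 − Pearson correlation between module-score rows,
average linkage, rows pre-sorted by label for deterministic tie-breaks;
constant rows are pushed to the maximum distance (2.0) with a warning.

## Cell-cycle phase assignment

Each marker set (S, G2M) is scored as the marker-mean minus the mean of
a size-matched random background drawn from the same mean-expression
decile as each marker (expression-matched controls remove the
detection-level bias a uniform background has); both marker sets are
excluded from all background pools; the raw difference is standardized
across cells.  A cell is G1 when both scores are ≤ 0, otherwise it takes
the phase of the larger score.  Limitation: the zero point of the
standardized scores depends on the population composition, so phase
fractions are most accurate within reasonably homogeneous populations;
scoring wildly different conditions pooled together biases the G1 rate.
Marker lists are an input (standard S/G2M lists, or the generator's
truth blocks).

## Synthetic generator

The generator is the package's stated world:

- **Aging axis**: log2 LFCs drawn N(0, `lfc_scale`) on an affected
  subset (default 1000 of 2000 genes, scale 1.0), exactly zero
  elsewhere — a sparse signature with known σ.
- **Perturbations**: true LFC = −ρ × aging LFC + N(0, `off_axis_sd`)
  noise confined to the affected genes.  Confining off-axis effects to
  the axis genes keeps the analytic reversal correlation
  −ρσ/√(ρ²σ² + τ²) valid for the genome-wide statistic (off-axis
  effects on never-affected genes would dilute it); the formula is
  verified against Monte Carlo in the tests.  ρ = 0 with zero noise is
  a null TF.
- **Counts**: negative binomial, mean μ and variance μ + μ²/dispersion,
  around per-cell expected values (relative abundances renormalized per
  cell times a lognormal library size; defaults 5000 counts, CV 0.3).
  The default NB size of 10 describes clean UMI-counting data and is
  the regime in which the stated marker-based phase classifier recovers
  known phase fractions; dispersion near 1–2 models substantially
  noisier protocols and can be set explicitly.
- **Cell cycle**: optional S and G2M marker blocks elevated 2^1.5-fold
  in cells of the matching phase, with per-condition (G1, S, G2M)
  fractions.  Marker genes draw their baselines from a moderate
  expression stratum (lognormal around 20 relative units) — marker
  lists are usable in practice precisely because their genes are well
  detected.  Old-state G1 arrest plus a composition-restoring null
  perturbation reproduces the confound that phase-restricted R_rej is
  designed to catch.
- **Shared universe**: a screen simulated with `shared_truth` from a
  two-state run reuses that run's realized baselines and axis, as the
  same biology underlies both experiments; without sharing, the two
  draws are independent worlds and cross-correlations are near zero by
  construction.
- **Network**: driver TFs target affected genes, null TFs target the
  remainder; a separate latent-activity generator produces TF/target
  covariation (with unregulated background genes, without which
  normalization would cancel a shared factor) for regulon-inference
  tests.

Not emulated: doublets, guide-efficiency heterogeneity, batch effects,
ambient RNA, and any real gene identity.  A green recovery test
establishes that the estimators invert this generative model at the
stated sizes — not that they are robust to artifacts the generator does
not contain.

## Defaults

| Parameter | Default | Meaning |
| --- | --- | --- |
| `pseudocount` | 1.0 | added before log2, at rate pseudocount/norm_scale |
| `norm_scale` | 1e4 | per-cell normalized total |
| `min_cells_per_group` | 10 | smallest group for any pseudobulk contrast |
| `permutations` | 1000 | gene-label permutations for the R_rej p-value |
| `aucell_top_fraction` | 0.05 | ranked-list fraction scanned by the recovery curve |
| `hit_threshold` | −0.3 | R_rej hit rule (inclusive) |
| `module_score_cut` | 5.0 | differential-module z threshold |
| `detect_fraction` | 0.05 | detection filter (fraction of cells with nonzero counts) |
| `alpha` | 0.05 | significance level after BH within mode |
| `min_abs_corr` | 0.1 | regulon pruning threshold |
| `regulon_min_size` | 10 | smallest retained regulon |

All stochastic stages derive independent child streams from
(root seed, operation name, replicate index), so stages can be run in
any order, or alone, without changing each other's results.

## Known limitations

- Gene identifiers are opaque strings matched exactly; no symbol
  aliasing or ortholog mapping.
- The gene-label permutation null assumes exchangeability; strong
  per-gene variance structure correlated with the aging signature would
  make it optimistic.
- Regulon inference is correlation pruning, not causal network
  inference; regulons inherit any bias of the input target map.
- The phase classifier's G1-by-exclusion rule is composition-dependent
  (see above) and has no notion of cycle pseudotime.
- Pseudobulk LFC has a compositional offset whenever total
  transcriptional output changes; correlation-based statistics are
  immune, per-gene readouts are not.
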