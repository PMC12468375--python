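# Methods

## Scope and model of the data

The package treats drug repurposing for the MGUS → sMM → MM disease
spectrum as a rank-aggregation problem. Inputs are (a) gene-by-sample
log2-scale expression matrices with case/control labels, one per cohort and
stage; (b) ranked drug lists from several signature-reversal tools, one per
tool × cohort × stage, carrying inhibition scores where strongly negative
values mean the drug's perturbation signature opposes the disease
signature; (c) chemical structures or binary fingerprints; (d) factorial
dose-response matrices for drug pairs; and (e) gene-set collections (GMT).
Everything runs offline: the web services that produce (b) and the portals
that produce (d) are upstream of this package, and their outputs are input
formats here.

## Differential expression and signatures

Columns are quantile-normalised to the mean-of-order-statistics reference;
within-column ties receive the mean of the reference values they span,
which leaves already-identical columns untouched. A matrix whose maximum
exceeds 50 is assumed linear-scale and log2(x+1)-transformed first (logged
either way).

Per gene, the case-vs-control comparison uses a moderated t-statistic:
pooled variances are shrunk toward a scaled inverse-chi-square prior whose
parameters are estimated across genes by method of moments on log residual
variances (digamma/trigamma moment matching; the trigamma inverse is a
Newton iteration). The statistic divides log2FC by the shrunk standard
error; its null distribution is t with residual-plus-prior degrees of
freedom; p-values are Benjamini–Hochberg adjusted. When the observed
log-variance spread is no larger than the sampling noise the prior df is
infinite and the test degenerates to a z-test on the common variance;
`prior_df=0` recovers the ordinary two-sample t exactly and is used as a
limiting-case test. The estimator's type-I rate on null simulations is
0.050 (100 seeds, checked in the acceptance suite).

Probe-level tables collapse to gene symbols by keeping, per symbol, the
probe with the largest |log2FC|; ties break by smaller adjusted p, then by
lexicographic probe id (the data cannot decide these, so determinism does).
Signatures keep, among genes with adjusted p strictly below 0.05, the 150
most over- and 150 most under-expressed by log2FC; a side with fewer
qualifying genes takes them all with a warning. Filtering before ranking is
the default; a `rank_first` flag flips the order for sensitivity analyses.
The up list requires log2FC > 0 and the down list log2FC < 0, which keeps
the two sides disjoint in degenerate one-sided inputs.

## Consensus ranking

Both aggregation levels use `Score = 0.7·R + 0.3·A`. The normalised rank
value of rank *r* in a *K*-item source is `(K − r + 1)/K`: the best rank
maps to 1, the worst to `1/K`, so a better rank can never lower a score and
all scores live in [0, 1] — the two requirements that pin the
normalisation. `R` averages these values over the sources that contain the
item (treating absence as rank `K+1`, i.e. value 0, is available as
`absent_policy="penalize"`); `A` is the appearance fraction. Tied source
scores receive average fractional ranks; final-score ties order
lexicographically; contributions are summed in sorted order so results are
bit-identical under any permutation of tools or datasets. Tool lists are
truncated to their top 50 entries before aggregation, matching the
shortest tool's output length, and drugs are matched across sources by
case-folded, whitespace-stripped name. Cross-dataset scores of 0.75 or
higher (inclusive) form the stage shortlist.

Pathway consensus is the same machinery with pathways as items: within
each dataset, terms are ranked by adjusted p ascending with average ranks
on ties, then aggregated across datasets.

An independent oracle — plain nested loops, its own fractional-rank
computation, no shared code or vectorisation — reproduces every R, A and
score to 1e-12 over all configurations up to 6 items × 3 tools × 3
datasets (acceptance suite).

## Over-representation analysis

ORA uses the upper-tail hypergeometric probability of at least the
observed overlap between a query and each gene set, restricted to a
background universe; BH adjustment runs across tested terms, and terms
with zero overlap are excluded before testing. The universe defaults to
the genes measured on the platform rather than the whole genome — the
conservative standard, and overridable. The tail equals one-sided Fisher's
exact on the corresponding 2×2 table to 1e-12 (tested). Drug-target ORA
pools the target genes of all shortlisted drugs (file-based drug→target
map; unmapped drugs are counted and reported) and applies the same test
with a strict adjusted-p < 0.05 filter.

## Structural similarity

Fingerprints are fixed-length bit-vectors; from structures they are RDKit
hashed topological path fingerprints (2048 bits by default, configurable),
after SMILES canonicalisation and largest-fragment salt stripping.
Similarity is bit-set Tanimoto; the clustering distance is Soergel, which
for binary vectors equals 1 − Tanimoto. Thresholds quoted on one scale are
translated with the `s = 1/(1 + d)` convention, under which the 0.15
Soergel cut corresponds to ~87% Tanimoto; note this conversion and the
binary-vector identity are two different conventions, and the package
states which it is using where (the conversion translates thresholds, the
identity builds the distance matrix). Cross-set screening flags pairs at
Tanimoto ≥ 0.80 and can reduce to each query drug's best reference match.
Clustering is agglomerative with complete linkage — a cut at 0.15 then
guarantees within-cluster maximum distance ≤ 0.15 — and the library is
canonically id-sorted before linkage so results are order-invariant;
cluster labels are contiguous from 1; singletons are expected for
structurally diverse shortlists.

## Synergy models

Responses are % inhibition on [0, 100] (values outside [−10, 110] are
clipped with a warning; viability data should be converted as
100 − viability upstream). All four scores are the unweighted mean of
observed minus expected over the positive-dose cells:

- **HSA**: expected = max of the two monotherapy margins at the component
  doses (taken from the measured margins).
- **Bliss**: expected = `y_a + y_b − y_a·y_b/100` on the measured margins.
- **Loewe**: the expected effect solves the isobole
  `x_a/D_a(y) + x_b/D_b(y) = 1`, where `D` inverts the four-parameter Hill
  fit of each margin; solved by bisection to 1e-9. Cells whose doses exceed
  what is needed for the joint maximal effect score against the asymptotic
  expectation (flagged). A sham combination — one drug split against
  itself — scores 0 by construction, which the tests verify to 1e-6.
- **ZIP**: Hill curves are fitted along each row and column of the
  positive-dose grid; the fitted surface (average of the two directional
  fits) is compared with the independence expectation evaluated on the
  fitted monotherapy margins. Fitting rows on positive doses only with all
  four parameters free makes the construction exact for independence-built
  surfaces (an affine transform of a Hill curve is again a Hill curve), so
  the null scores ~0 and a planted constant delta is recovered exactly.
  Grids with fewer than 4 positive doses per axis fall back to the
  raw-margin Bliss-style delta with a logged "degraded" flag.

Hill fits are multi-start least squares (slope starts 0.5/1/2/4, tight
tolerances); degenerate flat data yields an unconverged flat fit backed by
monotone interpolation. Classification is strict: a score must exceed +5
for moderate and +10 for strong synergy, so +5 and +10 themselves do not
qualify. Per-model top lists take pairs above +5 sorted descending; the
intersection requires synergy under all four models.

A property worth knowing: which model is "most conservative" depends on
the margins' shape. With sub-maximal efficacy and shallow Hill slopes the
independence expectation is inflated relative to dose equivalence, so
Loewe can score *above* Bliss on an independence-built surface; for steep
slopes (≳2) the ordering reverses and Loewe is the most conservative, the
regime in which the planted suite tests that ordering.

## Synthetic data and what it does not emulate

All generators are pure functions of (parameters, seed), draw from
per-component sub-streams of one master seed, and emit a `.truth.json`
sidecar sufficient to score recovery. Defaults are the conditions used
throughout the tests: expression — baseline 8.0 on the log2-like scale,
noise SD 0.5, effect |log2FC| = 2 on 100 up + 100 down of 1000 genes,
20 cases vs 20 controls; tool outputs — 3 tools × 4 datasets, top-50
lists over a 200-drug universe with 20 planted reversers at rank advantage
0.9 (decoys draw latent U(0,1), planted drugs Beta(1/p − 1, 1), which
beats an independent uniform with probability exactly p; inhibition scores
are laid out on [−100, 0) since only order matters downstream);
fingerprints — 3 clusters of bit density 0.25 with the per-bit flip rate
solved so the expected within-cluster Tanimoto hits the target (targets at
or below the random baseline d/(2−d) are rejected as infeasible, not
clipped); dose-response — margins from stated Hill curves, combination
cells equal to the chosen model's null expectation plus a planted delta
plus Gaussian noise (SD 2 by default) on an 8×8 dose grid.

The generators do **not** emulate probe-level artifacts, batch effects,
cross-platform differences, tool-specific score distributions, realistic
chemical scaffolds, or dose-response heteroscedasticity. Passing the
planted-recovery suite therefore demonstrates that the computations are
correct and well-calibrated under their stated models, not that the
pipeline's biological conclusions on real cohorts are right.

## Numerical and design choices

- BH adjustment and the hypergeometric tail each live in one shared
  function used by every module.
- Quantile normalisation interpolates fractional (average) ranks on the
  sorted-column-mean reference.
- Residual variances below 1e-12 are floored before the log in the prior
  fit; a fully zero-variance matrix is rejected as degenerate.
- All orderings that the data cannot decide break deterministically
  (lexicographic ids after the relevant score).
- Problem sizes in the test and acceptance suites (1000-gene cohorts, 100
  simulation seeds, 8×8 dose grids, 30-drug fingerprint libraries) were
  chosen as the smallest sizes at which the Monte-Carlo checks are stable;
  they are the package's own validation conditions.

## Known limitations

- The moderated t follows the standard empirical-Bayes scheme but is not a
  line-for-line limma port; heteroscedastic designs, covariates and trend
  fitting are out of scope.
- Drug identity across tools is name-based (case-folded) with an optional
  synonym map; no structure-based identity resolution is attempted.
- Heatmap-level similarity values depend on the fingerprint family chosen;
  only threshold-level statements (80%/87%) are fingerprint-robust.
- Loewe/ZIP scores inherit Hill-fit uncertainty; on noisy or
  non-monotone surfaces their tolerances are necessarily looser (1e-3 on
  nulls) than the closed-form Bliss/HSA (1e-6).
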