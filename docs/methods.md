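# Methods

## The design

`twindmr` analyzes DNA methylation in disease-discordant monozygotic twin
pairs. Because co-twins share genotype, birth cohort, age, sex and much of
their early environment, the within-pair difference in methylation
cancels those factors; what remains is disease- and exposure-linked
variation plus noise. The pipeline takes a normalized beta-value matrix
(CpGs × samples, values in [0,1]), a probe manifest (chromosome, 1-based
position), and a pair design sheet (case/control sample per pair, binary
exposures, age, sex), and produces per-CpG statistics (DMPs) and
region-level candidates (DMRs) with permutation inference.

## Quality control

Beta values follow the Illumina convention β = M/(M+U+100). Measurements
with a detection p-value strictly above 0.01 are set missing, and probes
with strictly more than 5% missing entries are dropped; both comparisons
are strict by design. Before any ratio computation, betas are clipped into
[1e-6, 1−1e-6] to protect fold changes against division by zero. Detection
p-values are consumed as given, never recomputed from control probes.

## Cell-type adjustment

Whole blood is a mixture of leukocyte populations whose composition can
differ between co-twins and masquerade as differential methylation. Given a
reference panel of mean beta profiles per cell type at discriminating
probes, each sample's proportions are estimated by least squares
constrained to the probability simplex (non-negative weights summing to
one), solved as a penalty-augmented non-negative least-squares problem
followed by exact normalization. This is the standard reference-based
reading of the deconvolution step; no published reference panel ships with
the package — the bundled generator produces synthetic panels and real
panels are user-supplied.

Composition is then removed by residualization: each CpG is regressed on
the estimated proportions (intercept included, one proportion column
dropped to break the sum-to-one collinearity) and replaced by residual +
grand mean, clipped back to [0,1]. The operation is idempotent. An
alternative mode (`celltype_mode: covariate`) instead appends the per-pair
proportion differences to the regression model; residualization is the
default because it matches the notion of a single "cell-type adjusted
dataset" feeding all downstream stages. A caveat worth knowing:
residualization removes *any* variation explained by estimated
proportions, so if composition itself shifts with disease, part of a true
disease methylation signal at composition-correlated probes is absorbed.
That trade-off is inherent to composition adjustment, not specific to this
implementation.

## Per-CpG pair model

For probe *j* and pair *i*, the response is δ_ij = β(case) − β(control).
Ordinary least squares fits

    δ_ij = α_j + Σ_k b_jk x_ik + ε_ij

with pair-level covariates x: the exposures (ever-smoking, anti-CCP
positivity, current DMARD treatment) as raw 0/1 indicators, and the
matching covariates (age, sex) mean-centered. Under this coding the
intercept α is the disease effect in unexposed pairs of average age and
sex — α > 0 means hypermethylation in the affected twin — and each
exposure slope is the additional exposure-linked difference. The coding
matters: if exposures were centered, α would equal the grand-mean δ and an
exposure-confined effect would bleed into the disease surface; with raw
coding, exposure-driven signal loads on its own slope surface. The price
is variance — the intercept extrapolates to the all-unexposed cell, which
at this cohort's prevalences (69/61/68%) is sparsely populated, inflating
its standard error (any unbiased exposure-adjusted estimator pays at least
this price, by Gauss–Markov). Consequences for regional inference are
discussed below.

Per missingness pattern the model is fit in one vectorized pass; pairs
with a missing beta are dropped at that probe, pairs with missing smoking
status are excluded from any fit that includes smoking (no imputation),
probes with fewer than `min_pairs = 10` complete pairs are skipped, and
rank-deficient covariate columns (e.g. all usable pairs treated) are
dropped with a log message. Two-sided t tests (residual df = n − p) give
p-values; Benjamini–Hochberg FDR < 0.05 defines significant DMPs and
uncorrected p < 5×10⁻⁵ suggestive ones. Fold change is reported separately
as mean(case)/mean(control) per probe (values below one = relative
hypomethylation), keeping the test on the difference scale where the null
is 0. A `response="logratio"` switch fits log(case/control) instead;
the difference scale is the default.

## Regional analysis (bump hunting)

Probes are grouped into clusters: maximal runs with inter-probe gaps
≤ `maxgap` (default 500 bp). The chosen coefficient surface (α or one
exposure slope) is smoothed within clusters — local linear fits with
tricube weights over ±1000 bp for clusters of ≥ 7 probes, a window-3
running mean for smaller clusters, passthrough for 1–2 probes. The
smoother is a fixed linear operator (it depends only on positions), which
makes it exact on linear trends and lets permuted surfaces be smoothed by
a single sparse matrix product.

Thresholds are ±(99th percentile of |smoothed values|) genome-wide
(symmetric by default; a signed 1st/99th-percentile variant is available).
Maximal same-sign runs beyond a threshold become candidate regions; each
is scored by its area (sum of |smoothed| over its probes) and ranked by
area, ties broken by genomic position.

Significance comes from permuting case–control status: each pair's labels
are swapped independently with probability 1/2, equivalent to flipping the
sign of its δ while covariates stay attached to the pair. Because every
OLS coefficient is a linear functional of δ, a permuted surface is a
matrix product with precomputed projection weights — identical algebra to
refitting each probe, verified exactly in the tests. The full
fit → smooth → detect chain is re-run per permutation with thresholds held
fixed at the observed ones (recomputing them per permutation is not done;
fixing them keeps the observed and null area statistics on the same
scale). With 3 pairs the 2³ sign assignments can be enumerated
exhaustively, which the test suite exploits as an exact oracle. From
`n_perm` permutations (default 1000; the desk-scale analyses use 200):

* `fwer_p` — fraction of per-permutation **maximum** areas strictly larger
  than the observed area;
* `suggestive` — observed area exceeds the smallest per-permutation
  maximum;
* `emp_p` — fraction of **all** null areas strictly larger (uncorrected);
* `fdr` — expected null count at or above the observed area divided by the
  observed count at or above it, monotonized by reverse cumulative
  minimum, capped at 1 (BH on `emp_p` is available as an alternative).

Tail counts use strict ">" throughout; a zero count is flagged as a
boundary (`< 1/n_perm`) rather than corrected. All four surfaces (α,
smoking, anti-CCP, DMARD) are processed by the same machinery; a surface
whose covariate is constant across usable pairs is skipped with a warning.

### Permutation "ghosts" at desk scale

A region that itself carries signal contributes to the permutation null:
under sign flips its probes produce coefficient values of magnitude up to
(effect × Σ|w_i|), where w is the coefficient's projection weight vector.
For the plain paired mean, ‖w‖ is 1/√n and the ghosts are negligible; for
the exposure-adjusted intercept or an unbalanced exposure's slope, ‖w‖ can
approach 1 and ghost bumps occasionally rival the observed area, making
FWER conservative precisely at strong signal regions. On a 450K-scale
genome the null maximum is dominated by genuine noise maxima instead, so
the effect is a property of scaled-down genomes and small cohorts. For
power analyses of fixtures that contain no exposure-linked structure, the
matching analysis is therefore the pure paired contrast (no covariates);
the full model is used whenever exposure surfaces are of interest.

## Annotation and enrichment support

Detected regions are exported as BED (0-based half-open; all internal
coordinates are 1-based inclusive) for an external regulatory-domain
enrichment service. Regions are annotated with all overlapping genes, else
the nearest gene within 100 kb (configurable), else "no nearby gene".
Because arrays carry 1 to >1000 probes per gene, pathway-level results are
checked for probe-count bias: Spearman correlation between
−log10(pathway significance) and the mean probes-per-gene of pathway
members, with a two-sided p-value from 10,000 pathway-label shuffles. The
enrichment test itself is out of scope; a post-filter utility (fold
enrichment ≥ 2 by either test, FDR < 0.05 by both) is provided for
external output tables.

## Synthetic data

The generator emulates the study conditions: 28 discordant pairs; exposure
prevalences 0.69 (smoking, 14% missing), 0.61 (anti-CCP), 0.68 (DMARD);
ages N(56, 10) truncated to [30, 80] (onset around 38 plus a median
18-year discordance duration); 78% female, sex shared within pair. The
default genome is one chromosome with 500 clusters of 6–14 probes
(≈5,000 probes), within-cluster gaps of 30–400 bp and between-cluster
gaps of 2–10 kb, so the analysis cluster structure is recoverable at
`maxgap = 500`.

Each probe gets a bimodal baseline (Beta(5,45) or Beta(45,5), i.e. modes
near 0.1 and 0.9), a shared pair-level deviation (sd `pair_sd = 0.10`) and
independent twin-level noise (sd `noise_sd = 0.05`), giving within-pair
correlation above between-pair correlation. Spiked regions are placed in
randomly chosen free clusters and drawn with intermediate baselines
(Beta(10,10)) — real reported twin DMRs sit at intermediate methylation,
and at the bimodal extremes [0,1] clipping would silently compress the
injected effect. Disease spikes add the effect to every affected twin;
exposure spikes only to affected twins of exposed pairs, which is what
makes exposure-linked regions detectable on their slope surface but not on
α. Two spikes may be co-located to model a region driven in opposite
directions by two exposures. Optional cell-type structure replaces a panel
of probes with reference-profile mixtures under Dirichlet weights (with an
optional case-ward shift), and detection failures are injected at a
configurable rate (default 0.002 in the analysis scripts).

What the generator does **not** emulate: probe-type chemistry differences,
batch/chip effects (the study design neutralized these by co-hybridizing
co-twins), genuine biological covariance between exposures and baseline
methylation, and realistic linkage of composition to disease beyond the
optional shift. Passing tests therefore demonstrate correctness and
calibration of the statistical machinery under the assumed model, not
robustness to every artifact of real arrays.

## Numerical choices and problem sizes

Quantiles use linear interpolation. Clipping bounds are 1e-6 (ratios) and
exact [0,1] (beta values). The simplex solver's sum constraint is enforced
by a 1e4-weighted penalty row plus exact renormalization (weights sum to 1
within 1e-8). Degenerate loess windows fall back to weighted means;
all-identical smoothed surfaces trigger a degenerate-threshold warning.
Permutation sign matrices come from a seeded `numpy` Generator; every
pipeline stage is a pure function of (inputs, config, seed), and each
output table records a hash of the analysis-relevant configuration.

The bundled analyses and tests run at the scaled-down genome
(≈5,000 probes) with 200 permutations, chosen so a full four-surface run
completes in seconds; calibration checks use 100 null datasets and the
null-uniformity check uses ≈50,000 probes. The statistical machinery is
identical at larger sizes; only runtime changes.

## Known limitations

* FWER at desk scale is conservative for strong-signal regions (ghosts,
  above); empirical p and rank are more informative there.
* The disease intercept's variance grows with exposure imbalance; with 28
  pairs and ~70% prevalences, exposure-adjusted disease effects are noisy.
* Residualization-based composition adjustment absorbs disease signal at
  composition-correlated probes when composition shifts with disease.
* Boundary clipping of beta values mildly distorts per-probe t statistics
  at extreme-methylation probes; the distortion is sign-symmetric and was
  not detectable in null-calibration checks at the 50,000-probe scale.
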