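# Methods

This note documents the statistical models, the defaults and the design
choices behind `glycoforms`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Identification filtering and the glycopeptide unit

The pipeline consumes glyco-PSM tables as produced by open-search engines;
it performs no spectral search or FDR estimation of its own. PSMs are kept
at glycan q ≤ 0.05 (configurable `q_max`). For O-glycan data, peptides
containing the N-sequon N-X-S/T are removed to prevent N/O misassignment,
along with PSMs lacking a target match. The sequon pattern is literal by
default (any X, including proline); an X ≠ P variant is available via
`sequon_exclude_proline` since the biological motif excludes proline but the
conservative removal does not need to.

The quantification unit is the **unique glycopeptide**: a unique peptide
sequence combined with a unique glycan composition. PSMs collapse by
taking the maximum MS1 intensity (peak-height proxy; `sum` available) and
element-wise sums of reporter vectors (ion counts are additive; `mean`
available). Site positions are trusted from the search export — HCD
fragmentation cannot localize O-sites, so no re-localization is attempted.

**Channel leak.** TMT reporter spillover produces spurious low signals. Per
feature, channels strictly below 1/16 of the maximum channel are set to
missing (a channel exactly at the boundary is kept). Masking individual
channels, rather than removing whole features, was chosen because the
spillover affects signals, not identifications; whole-feature removal is a
flag (`drop_feature`).

## Glycan classification and database rules

Classification is hierarchical and total: the first matching rule wins, so
for example a glycan carrying both NeuAc and Fuc is *sialylated*, not
*fucosylated*. High mannose and paucimannose require exactly the HexNAc(2)
core plus 4–12 / 1–3 hexoses and nothing else; "small" requires fewer than
three HexNAc and no other residues. The N and O hierarchies are verified
exhaustively over all compositions with residue counts 0–6 (~823k
compositions): each receives exactly one class per mode and phosphoglycans
always take precedence.

The database plausibility filter applies three inequalities:
HexNAc ≤ 2·Hex + 1; NeuAc+NeuGc ≤ Hex/2 + 1 **and** Fuc ≤ Hex/2 + 1
(read as two independent constraints, the more natural distribution of the
"or"); NeuAc+NeuGc+Fuc ≤ 5. Hex/2 is real division, not integer division —
the more permissive reading, since nothing indicates a floor. The filter is
idempotent and flags each rule separately.

Residue monoisotopic masses are the standard values (Hex 162.05282,
HexNAc 203.07937, Fuc 146.05791, NeuAc 291.09542, NeuGc 307.09033,
Phospho 79.96633, Sulfo 79.95682 Da); masses feed only descriptive
distribution summaries, so any standard table is adequate.

## Normalization and protein-abundance correction

Three per-sample calibrations are provided. `median` equalizes per-sample
medians (scale on raw data, shift on log data). `quantile` forces identical
value distributions. `vsn_like` is a variance-stabilizing-style contract:
arsinh of the raw intensities scaled by 1/ln 2 — so differences on the
output read as log2 fold changes for all but near-zero intensities —
followed by a per-sample affine calibration matching medians and median
absolute deviations across samples. Any method satisfying this contract
(monotone per sample, calibrated log-like output) is interchangeable here;
the method used is logged per run. Note that *any* distribution-matching
normalization assumes most features are unchanged — when a large fraction
of the proteome genuinely shifts, part of the biological signal is absorbed
into the calibration. This is a property of the approach, not of this
implementation.

Two protein-abundance corrections mirror two use cases:

- **Regression** (perturbation time courses): per glycopeptide, OLS of its
  log-intensity on the matched protein's log-intensity across samples;
  output is residuals plus the glycopeptide's mean. Constant protein
  profiles fall back to slope 0; unmatched glycopeptides pass through
  flagged. Recovery fidelity grows with sample count (the independent
  glycoform signal acts as regression noise, so the slope error scales as
  1/√n).
- **Ratio** (tissue comparisons, raw scale):
  `corrected = ((g/p)/(median_g/median_p)) · median_g` per sample, with
  per-sample medians over glycopeptides that have a matched protein
  (a dataset-global variant is a flag). The construction cancels any global
  rescaling of the protein matrix exactly; protein zeros yield missing
  cells.

## Moderated differential abundance

Per feature, a linear model over the design (condition cell means, plus
additive replicate — and any declared covariate — effects) is fit by least
squares. Residual variances are shrunk toward a pooled prior: a scaled
inverse-chi-square prior fitted by method of moments on log residual
variances (matching the standard squeezed-variance construction; the prior
degrees of freedom come from inverting the trigamma function on the excess
spread of log variances). Moderated t statistics use the posterior
variances with residual+prior degrees of freedom; p-values are adjusted by
Benjamini–Hochberg per contrast. The implementation agrees with
Bioconductor limma on shared fixtures (log2 FC to machine precision,
moderated t within 2%, a tolerance reflecting the slightly different prior
moment estimator), and limma serves as an independent oracle in the test
suite rather than as the implementation.

Significance is a two-part rule: |log2 FC| > log2(1.5) **and** adjusted
p < 0.05. Tissue contrasts tighten the fold-change cutoff to log2(2).
Differential analysis is complete-case (features quantified in all
channels); descriptive stages retain missingness.

## Microheterogeneity statistics

Sites are binned by distinct glycoform count: low 1–2, medium 3–10, high
≥11 (the printed bin edges overlap at 11; ≥11 was chosen as the more
explicit endpoint so the bins partition). The low/high machine-learning
labels use a different rule: low = exactly one glycoform, high = strictly
above the dataset's 90th percentile of glycoform counts, threshold reported
per dataset.

Within-protein profile similarity uses binary presence vectors over the
union of all observed compositions (presence, not intensity: observation
counts are the only replicate-stable reading), compared by Kendall tau-b
for every within-protein site pair. The null redistributes the global
multiset of (site, composition) assignments across sites, preserving each
site's glycoform-slot count; because a multiset is permuted, a site can
receive duplicate compositions, which slightly *lowers* the null's distinct
counts and makes the comparison conservative. Observed and pooled-null tau
distributions are compared with a two-sided Wilcoxon rank-sum test by
default (the distributions are not naturally paired); a per-pair signed-rank
variant is available. The number of permutations is configurable
(default 20).

Fisher contingency enrichment reports two-sided exact p-values, BH
adjustment across categories (significance preset: adjusted p < 1e-3) and
log2 odds ratios with a 0.5 Haldane correction when any cell is zero.

## Tissue specificity

A site's glycosylation pattern per tissue is the vector of its
glycopeptides' replicate-averaged intensities, normalized to sum 1 within
the site and tissue. Replicates are averaged before correlating because the
comparison is between tissues, not channels. Only sites with more than five
quantified glycopeptides are scored (the stricter of the two printed
variants; "at least five" is a flag). Pearson correlations over all tissue
pairs are averaged (sites missing a pair use the available pairs and are
flagged); the specificity cutoff is the dataset mean of those means,
*always recomputed* — published cutoffs for this quantity vary with the
dataset, so a hard-coded value would be wrong anywhere else.

## Surface exposure and kinetics

Enzymatic treatment of intact cells (deglycosidase or broad protease) only
reaches surface-exposed glycoforms. A site is *affected* when at least two
of its glycoforms change significantly upon treatment; single-glycoform
hits are reported but not called, trading recall for confidence.
Cross-enzyme agreement is quantified two ways: Pearson correlation of
per-composition counts of significantly changing glycopeptides, and Pearson
correlation of shared glycopeptides' log2 fold changes restricted to sites
affected under both enzymes.

Neural gas is implemented from its update rule: prototypes initialize as k
distinct input vectors (seeded); at step t the presented input ranks all
prototypes by distance and each moves by ε(t)·exp(−rank/λ(t)) toward it,
with exponential schedules ε: 0.5 → 0.005 and λ: k/2 → 0.01 over
t_max = 100·n steps (the classical published defaults; the schedules reach
their endpoints exactly at t_max). Results are bit-reproducible under a
fixed seed. Kinetic clustering operates on raw log2 fold-change profiles of
features significant at ≥1 time point (no z-scoring — the magnitudes carry
meaning; standardization is a flag): k=4 on all regulated features, k=3 on
the fucosylated subset with a significant negative fold change at ≥1 time
point.

## Biophysics

Solubility ratios are log2(NP40/SDS) per feature and replicate; glycoform
vs protein differential solubility median-normalizes both ratio sets, then
applies a moderated one-sample test to the paired per-replicate differences
(glycoform − protein), with the usual two-part significance rule. Median
normalization removes any global offset between the two sets by
construction.

Thermal profiles on the nine-point 40.4–66.3 °C gradient are aligned across
TMT sets by an internal-reference factor from first-temperature protein
intensities shared by all sets (the across-set mean divided by the set's
own mean — the across-set reading of an ambiguous reference definition),
followed by joint quantile normalization; the normalized matrix is divided
by its global mean, fixing the overall scale so that downstream ΔAUC is
exactly invariant to per-set intensity scaling. ΔAUC anchors each
condition by subtracting its own mean of the first two temperatures from
all temperatures, then takes the plain sum of the anchored difference (no
trapezoid weighting — the quantity is defined as a difference of summed
intensities). ΔAUC here is descriptive; hypothesis testing of melting
differences (hierarchical Gaussian-process testing) is out of scope.

## The synthetic-data generator

The generator emulates the statistical structure each analysis assumes:

- **Glycoforms per site**: a two-component zero-truncated
  negative-binomial mixture (weight 0.6 on a ZT-geometric with mean
  parameter 0.8; 0.4 on a heavy ZTNB, size 0.7, mean parameter 38.4). A
  single ZTNB cannot simultaneously put ~half the mass on 1–2 glycoforms
  and have mean ≈17 (its P(1–2) caps near 0.34 at that mean), so the
  mixture — which is also the biologically natural reading of a
  low-processing and a high-processing site population — is the default.
  Defaults give truncated mean 17.4, P(1–2) ≈ 0.51.
- **Compositions** are rejection-sampled under the three database rules, so
  every generated glycan passes the filter by construction.
- **Intensities**: log-normal protein abundance (median 1e6, sd 0.6 decades)
  × sparse Dirichlet fractional abundances per site (α = 0.3, so most
  glycoforms have low fractional intensity) × log-normal noise (sd 0.1 on
  the log2 scale). Channel leak is injected as a low spillover value
  proportional to the feature's maximum channel.
- **Templates** plant known effects: two-group fold changes (default 10% of
  features at 4-fold); four kinetic prototype curves over four time points
  (plateau-early, plateau-late, transient, monotone-up) on 25% of features
  — a minority, because aggressive normalization legitimately assumes most
  features are unchanged; tissue-divergent sites (20%) whose relative
  profiles re-draw per tissue; class-dependent surface exposure
  (high-mannose 0.04 up to sialylated/fucosylated 0.25, ~15% of features
  overall, mirroring that enzymatic shaving affects a minority of the
  quantified glycoproteome); glycoform solubility shifts (+1.5 log2 on 10%,
  4 replicates, ratio noise 0.1); and sigmoidal melting curves with planted
  ΔTm on a protein subset.

Problem sizes in the tests (tens of proteins, hundreds to ~2,000
glycopeptides, 20 permutations, 10–20 seeds) were chosen so each check has
decisive power at desk scale.

**What the simulations do not show.** The generator draws independent
log-normal noise; real reporter data have correlated, intensity-dependent
noise, batch structure beyond a replicate shift, missing-not-at-random
patterns and co-isolation interference. Passing recovery tests demonstrates
that the estimators are correctly implemented and calibrated under their
assumed model — not that those assumptions hold for any particular
instrument run. Dataset-scale headline numbers from deep tissue atlases
(e.g. absolute glycopeptide counts) depend on real spectral data and are
out of scope here.

## Numerical and edge-case choices

- BH adjustment is the step-up with cumulative minimum, capped at 1;
  inputs outside [0,1] raise.
- Zero residual variance with zero effect yields t = 0 (not NaN); zero
  variance with non-zero effect yields ±inf.
- Quantile normalization requires complete values; the tissue and melt
  paths use it only after completeness filtering or on complete simulated
  frames.
- Ties in top-fraction selection break deterministically by feature id.
- Constant presence vectors are skipped in tau computations and counted.
- Sites with zero total intensity in a tissue skip that tissue pair; sites
  losing all pairs are dropped from scoring.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; reruns are byte-identical.

## Known limitations

- The pipeline trusts upstream site localization and glycan assignment.
- `vsn_like` is a stand-in contract for full variance-stabilizing
  normalization: it calibrates location/scale but does not fit the
  intensity-dependent variance model.
- The moderated model covers condition + additive covariates only; no
  spline time trends or random effects.
- O-glycan site-level analyses inherit the peptide-start convention forced
  by HCD's inability to localize O-sites.
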