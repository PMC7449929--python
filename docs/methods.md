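# Methods

This note documents the models, numerical choices and limitations behind
`glutme`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Enrichment scoring

The single-sample enrichment score of a gene set is a rank-based running-sum
statistic. Within one sample, genes are ordered by descending expression, with
ties broken by lexicographic gene id so the ordering (and hence the score) is
deterministic. At each position the weighted in-set cumulative fraction
(weights `(rank from bottom)^α`) is compared with the unweighted out-of-set
cumulative fraction, and the score is the sum of the differences over all
positions. Because it depends only on within-sample ranks, the score is
invariant under strictly monotone transforms of the expression values, so the
scale of the input matrix (log-normalized, TPM, counts) is immaterial.

* `α = 0.25` by default — the convention of the original single-sample GSEA;
  `α = 0` gives the unweighted Kolmogorov–Smirnov-like sum. Configurable.
* Scores are *not* normalized across samples by default (the raw running-sum
  statistic is reported); a min-max cohort normalization sits behind
  `normalize=True`.
* Signature genes absent from the matrix are dropped silently with a logged
  count; a signature with *zero* overlap is an error naming the signature, and
  a signature covering every gene is degenerate (no out-of-set comparison).

**ImmuneScore** is the plain sum of the scores of the ten immune cell-type
signatures (B cells, CD4+/CD8+ T cells, dendritic cells, eosinophils,
macrophages, monocytes, mast cells, neutrophils, NK cells) — additive by
construction and tested to 1e-9. The widely used compendium scorer this
emulates (xCell) performs spillover compensation over 64 signatures; that is
intentionally not reproduced: downstream logic needs only per-type scores and
their sum, so a generic ssGSEA over a configurable GMT collection is used. The
glycolysis signature is a named placeholder set — which curated glycolysis
set to load is the user's choice.

## Immune stratification

The ImmuneScore distribution of a mixed cohort is bimodal. The split threshold
comes from a Gaussian kernel density estimate computed directly as the mean of
Gaussian kernels on a regular 512-point grid spanning
`[min − 3·bw, max + 3·bw]`, with Silverman's rule-of-thumb bandwidth
`0.9 · min(sd, IQR/1.34) · n^(−1/5)` — grid size, cut and bandwidth chosen to
match R's `density` defaults (`bw.nrd0`), the convention of the original
analysis. A fixed bandwidth override is available.

The threshold is the grid point of minimum density between the two *highest*
local maxima (several interior minima: the lowest wins; ties: the smaller grid
value). A unimodal curve raises `NoValleyError` so the caller can fall back to
a fixed threshold; densities with more than two modes are handled by ignoring
all but the two highest — a documented restriction. A sample exactly at the
threshold is labeled immune-poor (strict `>` for rich); the convention is
arbitrary and documented. Thresholds are reported at grid resolution.

Correlations are Pearson product-moment with two-sided p from the t
distribution (n−2 df), raw (no multiple-testing correction, matching how such
panels are conventionally reported). Per-cluster correlations skip clusters
with fewer than 3 samples with a logged warning rather than failing the panel.

## PET quantification

World coordinates are mm with voxel `i` covering `[i·s, (i+1)·s)` (index =
`floor(mm/s)`); sphere membership is evaluated at voxel centers. Segmentation
uses an adaptive threshold between local background and lesion peak:
`T = B + f·(P − B)` with `P` the max SUV inside the tumor VOI and `B` the mean
SUV in a shell just outside it (width 2 voxels by default, configurable). The
specific published adaptive-threshold variant used in the original clinical
analysis is not publicly specified; this background-plus-fraction-of-peak form
is a declared stand-in reproducing the dependence on tumor and background
intensities with one tunable, default `f = 0.41` (a standard adaptive choice),
exposed everywhere. MTV is the segmented voxel count times voxel volume;
`TLRmax = SUVmax(tumor mask) / SUVmean(liver VOI)` is exactly invariant to
global rescaling of the volume (up to floating-point rounding of the common
factor). Lesions with MTV ≤ 5.0 cm³ are excluded (strictly greater survives)
because partial-volume effects underestimate their TLRmax. SUV values are
taken as given — no decay or body-weight correction.

On a noise-free 1-cm sphere at 1-mm voxels, the segmented volume differs from
the analytic 4.19 cm³ by less than a 1.5-voxel surface shell, and the error
shrinks monotonically at 2 → 1 → 0.5 mm voxels (voxelization error only).

## Single-cell gating

Normalization is `ln(1 + 10⁴ · count / cell_total)` (natural log, scale
10,000), exactly invariant to per-cell count rescaling; zero-total cells are a
hard error listing the offenders. A cell is positive for a transporter iff its
normalized expression strictly exceeds the cutoff; the same cutoff gates both
GLUT1 and GLUT3, giving four exhaustive, exclusive classes whose fractions sum
to 1 exactly. The original scatterplot's numeric cutoff is not printed
anywhere; the default 0.5 on the log-normalized scale is a package choice,
exposed as a flag and echoed in all outputs. Per-cell gene-set activity is the
set mean of normalized expression — rank-based running sums are unstable in
sparse per-cell profiles, so the set mean is the documented single-cell
analogue of the bulk score. Upstream steps of a standard droplet pipeline
(HVG selection, scaling with covariate regression, PCA, graph clustering,
t-SNE, marker finding) are intentionally not re-implemented; cell-type labels
come from the generator or the user.

## GLUT-ratio biomarker

`ratio` mode computes `(GLUT3 + ε)/(GLUT1 + ε)` on the log-normalized scale
with pseudocount `ε = 1e-6` (how zero GLUT1 should be handled is unstated in
the source analyses; the pseudocount is the package's choice, and whether to
divide log-normalized values or raw counts is likewise open — ratio of
log-normalized values is the default, both are supported via the input given).
`zdiff` mode computes `z(GLUT3) − z(GLUT1)` with z-scores within timepoint
(pre and on separately), for cohorts distributed only as z-scores; zdiff
ratios have mean 0 and variance ≤ 2 by construction. %change is
`100·(on − pre)/pre` relative to baseline; in zdiff mode a percent change is
undefined for signed values, so the absolute difference is the meaningful
change measure.

Responders are PR/CR; nonresponders are PD ∪ SD. Two-group comparisons use
Mann-Whitney U — exact two-sided p when the combined sample is ≤ 12 and
tie-free (verified against full enumeration for all combined n ≤ 10), normal
approximation with tie correction otherwise; three groups use Kruskal-Wallis.
Survival: Kaplan-Meier curves split at the cohort *mean* ratio (not median —
the convention followed deliberately) with the log-rank test, and a univariate
Cox proportional-hazards fit (lifelines; Breslow tie handling) reporting the
hazard ratio per unit covariate with Wald 95% CI. Monotone likelihood or
non-convergence raises a flagged error rather than returning a diverged
estimate.

## Synthetic cohorts — the stated world

The generators encode the *assumed* data structure, not any fitted model; no
effect sizes for the latent immune fraction are published, so the defaults are
tuning choices fixed once, not estimates.

**Bulk** (`BulkSimParams`): latent immune fraction `f_i` from the mixture
`0.7·Beta(2,8) + 0.3·Beta(8,3)` (a large immune-poor mode at mean 0.2, a
smaller immune-rich mode at mean 0.73, echoing the visible cohort imbalance).
Bulk GLUT1 raw level is `(1−f)·glut1_cancer_mean`, GLUT3 `f·glut3_immune_mean`
(50 and 40), immune signature genes scale with `f`, glycolysis genes with
`1−f`, filler genes flat; all expression carries multiplicative lognormal
noise (sd 0.25 on the log scale, preserving positivity) and is stored as
`log1p`. TLRmax is `c0 + c1·G1raw + c3·G3raw + N(0, 0.3)` floored at 0.01 —
uptake as the sum of the cancer-compartment GLUT1 and immune-compartment GLUT3
contributions, with additive Gaussian error as a simple PET noise model;
`(c0,c1,c3) = (0.5, 0.15, 0.15)` put TLRmax on the realistic 1–10 range. The
true cluster label is `f` above/below the analytic crossing point of the two
weighted component densities (Brent root-finding between the component means;
midpoint fallback if one component dominates everywhere).

**Response** (`ResponseSimParams`): baseline log-ratio `b ~ N(0, 0.8)`;
P(non-PD) = `logistic(0 + 0.8·z(b))`; non-PD splits PR/CR vs SD at 0.5. The
on-treatment log-ratio is `b − 0.6·(b − mean) + N(0, 0.15)` for SD and PR/CR
(regression toward the cohort mean: low-baseline tumors rise — the
pseudoprogression-like influx pattern) and `b + noise` for PD. PFS is
exponential with hazard `0.08·exp(−0.3·z(b))` per month, censored at 36
months. Defaults `n_patients = 200`; the waterfall and median properties are
stated (and tested) at n = 1000.

*Known limitation*: under this pullback-to-the-mean dynamic, the
on-treatment responder/nonresponder separation is **not** systematically
stronger than the pre-treatment separation (the compression shrinks the gap
about as often as the variance reduction sharpens it). Reproducing a
"more significant on treatment" ordering would require an influx term raising
responders' GLUT3 specifically, which this generator does not model. A green
response-biomarker test therefore establishes the median ordering and the
waterfall correlation structure, not the p-value ordering between timepoints.

**Single cell** (`ScSimParams`): 2000 cells over cancer/myeloid/T/endothelial/
fibroblast at 0.2/0.3/0.3/0.1/0.1; negative-binomial (Gamma-Poisson) counts
with dispersion 2 (variance `μ + μ²/2`; `math.inf` switches to the Poisson
limit) and lognormal library-size factors (sd 0.3). GLUT1 mean 5 in cancer
only; GLUT3 means 1.5/1.0/0.8 in myeloid/T/endothelial and 0 elsewhere —
partial dropout chosen as realistic, not calibrated to any printed fraction.
Each type has 10 own markers (mean 8 vs background 0.2), plus glycolysis
(high in cancer), OXPHOS (higher in myeloid) and housekeeping groups. What the
generator does **not** emulate: full-transcriptome scale, batch effects,
ambient RNA, doublets, spatial heterogeneity — so green tests establish that
the *pipeline logic* recovers the designed composition and sign structure, not
that it is robust to those artifacts.

Determinism: every generator consumes a single `numpy.random.default_rng(seed)`;
identical parameters give bit-identical outputs, which the suite asserts.

## Numerical conventions

* Ties in expression ranking: stable lexicographic gene-id order.
* Cluster boundary: score exactly at the threshold → immune-poor.
* MTV boundary: exactly 5.0 cm³ → excluded.
* Exact Mann-Whitney only for tie-free combined n ≤ 12; otherwise tie-corrected
  normal approximation.
* KDE valley ties: smaller grid value.
* Pseudocount 1e-6 in ratio mode; zero or negative GLUT1 + pseudocount is an
  error rather than a silent clamp.
* Floating-point "exact" invariances (TLRmax scaling, additivity) are asserted
  at 1e-12/1e-9.
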