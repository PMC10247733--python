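# Methods

## The study design being modeled

The package analyzes paired populations of near-haploid ("haploid") and
diploidized ("diploid") cells of the same lineage. The biological null is
that diploidization doubles every gene's output: diploid:haploid expression
should be 2:1 (log2 = 1) for every gene, in bulk and in single cells, and
DNA-content-proportional quantities (e.g. DNA-damage foci counts) should
follow the same 2:1 expectation. The analyses quantify where and when —
i.e. in which cell-cycle stage — that expectation fails.

## Synthetic data model

All inputs are generated by `haplocycle.synthetic`; nothing is downloaded.

**Cell-cycle geometry.** The cycle is the unit circle. Each of the five
phases (G1S, S, G2, G2M, MG1, in progression order) owns a fixed arc of
width 2π/5; a cell's phase is the phase whose arc contains its angle θ.
Both ploidy groups share the arcs, so gene programs peak at the same angles
in both; groups differ in *occupancy*: a cell's phase is drawn from the
group's dwell fractions and θ uniformly within that arc.

**Dwell fractions.** Flow-cytometry-style stage proportions for this system
are only reported graphically in the literature this design emulates, so
defaults are qualitative choices, fixed once: diploid
{G1S .30, S .25, G2 .15, G2M .15, MG1 .15} and haploid
{G1S .25, S .20, G2 .17, G2M .23, MG1 .15} — the haploid group spends more
of its cycle in G2/G2M and less in S. These are not measured values.

**Expression.** A cell at angle θ in group *g* has per-gene mean

    mu_cg = baseline_g' * program(θ) * dosage(g) * 2^deviation,

where `baseline` is lognormal across genes scaled so a haploid cell
averages `mean_depth` (default 5000) total UMIs; `program(θ)` is a raised
cosine bump ((1+cos(θ−peak))/2)^κ scaled to peak at `program_amplitude`
(default 3, κ = 8) for the 40-per-phase signature genes and 1 otherwise;
`dosage` is 1 for haploid and `dosage_factor` (default 2) for diploid; and
`deviation` (default none) is a stage-restricted log2 offset applied to a
planted gene set in diploid cells only, enabling recovery tests for the
stage-specific differential-dosage machinery. Counts are negative-binomial
(var = μ + αμ², α = `nb_dispersion`, default 0.5; α = 0 gives Poisson) and
then thinned by independent Bernoulli dropout (default rate 0.1).

Each `simulate_*` function draws from its own RNG stream derived from
(seed, function name), so the four generators are individually reproducible
and mutually independent.

**What the generator does not model:** ambient RNA, doublets, batch
effects, hashtag demultiplexing, gene-length or GC biases, transcriptional
bursting beyond NB dispersion, or any real gene identity (genes are
anonymous `g00001`-style symbols; the bundled Whitfield-derived five-phase
GMT is for real datasets). Tests passing on this generator demonstrate that
the *pipeline machinery* recovers planted structure under realistic count
noise — not that it would resolve the subtler structure of real tissue.

## Imputation

Dropout is smoothed by Markov-affinity graph diffusion: kNN graph
(k = 30) on cells in 20-component PCA space of log1p median-normalized
expression, Gaussian kernel with per-cell adaptive bandwidth (distance to
the ka = 10-th neighbor), symmetrization (A + Aᵀ)/2, row normalization, and
diffusion Mᵗ·X with t = 3 by default (t = 7 suits noisier patient-derived
data). Two numerical choices matter:

- The *diffusion operand* is the linear normalized matrix, not its log.
  Diffusing log-transformed values and exponentiating back amounts to a
  geometric mean, which under-estimates means more severely for the
  lower-count (haploid) group and biased group dosage ratios by ≈ +0.06
  log2 in testing; diffusing linear values keeps group means unbiased.
- Ratio analyses need absolute scale, so the smoothed normalized matrix is
  mapped back by inverting each cell's size factor (`layers["imputed"]`).
  Per-cell normalization would silently erase the 2:1 structure that is
  the central quantity here.

k, ka and the PCA depth are this package's choices (the published analyses
this emulates do not state them); they are exposed in `DiffusionParams`.

## Phase scoring

Signatures are filtered per dataset: (i) detection in ≥ 5% of cells by raw
UMIs; (ii) Pearson r ≥ 0.5 between the gene's imputed expression and the
mean imputed expression of the stage-(i) genes. The correlation filter runs
within each ploidy group with an either-group pass rule — the permissive
choice for mixed-ploidy datasets, where a gene can track the cycle in one
karyotype only. Scores are per-cell means of z-scored imputed expression
(z-scoring stops high-abundance genes from dominating and makes the
G2M–G1S plane comparable between groups; a raw-mean mode exists). The
assigned phase is the argmax score; exact ties are "unassigned" rather than
broken by phase order, so downstream proportions are not biased.

## Pseudo-time

The ellipse is fitted to (G1S, G2M) score pairs by the numerically stable
partitioned direct least-squares conic fit with the ellipse constraint,
after centering/scaling for conditioning, then converted to geometric
parameters (center, semi-axes a ≥ b, rotation in [0, π)). Cells project to
the parametric angle of their nearest ellipse point (coarse grid + bounded
1-D minimization). Rolling-circle smoothing averages expression over cells
within radius 0.5 — interpreted in z-scored score units, configurable — of
each of 360 uniform-angle anchors; windows use all cells, empty windows are
missing (not zero), and SEM (hence the 1.96 × SEM CI band) requires ≥ 2
cells. Orientation is fixed by majority vote of assigned phases along the
anchor grid (pseudo-time must advance G1S→S→G2→G2M→MG1) and the origin is
the anchor of maximal smoothed G1S score. One ellipse is fitted per ploidy
group by default (a joint fit is a caller choice); the grid density and
radius are parameters, not fitted.

## Dosage ratios and differential expression

Per stage, per gene: group means of *absolute-scale* imputed expression
(log2 diploid/haploid, finite only when both means are positive; zero-mean
genes are counted separately), a two-sided Wilcoxon rank-sum p-value, and
BH q-values computed within each stage's gene family. The rank-sum test
runs on the *depth-normalized* smoothed layer: on absolute-scale values the
global 2:1 shift alone makes every gene "significant", so the test is asked
the interesting question — deviation beyond the global dosage factor —
while the reported ratio keeps the absolute structure. Caveat: p-values on
diffusion-smoothed values are anticonservative whenever the two groups are
not exchangeable (cells share information with their neighbors); under an
exchangeable null they measured conservative in testing (type-I ≈ 0.02 at
nominal 0.05), and a raw-normalized test layer is available via
`test_layer="norm"`. The census counts genes per stage with log2 ratio
below 0.5 (≈ 1.4-fold linear) and emits per-stage ECDF tables for plotting.

Small-sample rank-sum tests use the exact null (scipy) when untied with
n ≤ 25 per group, full midrank enumeration when tied and the split count is
tractable (total n ≤ 12), and the tie-corrected normal approximation
otherwise; enumeration beyond that is combinatorially infeasible.

Bulk tables are normalized per sample by the mean of the five spike-in
(ERCC) rows with the highest mean count across all samples, giving an
absolute scale that survives depth differences.

## Screens

Guide log2 fold change = log2 of depth-normalized, pseudocounted (+1)
endpoint/input abundance. The gene score is the median guide log2FC; a gene
is essential when its score and at least 2 of its guides fall at or below a
threshold set from the non-targeting control distribution (5th percentile
by default). This deterministic rule replaces rank-aggregation scoring of
the original screen analyses with something exactly testable; it is not a
reimplementation of that software. The ploidy-specific hit set is pure set
algebra — essential in every haploid screen, in no diploid screen, not a
panel common essential, stage-overexpressed — with a provenance table
recording which criterion removed each candidate.

## Foci

Cells are binned low/medium/high by within-group DAPI-intensity quantiles
(0.3/0.7 by default; mapping low→G1/S, medium→S, high→G2/M), a
deterministic stand-in for mixture-model peak calling. "Occupancy" of a
focus is defined by centroid distance ≤ `match_radius` (default 0.5 image
units) rather than pixel-mask overlap, since segmentation is out of scope;
both directional occupancy fractions (γ-H2AX by RAD51, RAD51 by γ-H2AX) are
averaged over cells that have at least one focus of the relevant channel.
Group foci-count ratios are computed per replicate and tested against the
dosage expectation with a two-sided one-sample Student's t-test (undefined
and reported as such at zero replicate variance); between-group
comparisons use two-sample equal-variance t-tests.

## Kinetics

Doubling time is 1/slope of a least-squares fit of log2(count) vs time.
Stage durations default to proportional allocation
(duration = proportion × doubling time), the model consistent with simple
stage-interval arithmetic; an exponential-age-structure mode (inverting the
steady-state age density 2(2^−x1 − 2^−x2), which corrects for the young-cell
excess of asynchronous cultures) is provided but never applied silently.
Competition fitness is the slope of log2 of the baseline-normalized
marked:unmarked ratio, converted to per-doubling units.

## Problem sizes and tolerances

Default study conditions are 2000 cells per group × 2000 genes (the
acceptance script's setting); unit tests run reduced instances (hundreds of
cells/genes) chosen so every statistical check retains comfortable margins.
Exact-oracle comparisons (rolling windows, matrix powers, BH step-up,
hypergeometric enumeration, all-pairs co-localization, rank-sum
enumeration) use tolerances of 1e-10–1e-12; parameter-recovery checks use
the uncertainty implied by their noise models (e.g. ellipse parameters to
1e-6 noiseless, 0.05 under σ = 0.05 noise; binomial SEs for proportions).

## Known limitations

- The phase-signature GMT shipped for real data is a curated
  Whitfield-derived list, not the dataset-specific list any particular
  study used; on synthetic data the generator's own memberships are used.
- The rolling-circle radius is scale-dependent; it is calibrated to
  z-scored score planes and should be revisited in raw-mean scoring mode.
- DE on smoothed data (see above) trades calibrated p-values under
  non-exchangeable nulls for power; treat q-values as rankings when groups
  differ globally.
- The essentiality rule's control-quantile threshold is a design choice;
  at very low control counts the 5th percentile is noisy.
- Foci co-localization by centroid distance ignores focus size and
  intensity.
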