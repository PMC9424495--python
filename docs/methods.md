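# Methods

`thkinetics` implements a kinetic transcriptomics workflow for dense
multi-condition time courses of CD4+ T helper (Th) cell differentiation:
detection of kinetic genes, classification of their temporal patterns,
two-step differential kinetics with a correlation-index filter, and a
per-gene linear decomposition of a hybrid lineage's transcriptome into the
contributions of the two canonical lineages. Every statistical claim the
package makes is exercised against a synthetic-data generator with exact
ground truth; this note records the models, the defaults and why, the
numerical conventions, and what the synthetic benchmarks do and do not
establish about real data.

## Data model

The unit of analysis is a genes x samples matrix of log2 intensities with a
sample design mapping each sample to a condition (Th0 neutral, Th1, Th2,
and the T-bet/GATA-3 double-positive hybrid "Th12"), a measurement time in
hours, and a replicate label. Downstream statistics require a complete
matrix; missing values are only tolerated before normalisation.

Preprocessing follows the standard microarray path: quantile normalisation
(every column mapped rank-wise onto the mean order statistics; ties take
the mean of tied ranks), log2 transform, and an expressed-gene filter that
keeps a gene when its mean over at least one condition's samples exceeds
the global median of the whole matrix. On an all-identical matrix the
strict inequality retains nothing — degenerate but intended. With heavily
tied data the "identical column sums" property of quantile normalisation
holds only approximately (tie groups of odd size interpolate rather than
redistribute); for continuous intensity data it is exact.

Probe-level matrices are collapsed to genes either by `max_mean` (the
probe with the highest overall mean represents the gene; the common
deterministic microarray convention, and the default) or by per-gene
averaging.

## Synthetic data generator

The generator emulates the experimental design the analysis assumes: four
polarizing conditions x ten timepoints x two independent replicate
experiments, on the log2 scale. Defaults:

* time grid {0, 3, 6, 12, 24, 36, 48, 72, 96, 120} h — ten points spanning
  five days with 3-h spacing over the earliest interval, where the fastest
  transcriptional responses occur;
* noise: homoscedastic Gaussian with sigma = 0.25 log2 units per sample —
  typical replicate scatter for well-normalised arrays; a config knob for
  power studies;
* per-gene baselines N(7, 0.75^2) log2 units, shared across conditions —
  so the expression-filter and PCA operate on realistically dispersed
  levels;
* temporal archetypes: C1 fast transient up, a gamma pulse
  A (t/tau) exp(1 - t/tau) peaking at tau (default range 4-12 h); C2
  delayed stable up, a logistic ramp anchored to 0 at t = 0 (midpoint
  12-48 h); C3 stable down, the negated ramp; amplitudes 1.5-3.5 log2
  units (strong responders, the population the workflow targets).

Hybrid-program genes receive two *dissimilar* lineage curves (distinct
archetypes with signed Pearson r < 0.5; r > -0.95 to keep the two programs
separately identifiable — anticorrelated trends are maximally dissimilar
and are deliberately retained, since up-in-Th1/down-in-Th2 genes are a
major class in reality). The hybrid condition then follows one of four
generating programs: an exact Th1 copy, an exact Th2 copy, a convex
superposition w·Th1 + (1-w)·Th2, or an *independent* curve. Independent
curves are smooth random trajectories (natural cubic spline through
Gaussian control values at five knots, anchored at zero for t = 0, scaled
to a realistic amplitude), rejection-sampled until |Pearson r| to both the
Th1 and Th2 mean curves is below 0.3 (retry cap 1,000). Single-archetype
candidates cannot satisfy that bound: on a ten-point grid the three smooth
archetypes span only ~2-3 effective dimensions, so any archetype-shaped
candidate correlates strongly with one of the two lineage curves.

What the generator does **not** emulate: probe-level structure,
intensity-dependent (heteroscedastic) noise, gene-gene correlation beyond
the shared archetypes, batch or array effects, and count-type noise of
sequencing data. Recovery results on this generator therefore demonstrate
the *statistical identifiability* of each analysis under the stated noise
model, not performance on any particular real dataset.

## Kinetic genes

Per condition, each gene's log2 profile is regressed on a polynomial in
time (default cubic — ten timepoints comfortably support rise, peak and
plateau; degree is a parameter) with all replicate samples entering as
independent observations. The F-test against the intercept-only model has
exact (d, n-d-1) degrees of freedom; p-values are Benjamini-Hochberg
corrected *within the condition* and called at q < 0.05. Independently, the
fold-change rescue rule flags genes with |log2 FC vs t=0| >= 1 at two or
more consecutive timepoints; the rule is two-sided by default so that
stably downregulated genes remain eligible (a strict one-sided variant is
available). A gene is kinetic in a condition if either criterion fires.

FDR is controlled per condition on the call table. The *union* set (kinetic
in >= 1 of four conditions) is the analysis gene set for the differential
step, not an FDR-controlled discovery set — unioning four families
accumulates each family's false positives (observed union FDR ~0.12 on the
standard benchmark versus ~0.03 on the per-call table).

### Temporal pattern clustering

Kinetic genes of one condition are clustered on their replicate-mean
profiles under the correlation distance 1 - r (shift- and scale-invariant)
with agglomerative complete linkage, cut at exactly k clusters (default
k = 3). Genes with constant profiles (undefined correlation) are held out
and attached to the nearest centroid by Euclidean distance. Centroids are
labelled from two shape features — net change (final - initial) and peak
prominence (max above both endpoints): negative net change -> C3, dominant
prominence -> C1, otherwise C2; with k = 3, duplicate labels are resolved
in favour of the stronger exemplar.

A geometric caveat, visible in `examples/02_kinetic_genes.py`: under
correlation distance the C1 pulse and the C3 down-ramp are *positively*
correlated (~0.6; both are high early and low late) while C2 opposes both.
When noise-only false positives contaminate the kinetic set they can claim
one of the three clusters, merging C1 with C3; one extra cluster (k = 4)
absorbs them. This is a property of correlation-distance clustering at
fixed k, not of the implementation, and is why k is exposed.

Cluster *switches* between two conditions are genes kinetic in both with
different archetype labels; genes kinetic in only one condition are
reported separately, never as switches.

## Differential kinetics

The multi-condition model regresses each gene on a shared time polynomial
plus, for every non-reference condition (reference Th0), an offset and
polynomial-time interactions. Step one is the nested F-test of this full
model against the time-only model, BH-corrected across genes. Step two
tests, for each condition pair, the joint linear hypothesis that all
coefficients distinguishing the pair vanish (an exact F-test on the
restriction R·beta = 0, symmetric in the pair ordering); per-contrast BH is
applied among the step-one survivors and `quantitative_deg` requires both
steps. The joint F replaces the stepwise coefficient selection of
regression-based time-course workflows because it is deterministic,
order-independent and reparameterization-invariant; a backward-stepwise
mode (`stepwise_contrast_flags`, drop the least significant condition
coefficient until all survive at alpha = 0.05) is provided for fidelity and
is measurably more liberal, as greedy selection without multiplicity
control must be.

The *correlation index* is 1 - r, with r the Pearson correlation between
the two conditions' replicate-mean profiles over shared timepoints
(default; an all-samples mode correlates time-matched replicates). The
index lives in [0, 2]: 0 for identical trends, 1 for unrelated, 2 for
opposite. Quantitative DEG with index > 0.3 are *qualitative DEG* — the
trends differ, not just the levels. Genes with zero-variance profiles have
an undefined index and are excluded from qualitative calls rather than
imputed. The categories nest by construction
(qualitative ⊆ quantitative ⊆ kinetic), which is the structure the
correlation-volcano table exports.

## Hybrid decomposition

For each gene of the analysis set (canonically the Th1-vs-Th2 qualitative
DEG), the hybrid condition's profile is modelled as

    Y_hyb(t) = beta_Th1 · Y_Th1(t) + beta_Th2 · Y_Th2(t) + eps,

with no intercept term, fit by least squares on the ten replicate-mean
timepoints (an all-samples mode fits all 20 hybrid samples). Coefficient
t-tests use n - 2 degrees of freedom; classification is per-gene at
alpha = 0.05 without cross-gene multiplicity correction — the coefficients
classify a gene, they are not discoveries. Both significant and positive ->
Superposition; only one -> Th1-like / Th2-like; neither -> Independent. A
*significant negative* coefficient is flagged and the gene is classified by
its positive pattern only: silently calling a gene "like" a lineage it
anti-correlates with would be misleading. Pairs with |r(Th1, Th2)| > 0.999
are unidentifiable and reported unfit.

Two estimator choices matter and are deliberate:

1. **Profiles are mean-centred before the fit** (the no-intercept form is
   kept on centred data). On raw log2 values the shared per-gene baseline
   (~7 log2 units) dominates both regressors; any no-intercept fit is then
   pushed toward beta = (0.5, 0.5) with both coefficients "significant",
   and in simulation 44% of truly Independent genes were misclassified as
   Superposition even without noise. Centring removes the common baseline
   so the coefficients measure the contribution of each lineage's *kinetic
   response*, which is the scientific question; the uncentred raw fit
   remains available (`center=False`).
2. **The regressors are always the replicate-mean lineage profiles**, also
   in the all-samples mode (where only the hybrid target keeps
   per-replicate points). Regressors are estimated, not known, so the fit
   is an errors-in-variables regression and the coefficients are
   attenuated by the regressor noise; using raw replicate samples doubles
   the regressor noise variance and, in simulation, doubles the
   standardized bias of beta (about -1.2 SE versus -0.6 SE). With
   mean-profile regressors the generating weights of superposition genes
   are recovered within 3 SE in ~95% of cases at sigma = 0.25; the
   residual shortfall from nominal coverage is the remaining attenuation
   and is largest for strongly anticorrelated lineage pairs, where the
   design is worst-conditioned. Interpret beta point estimates as very
   slightly shrunk toward zero.

The threshold-robustness scan re-classifies the gene set over grids of
alpha (and of the correlation-index threshold regenerating the analysis
set) and reports category fractions in long format; on synthetic data the
Independent fraction moves by < 0.1 across alpha in {0.01, 0.05, 0.1}.

## Enrichment

Overrepresentation uses the hypergeometric upper tail P(X >= k) (survival
function; stable for small tails), with the universe equal to the
expressed genes — the standard ORA background. Gene sets are intersected
with the universe first and the size filter [3, 1000] applies to
within-universe sizes, because the m in the test *is* the within-universe
size. p-values are BH-corrected across all tested sets pooled over sources,
significant at FDR < 0.1.

## Exploration

PCA is computed on gene-centred samples; each component's sign is fixed so
its scores correlate non-negatively with time, removing the arbitrary sign
flip that would otherwise break reproducibility. Lineage trajectories are
differences of replicate-mean component scores against the neutral
reference (Th0) per timepoint; the reference's own trajectory is
identically zero. The bifurcation detector is a parameterized heuristic,
not a claim of an exact published procedure: first timepoint with |dPC|
above `fraction` (default 0.2) of the trajectory's maximum, plateau at 0.9
of the maximum, NaN for all-zero trajectories.

Genes correlated across *all* condition pairs (minimum pairwise r of the
replicate-mean profiles above 0.9; threshold exposed) carry no lineage
information and can be removed before the PCA; constant profiles count as
correlated. Quadrant co-expression statistics convert a 2x2 cytometry
frequency table into the conditional frequency of marker B within
A-positive cells and B's marginal frequency; conditional > marginal
indicates co-production synergy.

## Pipeline and reproducibility

`run_full_analysis` executes simulate/ingest -> preprocess -> kinetics ->
differential -> hybrid -> enrichment -> exploration from one flat config.
The qualitative Th1-vs-Th2 DEG feed the hybrid stage automatically; with no
qualitative DEG (e.g. a null dataset) the hybrid stage is skipped and the
manifest says why. Every output is TSV with a provenance comment header;
the manifest records per-stage parameters, row counts, wall times and
SHA-256 digests, and a rerun with identical config and seed reproduces
every file byte-identically. All randomness flows from the single config
seed through `numpy.random.default_rng`.

## Numerical conventions

* Residual sums of squares below 1e-12 are treated as perfect fits: the
  overall F-test reports p = 0 when there is variance to explain and p = 1
  when there is none; in perfect hybrid fits a coefficient is "significant"
  iff its magnitude exceeds 1e-8.
* Pearson correlations are clipped to [-1, 1] against floating-point
  overshoot; zero-variance profiles yield NaN and are excluded from the
  calls that would consume them (logged).
* Probe-collapse ties (`max_mean`) resolve to the first probe in input
  order; gene and sample order are preserved everywhere, so outputs diff
  cleanly between runs.

## Benchmark problem sizes

The test suite and the acceptance script use deliberately modest problem
sizes chosen to exercise each statistical property with adequate power
while keeping a full run fast on a single core: 2,000 flat genes for
type-I-error calibration (99% binomial band around 0.05), 300 archetype +
1,700 flat genes for kinetic recovery, 60 genes x 20 seeds for clustering
recovery, 200 genes per category for hybrid classification, 500
superposition genes for coefficient-coverage checks, and a ~2,000-gene
end-to-end pipeline run (a few seconds).

## Known limitations

* The F-tests assume homoscedastic Gaussian noise on the log2 scale; no
  empirical-Bayes variance moderation is applied, so very short time
  grids with few replicates would benefit from external shrinkage.
* The hybrid decomposition is errors-in-variables OLS (see above); beta
  estimates are mildly attenuated and their nominal confidence coverage is
  approximate, degrading with anticollinear lineage profiles.
* Correlation-distance clustering at fixed k is sensitive to contaminating
  noise genes (C1/C3 merging); inspect centroids, or raise k.
* The union of per-condition kinetic calls does not control FDR.
* The expressed-gene filter compares condition means against the global
  median; per-condition medians are a plausible alternative reading and
  would retain slightly different sets.
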