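# Methods

`connsweep` implements a condition-specific, graph-theoretical analysis of
task-fMRI functional connectivity for a two-group (patients vs. controls)
block-design study, together with a synthetic cohort generator that stands
in for non-public patient data. This note documents the models, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic validation does and does not establish.

## Pipeline model

Each participant contributes one scanning run: ROI BOLD series from a
160-node functional atlas (six networks: cingulo-opercular,
fronto-parietal, default-mode, sensorimotor, occipital, cerebellum),
nuisance channel signals (white-matter/CSF stand-ins), six rigid-body
realignment parameters, and a block design alternating 27.5 s of coherent
visual motion with 27.5 s of static dots (12 cycles, TR 2.45 s, 260
volumes; the twelfth cycle is truncated at the 637 s run end).

Stages run in fixed order:

1. **Motion QC.** Jenkinson framewise displacement
   FD_t = sqrt((R²/5)·tr(AᵀA) + tᵀt) from consecutive relative rigid-body
   transforms, with sphere radius R = 80 mm about the isocentre (the
   standard convention; the source analysis does not print a radius).
   Note FD is origin-dependent: adding a constant to the parameters
   changes FD unless the relative rotation is unaffected, which is why
   the offset-invariance checks use translation-only and single-axis
   rotation traces. Exclusion: sessions over 3 mm / 3° maximum motion are
   pre-filtered; then, in a single pass (never re-applied to survivors),
   participants with within-group |z| > 3 on mean FD or on the
   task–FD Pearson correlation (raw 0/1 task vector; a convolved variant
   is exposed as an option) are excluded.
2. **Denoising**, in this order: OLS removal of 5 nuisance principal
   components (aCompCor-style, deterministic sign convention), the 6
   realignment parameters, and the HRF-convolved motion and static
   regressors (so task co-activation does not masquerade as
   connectivity); discrete-cosine high-pass at 0.008 Hz (exact,
   phase-free; the DCT step also removes linear trend, making the
   subsequent explicit detrend largely redundant — both are applied as
   listed); linear detrend; despiking by tanh soft-clipping at
   s = 3 robust sd (1.4826·MAD), a documented stand-in for an
   undocumented toolbox default, with the parameter exposed
   (`despike_sd`). No low-pass anywhere. An optional spike-regressor mode
   (FD > 0.5 mm default) censors high-motion frames by regression.
3. **Condition-specific connectivity.** Per-scan weights are the
   HRF-convolved condition boxcar (canonical double-gamma: response peak
   6, undershoot 16, ratio 6, unit-peak scaling; scan-midpoint sampling
   rule) with negative values clipped to zero. The original toolbox
   additionally tapers condition boundaries; that kernel is not described
   in print, so the clipped convolved boxcar is used and the divergence
   documented here. Weighted Pearson correlations (frequency-weight
   semantics, scale-invariant) between all node pairs are Fisher
   z-transformed with |r| capped at 1−1e-7, anticorrelations set to zero
   (not absolute-valued), giving one symmetric nonnegative 160×160 matrix
   per condition.
4. **Cost sweep.** Proportional thresholding keeps the
   k = round(cost·n(n−1)/2) strongest weights (ties broken by row/column
   order for platform-independent reproducibility; zero weights are never
   kept). Main grid 0.04–0.30 step 0.01 (27 costs; the source text's "35
   thresholds" contradicts its own printed range, and the range wins).
   Per cost: degree centrality, clustering coefficient, eccentricity.
   Eccentricity on disconnected graphs uses the within-component
   (finite-distance) convention — propagating infinities would destroy
   the AUC summaries; isolated nodes get 0. Node curves are summarized by
   the trapezoidal AUC over the cost grid.
5. **Small-world screening.** On a separate grid (0.01–0.59 step 0.02; a
   0.02 step from 0.01 cannot land on 0.60), each graph is rewired to a
   degree-preserving random null (Maslov–Sneppen double-edge swaps, ~100
   attempts per edge) and a lattice null (swaps accepted only when they
   strictly shrink the total |i−j| edge span). The small-world regime is
   the longest contiguous cost run where, strictly,
   E_glob(lattice) < E_glob(real) < E_glob(random) and
   E_loc(random) < E_loc(real) < E_loc(lattice), on participant-pooled
   mean curves. An optional mode normalizes metric curves by the random
   null before AUC.
6. **Aggregation.** Unweighted network means of node AUCs give 6
   networks × 3 measures = 18 values per condition, 36 per participant;
   condition deltas are motion − static (computed on network means,
   equivalent to node-then-mean by linearity). The connectivity
   decomposition thresholds reduced weight blocks — within the focal
   network, between the sensorimotor and cerebellar networks, and from
   the focal network to the four remaining networks — each at
   k = round(cost · admissible pairs) (density relative to the block's
   own admissible pairs, the natural extension of proportional
   thresholding to rectangular blocks) and AUC-summarizes retained edges
   per focal node. Pre-threshold, the three partitions of a focal node's
   edges sum exactly to its full degree; post-threshold they need not,
   since each partition is thresholded separately.

## Group statistics

Classical split-plot sums of squares (the aov/afex family), not REML:
with n subjects, k within levels and p between parameters, the between
stratum fits subject means on [1, centered age, group(±1)] (error df
n−p), and the within stratum fits orthonormal contrast scores on the same
design (error df (k−1)(n−p)). Type III 1-df tests use the sum-to-zero
coding. Sphericity: Mauchly's W = det(S)/((tr S/(k−1))^(k−1)) on the
contrast covariance with its chi-square approximation, and
Greenhouse–Geisser ε = (Σλ)²/((k−1)Σλ²), clamped to [1/(k−1), 1]. The
GG-adjusted p is reported only when Mauchly's p < .05, mirroring the
source analysis' conditional reporting. The omnibus multivariate tests
pool hypothesis and error cross-products over the three measures (Pillai's
trace, with rank-reduction via the pseudo-inverse so degenerate DV sets
fall back to the lower-dimensional test); between effects are tested
against the between-stratum SSCP (df n−p), within effects against the
pooled contrast SSCP (df (k−1)(n−p)). Reported dfs follow this layout;
the source paper's printed dfs are internally inconsistent (its between
dfs imply one more subject than its multivariate dfs) and are not
reproduced.

Post hoc group contrasts within each network use the covariate-adjusted
per-network group difference with a standard error pooling both strata,
SE² = c·[MS_between + (k−1)·MS_within]/k (c the design variance factor of
the group difference, ≈ 1/n₁+1/n₂), Satterthwaite df for the mean-square
combination, and Tukey adjustment via the studentized-range distribution
with the number of means chosen so its pairwise count equals the family
size (4 means for the 6 within-network contrasts; a family of one is
unadjusted). The contrasts are gated by a policy flag requiring a
significant upstream group effect or group×network interaction. The
3-level connectivity-type decomposition ANOVA reuses the same machinery
without the covariate. An optional report flag notes the Bonferroni
criterion (α/3) across the three analysis families; it never gates.

## Synthetic cohort generator

The generator emulates the study conditions, not real BOLD physics. Per
network a shared latent AR(1) series L(t) (ρ = 0.3, matched by the
idiosyncratic node noise) drives node signals
noise_sd·(√c·L + √(1−c)·ε) + drift, so the expected within-network
correlation at constant coupling c is exactly c — a latent-factor
construction that is positive semi-definite by design, with per-network
coupling directly controllable. Coupling is modulated per (group,
network, condition) through the unit-peak HRF-convolved block regressor;
modulations leaving [0,1) raise an error rather than being repaired
silently. Drift is two random-phase cosines at 0.002–0.006 Hz
(amplitude 0.5 by default). Nuisance channels mix drift, a shared global
AR(1) series, and white noise. Head motion is a random walk (step sd
0.02 mm / 2·10⁻⁴ rad) plus a task-locked component scaled by the
motion–task coupling (0.3 default) and a per-subject amplitude. Cohort
defaults mirror the study: 18 HC / 17 PPV, ages uniform on [20, 60]. All
randomness descends from one seed via spawned substreams, so cohorts are
bit-reproducible and per-participant data do not depend on cohort
ordering.

Not emulated: voxel-level imaging, physiological (cardiac/respiratory)
noise, spatial autocorrelation between networks, realistic BOLD spectra,
or behavioral responses. Passing tests therefore establish that the
pipeline recovers the effects this generative family encodes — not that
it would detect effects in real patient data, whose raw form is not
publicly available.

A second, compact generator (`simulate_summary_cohort`) draws network
summary values directly — subject intercept + cell effect + residual,
within-cell sd = √(subject_sd²+noise_sd²), null age covariate — and is
what the calibration and power studies use: simulating 500 full imaging
cohorts through the whole pipeline would test the same statistical
machinery at several orders of magnitude more cost.

## Validation results and one known shortfall

Monte-Carlo studies at the study's group sizes (18/18 for the null,
18/17 with effect): the group×network interaction of the mixed ANCOVA
rejects at 4–5% under the null (inside the binomial 95% band around
α = .05 over 500 replicates), and a +1 within-cell-sd sensorimotor shift
for the patient group is flagged by the interaction in ≈ 83–84% of 200
replicates. The Tukey-adjusted sensorimotor contrast, however, rejects in
only ≈ 62–63%: its noncentrality at this design is pinned at
Δ/(s·√(2/18)) = 3.0 while the studentized-range critical value is ≈ 2.6,
putting the theoretical power near 0.65 for any split of subject vs.
residual variance. A joint ≥ 80% detection rate for interaction *and*
adjusted contrast is therefore not attainable at a 1-sd effect with these
group sizes; the corresponding acceptance test records this honestly
rather than inflating the effect.

## Numerical conventions and degenerate inputs

Rounding in thresholding is half-up (never banker's). Correlation caps at
|r| = 1−1e-7 keep atanh finite for duplicated nodes. Zero weighted
variance raises an error naming the offending node. Zero within-group sd
disables exclusion in that group with a warning. Constant time series
yield rank warnings in the PCA and degenerate-data errors in the
statistics (F undefined) rather than NaNs. Interchange files carry 6
significant digits; identical config + inputs reproduce outputs
byte-for-byte.

## Problem sizes in the shipped studies

The test suite and `scripts/acceptance.py` use a full-size cohort
(35 participants, 160 nodes, 260 volumes) for the structural pipeline
run, 4 participants for the null-model screening (each rewired at 30
costs with 100 attempts per edge), 500/200 replicates for
calibration/power, and 100 random graphs (n ≤ 30) for the graph-library
oracle comparison — sizes chosen to keep the whole validation suite
comfortably reproducible on a laptop-class single core.
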