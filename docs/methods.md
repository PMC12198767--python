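# Methods

## Problem and scope

After a first stroke, functional brain networks reorganize. One hypothesis
is that this reorganization makes the network *more resilient* to further
lesions: a recurrent stroke removes another set of regions, and a resilient
network loses less of its integrative and modular character. Because
recurrent strokes cannot be scheduled, resilience is probed *in silico*:
regions overlapping real lesion masks are deleted from each subject's
functional connectome, and graph metrics are compared before and after the
deletion.

`connres` implements that analysis end to end — preprocessing of region
time series into connectivity matrices, lesion-mask-to-region mapping,
graph metrics over a proportional-threshold density sweep, the virtual
attack battery with a normalized resilience statistic, a
participation-coefficient hub analysis, and the group-level statistics —
together with a synthetic-cohort generator that stands in for the clinical
data, which sit behind a restricted portal.

## Connectome construction

Input is a region-by-time BOLD-like series per subject (246 atlas regions
by default). The pipeline is fixed-order:

1. **Detrend / nuisance regression.** Each region series is replaced by its
   least-squares residual after projecting out an intercept, a linear
   trend, and any supplied nuisance regressors (in synthetic runs: the
   drift basis and spike indicators the generator emits, standing in for
   motion and CSF regressors). A rank-deficient nuisance block triggers a
   warning and a pseudo-inverse projection.
2. **Winsorization** to each region's own 5th/95th percentiles (linear
   interpolation between closest ranks; the percentile convention is a
   documented choice, the sources do not state one).
3. **Wavelet sub-band.** A periodized DWT (default `sym8`) is taken to the
   level whose dyadic band `[1/(2^(j+1) TR), 1/(2^j TR)]` best overlaps
   0.03–0.06 Hz — level 3 at TR = 2 s — and only that detail level is
   reconstructed. `sym8` was chosen for spectral concentration: for
   white-noise input ~75% of output energy lies inside the target band
   (`db4` manages only ~68%). The family is configurable.
4. **Pearson correlation** between all retained region pairs; zero-variance
   regions are a hard error naming the offenders.
5. **Region exclusion.** Signal-dropout regions (data-dependent, supplied
   as input) and, for patients, regions overlapping the subject's own
   primary lesion are deleted; a ledger records each removal and its
   reason. Removal is idempotent.

## Lesion mapping

An atlas label volume and a co-registered binary mask yield per-region
overlap fractions `|voxels of r in mask| / |voxels of r|`. A region is
lesioned when its fraction reaches 0.5. The boundary is **inclusive**
(≥ 50%) everywhere; the source material uses "more than 50%" in one place
and "at least 50%" in the operational definition of an attack, and the
inclusive reading was adopted with a `strict_greater` switch restoring the
strict variant. No resampling is performed: inputs must share a voxel grid,
and this is an explicit contract rather than a silent interpolation.

## Graph metrics and the density sweep

Metrics are computed on **binarized** graphs. A weighted matrix is first
cleaned with an absolute threshold (w > 0; negative correlations are
discarded), then swept over proportional thresholds δ ∈ {0.1, …, 1.0}: at
density δ the `round(δ·P)` strongest of the P positive edges become edges
(round half away from zero; ties broken by weight, then lexicographic node
pair, so results are reproducible). The ten edge sets are nested by
construction.

Binary, undirected conventions (Rubinov–Sporns):

- **Global efficiency** `E_glob = mean over ordered pairs of 1/d(i,j)`,
  with `1/∞ = 0` — low densities necessarily disconnect the graph.
- **Modularity** `Q = Σ_s [e_s/m − (d_s/2m)²]` evaluated at the *fixed*
  a-priori partition (17 modules by default, the Yeo-style template); no
  community detection. Edgeless graphs score 0 by convention.
- **Mean clustering coefficient**, with 0 for nodes of degree < 2.
- **Participation coefficient** `PC_i = 1 − Σ_s (k_is/k_i)²`; isolated
  nodes score 0.

Each metric's curve M(δ) is summarized by the trapezoidal **AUC** over
δ ∈ [0, 1]. The δ = 0 endpoint is supplied analytically (every metric of
the edgeless graph is 0) rather than as an eleventh empty graph; the
`value_at_zero` argument makes the endpoint explicit and overridable.

The exact metric formulas were adopted from the standard binary-graph
definitions; the supplementary material that would pin them down was not
part of the available text, so oracle tests compare every metric against
independent brute-force implementations (and networkx) rather than a
single authority.

## Attack battery and the resilience statistic

For each subject-timepoint matrix the battery computes pre-attack AUCs
once, then for every lesion set in the library deletes its regions from
the weighted matrix, re-thresholds, re-binarizes and recomputes the AUCs.
For a metric M:

    R(M)      = M_pre − M_post
    R_norm(M) = 1 − R_obs(M) / mean(R_control(M))

Controls therefore average exactly 0 (the battery reproduces this to
1e-12) and an attack causing no damage scores 1. The control reference is
control TP1 only, mirroring the source convention that control timepoints
were statistically indistinguishable; control TP2 rows are excluded from
the analysis by default.

**Skip rule.** An attack is skipped for a subject iff its region set is
entirely contained in the regions that subject has already lost (primary
lesion or dropout). Partial overlaps proceed on the remaining regions and
the application reports which regions were already absent. The sources do
not define partial-overlap behaviour; proceeding on the remainder keeps
the battery size maximal.

**Normalization mode.** The denominator is the grand control mean per
metric (**pooled**, the default). A per-attack mode (denominator = mean
control R for that specific mask) is provided and fully supported. Pooled
was made the default after the per-attack variant proved ill-conditioned
at desk scale: many masks damage controls by ~1e-4 or less, so the
per-mask denominator sits inside Monte-Carlo noise of zero and the ratio
statistic explodes. The control-mean-zero identity holds under both modes.
A guard excludes outcomes whose denominator is within `eps` (default 1e-9)
of zero; excluded rows carry a flag and a missing `r_norm`.

A caveat either way: the statistic presumes the control group is, on
average, *damaged* by an attack. For metrics whose mean control change is
negative (clustering can improve when weakly clustered nodes are deleted),
the sign convention of `R_norm` inverts and its variance is inflated by
the weakly identified denominator. This is a property of the statistic,
not of the implementation, and it is the main reason the type-I behaviour
of the clustering contrasts is the noisiest of the three metrics.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
tested; it is not a tuning dial. Structure mirrored from the study design:
75 patients (TP1/TP2/TP3, 20% lacking TP3) and 18 controls (TP1/TP2) by
default; 246 nodes in 17 modules; a library of 122 lesion region sets.

**Connectomes.** Within-module weights center on `mu_within` = 0.55,
between-module on `mu_between` = 0 (band-filtered between-network
correlations are weak), with N(0, 0.05) noise, symmetrized, clipped to
[−1, 1], unit diagonal. A hub set (10% of nodes, assigned round-robin so
every module gets a gateway before any module gets a second) carries the
inter-module backbone: hub–hub pairs get strong edges at `mu_within`. At
low binarization densities a module therefore reaches the rest of the
network only through its gateways — a concentrated architecture whose
hubs are single points of failure, and which makes the designated hubs
the highest-participation nodes.

**Group difference.** The redistribution strength κ ≥ 0 transplants the
full surplus of a fraction κ/(1+κ) of backbone edges onto randomly chosen
member–member inter-module edges: shortcut count, strength and total
weight are preserved, but the shortcuts de-concentrate from the hub set.
Controls default to κ = 0, patients to κ = 3. Consequences, verified as
pipeline properties: patient hub PC falls, peripheral (anti-hub) PC
rises, whole-network mean PC stays put (weight preservation), and the
patient network tolerates clustered deletions better because no single
gateway loss can sever a module — the architectural signature the analysis
is designed to detect. An earlier candidate mechanism (thinly spreading
hub weight over all peripheral edges) was rejected during design because
the diluted shortcuts fell below the binarization threshold at the
densities where the backbone matters, which inverted both the PC and the
resilience signatures.

**Lesion library.** Mask sizes follow a discretized log-normal, median
anchored at 6 regions; σ = 0.9425 is the least-squares fit of the two
continuous quartiles to the target IQR [2, 11] under the median constraint
(a two-parameter law cannot match all three numbers; the discretized law
lands at median 6, IQR [3, 11]). Sizes are truncated to [1, 0.2·n_nodes].
Regions are drawn preferentially from a seed module (p = 0.75) to mimic
the spatial clustering of vascular territories.

**Covariates.** Age ~ N(53, 9) years (patients), NIHSS ~ discretized
log-normal with mean ≈ 6 and SD ≈ 6 clipped to [0, 42], sex, lesion type
(85% ischaemic) and location sampled at the cohort frequencies; lesion
volume couples the mask's region count with a log-normal factor so that
the median volume is ~10 cm³. All are documented defaults, overridable
through `CohortSpec`.

**Determinism.** Every generator output is a pure function of its inputs
and seed; cohort-level randomness derives from a single `SeedSequence`
spawn tree, so an identical `CohortSpec` reproduces the cohort bit for
bit.

**Time series.** BOLD-like series are coloured Gaussian noise (Cholesky
factor of the PSD-repaired target correlation), plus per-region linear and
slow-cosine drifts and sporadic global spikes so the preprocessing stages
have realistic work. The generator emulates correlation structure only —
no haemodynamics, no spatial embedding, no scanner artefacts beyond
drift/spikes — so passing tests certify the pipeline's algebra and
statistical calibration, not physiological realism.

## Statistics

Attack outcomes are analysed as repeated measures: one row per subject ×
timepoint × mask, matching the large denominator degrees of freedom the
study reports (subject-level aggregation is available behind a flag in the
location ANOVA). Group/timepoint comparisons use a linear mixed model with
the four design cells (control TP1, patient TP1/TP2/TP3) as fixed effects
and a random intercept per subject, fitted by REML through statsmodels;
pairwise cell contrasts are Wald z-tests.

**Multiplicity.** The report applies Benjamini–Hochberg FDR across its
entire pairwise-contrast table (all three resilience metrics jointly, one
family). Correcting per metric would triple the families and push the
probability of at least one null rejection to ~1 − 0.95³ ≈ 14% under the
global null; a single report-level family keeps it at ~5%, which is what
the null-cohort calibration check verifies. Bonferroni (used for the
location ANOVA's pairwise comparisons) always dominates BH, and this is
asserted as a property test.

**Factor models** regress patient `r_norm` on timepoint, age, sex, NIHSS,
lesion size, type and location (random intercept per subject), emitting a
coefficient table with CIs. The **subsample balance check** redraws 18
patients (the control group size) four times and refits the group model.
The **location ANOVA** first averages `r_norm` across timepoints within
patient × mask, then applies a classical one-way F test across lesion
locations with Bonferroni-corrected pairwise t-tests; locations with
fewer than two units are excluded with a warning, and an all-constant
response is flagged as undefined rather than reported as a number.

**Hub analysis.** A node's PC per subject-timepoint is the AUC of nodal PC
over the same density grid (single-density mode available); the evaluation
density is not stated in the sources, and AUC keeps the convention of the
whole-brain metrics. Hubs are the 10 highest-PC nodes by control-TP1 mean
(ties broken by node id), anti-hubs the 10 lowest. Spearman correlations
(mid-ranks) relate patients' hub/anti-hub mean PC to their mean resilience
per timepoint. The nodal PC distribution is fitted with an exponentiated
Weibull by MLE with location fixed at 0; the reported skewness is the
fitted distribution's third standardized moment, not the sample's. MLE
recovery was verified at n = 5000 (each parameter within 10%); the
exponentiation and Weibull shapes trade off, so smaller samples identify
the pair only loosely.

## Reduced problem sizes

The simulation suites run at a reduced scale chosen as this package's own
test conditions: cohorts of 20 patients / 10 controls on 60-node,
8-module networks with 30-mask libraries, 20 seeds per condition. The
injected-effect direction checks, the null-cohort calibration and the
type-I control all use these sizes; the full 246-node / 122-mask defaults
run through the same code paths and are exercised structurally (shape
checks and single-matrix computations) in the same suite.

## Known limitations

- The normalized resilience statistic is unstable whenever the control
  group's mean damage for the chosen denominator is near zero (see
  above); per-attack normalization at desk scale is the worst case.
- Patients' primary lesions make their matrices smaller before any attack,
  so even with identical κ in both groups the two groups are not
  exchangeable. For global efficiency — whose control damage is solidly
  positive — the residual patient bias is within Monte-Carlo noise, but
  for modularity and clustering the handicap couples with the weakly
  identified denominator into patient-mean offsets of several standard
  errors. This is a property of the normalized statistic as applied to a
  lesioned group, not of the implementation. `CohortSpec
  (include_primary_lesions=False)` produces fully exchangeable groups for
  clean null calibration, and the test suite uses both variants.
- White-matter tract attacks, edge-deletion or attenuation lesion models,
  weighted-graph metric variants and community detection are out of scope.
- The exponentiated-Weibull location parameter is fixed at 0; support is
  (0, ∞), so PC values of exactly 0 must be excluded by the caller.
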