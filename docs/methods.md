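# Methods

This note documents the generative model, the estimators, the numerical
choices, and the limits of what the synthetic benchmark can show.

## Generative model

### Paradigm

TR 2 s, 234 volumes (468 s). Twelve 6-s odor+visual trials, one per 36-s
cycle starting at t = 10 s, intensities assigned in ascending blocks of
three (1,1,1,2,2,2,…). Twelve visual-only trials sit midway between odor
cycles (odor onset + 18 s). The visual-trial count and placement are a
package choice — the task structure fixes only that both condition types
exist — and are configurable in `build_paradigm`. Every odor trial's full
cycle must fit inside the scan; violations are rejected naming the first
offending onset.

### Cohort

Group sizes default to 31/19/12 (CN/MCI/AD). Each behavioral score is a
truncated normal at the cohort group mean ± SD, truncated to the
instrument range (UPSIT 0–40, MMSE 0–30, DRS-2 0–144, DRS-memory 0–25,
CVLT-II 0–80, GDS 0–30, age 40–100). Scores are kept continuous; rounding
to integer item counts would perturb the printed moments without changing
any downstream behavior. ROI volumes (hippocampus ≈ 7500/6600/6100 mm³,
POC ≈ 4200/3700/3450 mm³) and QC metrics are group-graded at plausible
magnitudes; the volume grading places the AD–MCI difference inside one SD,
matching the observation that it does not reach significance. Sex is
Bernoulli at the cohort ratios (16/15, 9/10, 4/8 M/F).

Olfactory class is a deterministic function of UPSIT: < 20 anosmic, 20–30
inclusive hyposmic, > 30 normosmic. The source text says "above 20" and
"above 30", leaving the boundary points open; both are assigned to the
hyposmic band and tested as such.

### Network time series

Each subject's ON/DMN "neural" series come from the same structural model
the euSEM stage estimates:

    η(t) = (I − A)⁻¹ [Φ η(t−1) + Γ u(t) + ζ(t)]

with u(t) the two condition indicators convolved with a canonical
double-gamma HRF (peak 5 s, undershoot 15 s, unit peak), Φ = 0.3·I,
ζ ~ N(0, 0.15²), and A carrying only the subject's planted DMN→ON
coefficient. Γ encodes the group-graded amplitudes:

| group | ON odor | ON visual | DMN (both) | noise SD | rand. w | EC mean ± SD |
|-------|--------:|----------:|-----------:|---------:|--------:|-------------:|
| CN    |    1.00 |      0.60 |      −0.80 |      0.6 |    0.00 | 0.30 ± 0.08  |
| MCI   |    0.55 |      0.10 |      −0.50 |      0.6 |    0.25 | 0.25 ± 0.10  |
| AD    |    0.50 |      0.50 |      −0.40 |      0.6 |    0.60 | 0.12 ± 0.10  |

The pattern encodes the reported findings qualitatively: ON odor response
CN > MCI ≈ AD; the odor-minus-visual difference positive in CN and MCI
(larger in MCI, via its low visual response) and absent in AD; DMN
suppression weakening with disease; EC graded CN > MCI > AD. Temporal
randomization mixes the task-locked series with smoothed noise
(η ← (1−w)·η + w·s, s Gaussian-filtered white noise matched in SD), zero
in CN and largest in AD — "lower in magnitude and divergent".

Calibration of the free scales was done once, at design time: the study
conditions require the CN ON/DMN series to be anti-correlated on every
seed and subject time courses to be recoverable at r ≥ 0.9 from the
default data. A contemporaneous EC of ~0.5 acting on a strongly suppressed
DMN cancels most of the ON drive and injects positively correlated noise
into both nodes, destroying the anti-phase property for high-EC subjects —
hence the EC scale of ~0.3 and the innovation SD of 0.15. Voxel noise SD
0.6 against unit-peak responses (peak CNR ≈ 1.7) is consistent with
spatially smoothed event-related data and leaves the network-recovery
properties stable across seeds rather than marginal.

The stationarity of the induced lag-1 system, spectral radius of
(I−A)⁻¹Φ < 1, is asserted at generation.

### EC–UPSIT coupling in MCI

Within MCI, planted EC is linear in UPSIT plus independent noise. The
slope is chosen so that corr(EC, UPSIT) equals the target (default 0.639)
*within the UPSIT > 20 subpopulation* of the truncated score distribution,
because that is the subgroup the headline analysis retains. Calibrating on
the full MCI group instead would leave the post-filter correlation
attenuated by range restriction to ≈ 0.52. The subpopulation moments are
computed analytically from the truncated normal, so the property holds by
construction rather than by simulation tuning.

### Voxel data

24×24×12 grid. Each network is a set of hard-truncated Gaussian blobs
(σ = 1.6, support radius 2.8 voxels) at fixed coordinates standing in for
the anatomical nodes; ON sits on the z=3 plane and DMN on z=9, which makes
all nine blobs pairwise disjoint by construction. Voxel signal is
Σ_networks map × η_network(t) plus white noise; the mask is the full grid.
No motion, spikes, drift fields, or anatomy are simulated.

## Estimators

### Group ICA

Per subject: voxel-wise mean centering, temporal PCA to 40 components
(SVD). Group: concatenation, PCA to 50 with whitening (spatial covariance
I ± 1e-6). FastICA (scikit-learn; symmetric decorrelation, log-cosh
contrast, tol 1e-6, max 1000 iterations) on the top-variance whitened
components, 10 restarts from seeded initial conditions. Restarts that hit
the iteration cap are flagged but still clustered: with a large Gaussian
noise subspace the fixed point never settles globally even when the signal
components have, and the stability index — mean within-cluster |r| minus
mean between-cluster |r| after average-linkage clustering on 1 − |r|,
clipped to [0,1] — is the instrument that exposes unreliable components.
20 components are retained by default on the synthetic grid (the 40/50
PCA levels target whole-brain data; all counts are configurable).

ON/DMN selection is by spatial correlation against the planted templates
(sign-oriented positive, ties broken by stability, matches below |r| = 0.3
flagged unmatched). Back-reconstruction is dual regression — spatial then
temporal least squares — returning unit-variance time courses with the
scale stored. After selection, the ON time course correlates positively
with the odor regressor on CN data and the DMN negatively.

### HRF and β

FIR deconvolution over lags 0–20 s at TR resolution (11 coefficients),
pooling the odor+visual events, with Legendre drift columns up to order 2.
Only the odor events are modeled: under the default paradigm the visual
onsets sit exactly 18 s after the odor onsets, so FIR columns for both
conditions at a 20-s window are exactly collinear (odor lag 9 ≡ visual
lag 0); the 36-s odor cycle keeps the single-condition design overlap-free.
Estimates are unit-peak-normalized with sign preserved (a suppressed
network keeps its negative curve) and the scale stored.

The CN group HRF — the lag-wise mean of the CN unit-peak estimates, ON
network — is the only response shape used for β estimation in every group;
per-group HRFs are deliberately not used (MCI/AD time courses are too
random for reliable per-subject deconvolution, which is the observation
this convention encodes). Single-trial regressors place that estimated
event-response curve directly at each trial onset: the FIR curve is the
response to the full 6-s stimulus, so convolving it with the stimulus
boxcar again would double-count the duration. All trial regressors plus
drift are fit jointly by OLS; β therefore carries the units of the time
course (SD units after back-reconstruction). Suppression is reported as
the signed (negative) β; the M ± 2.5 SD outlier rule is applied to
condition-mean β before group tests, and nowhere else.

### euSEM

Two nodes (ON, DMN), two inputs (odor+visual, visual-only), lag-1,
candidate set of 14 paths: 2 contemporaneous (A), 4 lagged (Φ, incl.
self), 4 exogenous (Γ), 4 bilinear (T, contemporaneous u·η variant;
a lagged variant is configurable). Estimation is per-equation OLS over
t = 2..T with an intercept; designs with condition number above 1e8 are
rejected.

The group search is forward: each absent candidate is tested by
single-addition t test in every subject; the candidate significant
(p < α = 0.01) in the largest fraction of subjects enters if the fraction
reaches the majority criterion (0.75). Three conventions make the search
identifiable, all standard for this model family: lag-1 self-paths are
freed from the start (contemporaneous direction is not discriminable
before autoregressive terms are controlled); contemporaneous paths that
would close a directed A cycle are inadmissible (SEM recursiveness); and
fraction ties break by the larger median |t| across subjects before
lexicographic order. After the search stops, admitted paths whose refit
significance fraction drops below the majority are pruned. An empty
structure is a valid outcome; on white-noise cohorts the search admits
nothing in ≥ 95% of runs.

The headline coefficient is contemporaneous A_ON←DMN (the lagged or
bilinear DMN→ON terms can be selected instead), residualized on age by
OLS. In the pipeline, if the search did not admit the path, it is added
for extraction only and the forcing is logged.

### Statistics

One-way fixed-effects ANOVA (scipy) with Welch pairwise post-hocs from
group summaries, uncorrected by default (Bonferroni optional); an
algebraically identical from-summary variant. Pearson χ² without
continuity correction. Pearson r with the two-tailed t-based p. Two-way
ANCOVA EC ~ UPSIT + DRS-memory + UPSIT:DRS-memory (+ age) by OLS with
Type-III sums of squares on mean-centered covariates (statsmodels).
`behavioral_report` reproduces the full analysis grid — score ANOVAs, sex
χ², UPSIT–cognition correlations overall and in MCI+AD, β and volume
associations, and the MCI-only EC analysis under the strict UPSIT > 20
filter — skipping degenerate sections with a log entry. Every statistic is
tested against an independently coded brute-force oracle (explicit SS
decompositions, covariance formulas, partial-SS model comparisons) at
1e-10-grade tolerances, and null type-I rates are checked against the
binomial band around α.

## Pipeline and determinism

`run_pipeline` executes simulate → gICA → HRF → β → euSEM → stats, each
stage reading its inputs from the results directory, with per-stage seeds
derived as SeedSequence(master, crc32(stage)). The manifest records every
output file's SHA-256 plus the settings actually used (window lengths, α,
majority, boundary conventions); identical config + seed reproduce the
tree hash-identically. Runs are written as uncompressed NIfTI-1 by default
so the hashes are bit-stable; `.nii.gz` is available via config.

## Problem sizes

The test suite and the acceptance script run desk-scale versions chosen as
the package's own benchmark sizes: 10-subject CN cohorts for network
recovery, 20 cohort replicates for the anti-phase and β-pattern fractions,
100 replicates × 15 subjects at T = 200 for euSEM bias, 40 null cohorts
for the false-path rate, 200 cohorts for the EC–UPSIT recovery, and
500/300-replicate null batteries for type-I checks. The end-to-end
determinism check uses a 6/4/3 cohort on the full grid.

## What passing tests do and do not show

The generator plants exactly the structure the estimators assume: linear
mixing of compact disjoint networks, white voxel noise, a correctly
specified euSEM, no motion or physiological confounds, no registration
error. Recovery under these conditions validates the implementation — the
estimators find what is there, at the planted effect sizes and realistic
SNR — but says nothing about robustness to model misspecification,
spatially correlated noise, overlapping networks, or HRF variability
across regions and subjects. The headline EC–UPSIT check is a
planted-parameter recovery at the published correlation used as the
generator target, not a reproduction of the original subject-level result,
whose raw data are not public. Printed test statistics of the original
cohort (table F values, χ²) are additionally not recomputable from its
printed summaries under standard formulas and are therefore not asserted
anywhere.

## Known limitations

- Two-node euSEM only; no region-level models, no likelihood-based SEM fit
  indices, no confirmatory subgrouping.
- β estimation shares one group HRF across networks and groups by design;
  per-intensity responses are not modeled (intensities exist to counter
  habituation, not as a modeled effect).
- The ICASSO stability index is a dissimilarity-based surrogate, not the
  original cluster-quality index; with few restarts it is optimistic for
  singleton clusters.
- The inclusion filter's accuracy boundary is implemented as ≥ 75
  (the printed threshold is retained); motion is strictly < 3 mm.
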