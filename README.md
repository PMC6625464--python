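# olfnet

Olfactory-network / default-mode-network analysis of task fMRI in
Alzheimer's disease, with a fully synthetic data generator.

## The problem

Alzheimer's pathology reaches the primary olfactory cortex (POC) and
hippocampus early, and smell identification (the 40-item UPSIT) declines
before overt dementia. During an odor–visual association task, group ICA of
BOLD data reveals two task-locked networks: an **olfactory network (ON)** —
POC, hippocampus, insula, striatum — that activates with the stimulus, and
the **default mode network (DMN)** — PCC/precuneus, bilateral IPC, mPFC,
MTL — that is *suppressed* (negative task-locked signal change). In
cognitively normal (CN) subjects the two hemodynamic responses are in
anti-phase; in mild cognitive impairment (MCI) and AD the responses shrink
and the time courses randomize. The directed influence (effective
connectivity, EC) from the DMN to the ON, estimated by extended unified
structural equation modeling (euSEM), tracks olfactory performance in MCI.

`olfnet` implements that whole analysis chain as a tested pipeline, and —
because no raw subject data are public — a synthetic-data module that
generates CN/MCI/AD cohorts with exactly the statistical structure the
analysis assumes, so every stage is verifiable end to end against planted
ground truth.

## Methods at the core

- **Cohort generator** (`olfnet.cohort`, `olfnet.bold`): behavioral scores
  per group as truncated normals at the cohort means ± SDs (e.g. UPSIT
  33.42 ± 4.19 / 25.58 ± 7.69 / 11.58 ± 5.42 for CN/MCI/AD); two-network
  4-D BOLD runs built from the euSEM generative model with a planted
  DMN→ON coefficient, group-graded amplitudes, temporal randomization, and
  white voxel noise. Paradigm: TR 2 s, 234 volumes, 6-s odor stimuli once
  every 36 s at four ascending intensities (×3), interleaved visual-only
  trials.
- **Group ICA** (`olfnet.gica`): voxel-wise centering, per-subject temporal
  PCA (default 40), group PCA (default 50) with whitening, FastICA
  (symmetric, log-cosh) with random restarts, ICASSO-style agglomerative
  stability clustering (dissimilarity 1 − |r|), template matching for
  ON/DMN, dual-regression back-reconstruction.
- **HRF and single-trial β** (`olfnet.hrf`, `olfnet.betas`): least-squares
  FIR deconvolution over 0–20 s at TR resolution pooling the odor events;
  the CN group HRF is the single response shape used to fit one β per trial
  per network (joint least squares with polynomial drift). DMN suppression
  is a negative β.
- **euSEM effective connectivity** (`olfnet.eusem`): per node *i*,

  η_i(t) = Σ_{j≠i} A_ij η_j(t) + Σ_j Φ_ij η_j(t−1) + Σ_k Γ_ik u_k(t)
           + Σ_{j≠i,k} T_ijk u_k(t) η_j(t) + ζ_i(t)

  estimated per equation by OLS; a group forward search (significance in a
  majority of subjects, α = 0.01, majority 0.75) selects the shared
  structure; the headline quantity is the contemporaneous A_ON←DMN
  coefficient, residualized on age.
- **Statistics** (`olfnet.stats`): one-way ANOVAs (raw and from summary
  statistics) with Welch post-hocs, sex χ², Pearson correlations, the
  M ± 2.5 SD outlier rule, UPSIT classification (<20 anosmic, 20–30
  hyposmic, >30 normosmic), and the two-way ANCOVA with the
  UPSIT × DRS-memory interaction (Type-III SS, centered covariates).

## Worked example

The numbered drivers under `analysis/` run the stages in order on a
desk-scale cohort (10/8/6 subjects per group, 24×24×12 grid):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_group_ica.py
python analysis/03_hrf_betas.py
python analysis/04_effective_connectivity.py
python analysis/05_group_statistics.py
```

Representative output (seed 42):

```
cohort: 24 subjects, 23 retained after QC
  excluded sub-019: accuracy 65.6 < 75
ON  -> component 0, template |r| = 0.934
DMN -> component 1, template |r| = 0.964
CN ON vs DMN HRF correlation: -0.996 (anti-phase: True)
ANOVA      upsit: F =  20.84, p = 1.28e-05
r(upsit_vs_cvlt2_all) = +0.731, p = 0.0001
EC vs UPSIT (MCI, UPSIT>20, n=7): r = 0.617, p = 0.1403
```

Reading this: group ICA found both planted networks (template correlations
0.93/0.96); the CN group HRFs of ON and DMN oppose each other (r ≈ −1,
the anti-phase relation); UPSIT separates the diagnostic groups strongly
and correlates with verbal memory; and in hyposmic-or-better MCI subjects
the age-corrected DMN→ON coefficient rises with UPSIT — the headline
association, here at a small n where the point estimate is meaningful but
the p value is not. The mean condition-β table from step 03 shows ON
activation graded CN > MCI > AD, a positive odor-minus-visual difference in
CN and MCI but not AD, and DMN suppression weakening from CN to AD.

The same pipeline is scriptable (`olfnet run-all --seed 7 --out results`)
and fully deterministic: identical config + seed reproduce every output
file hash-identically (see `manifest.json`).

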