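# eegpheno — digital EEG phenotypes and stimulation-response stratification

`eegpheno` is a tested re-implementation of a clinical-neurophysiology
analysis pipeline that stratifies individuals into **digital EEG
phenotypes** from pre-stimulation resting-state spectral features and then
labels each phenotype cluster as a **positive**, **negative** or
**non-responder** to transcranial direct current stimulation (tDCS), based
on behavioral task performance under active vs sham stimulation.

It is written for researchers in EEG biomarkers and neuromodulation who
want to run, probe or extend this kind of responder-stratification analysis
without access to the original (non-public) clinical data: a synthetic
cohort generator with planted ground truth stands in for the study data and
makes every stage testable.

## The pipeline

1. **Features.** Each 2-minute, 32-channel, 500 Hz eyes-closed resting
   recording is band-pass filtered (1000-tap FIR, 2–45 Hz), demeaned and
   detrended; four artifact-prone frontal channels (AF4, Fp2, Fp1, AF3) are
   dropped; 4-s epochs (50% overlap) containing samples above 100 µV are
   rejected; data are re-referenced to Cz (then excluded). Per retained
   epoch and channel, relative band power (RBP) is computed in delta
   (2–4 Hz), theta (4–8), alpha (8–13), beta (13–30) and gamma (30–45);
   the session feature vector is the epoch-median, 27 channels × 5 bands =
   **135 features**.

2. **Clustering.** Session vectors are clustered with Fuzzy C-Means
   (fuzzifier m = 1.7) and spectral clustering (n_components = k),
   k scanned over 2–6 with five validity indices (silhouette,
   Davies–Bouldin, Calinski–Harabasz, spherical-Gaussian BIC, inertia);
   the analysis uses k = 4. FCM minimizes
   `J = Σ_ij u_ij^m d_ij²` with memberships
   `u_ij ∝ (1/d_ij)^{2/(m−1)}`; for spectral clustering, prototypes are
   cluster means and soft memberships are normalized inverse Euclidean
   distances to the prototypes. Session memberships are averaged over each
   subject's 4 sessions; the hard phenotype is the arg-max (e.g. membership
   (0.2, 0.3, 0.4, 0.1) → cluster 3).

3. **Response labeling.** Per condition family (stimulation group ×
   task concurrency) and endpoint (task × metric), subject-level
   active−sham deltas (±2.5 SD outlier filter) are correlated with cluster
   memberships by **partial Spearman correlation** adjusted for age, sex,
   IQ and handedness, with Benjamini–Hochberg FDR within the family.
   A significant correlation drafts a verdict by sign (higher accuracy or
   faster RT under active → positive); the verdict is confirmed only if a
   rank-sum Wilcoxon test of the cluster's members against all remaining
   subjects (BH-corrected within the condition) is also significant.

4. **Validation.** Subject-level 80/20 clustering hold-outs with
   nearest-prototype test assignment; repeated (M) correlation hold-outs at
   80/60/40% of subjects; Kruskal–Wallis check that clusters carry no
   baseline performance structure.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (56 subjects × 4 sessions, four phenotype archetypes,
a planted positive responder on N-Back accuracy in phenotype 2 and a
planted negative responder on Flanker reaction time in phenotype 3):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_extract_features.py
python analysis/03_cluster_phenotypes.py
python analysis/04_label_responders.py
python analysis/05_validate_robustness.py
```

Output of steps 03–05 (abridged):

```
spectral: session-level ARI vs planted phenotypes = 0.965; subject shares per cluster {1: 0.232, 2: 0.25, 3: 0.25, 4: 0.268}
fcm: session-level ARI vs planted phenotypes = 0.942; ...
96 correlations tested; 5 significant drafts
confirmed responder labels (cluster, condition, endpoint, verdict, rho, wilcoxon p_adj):
  cluster 3 | A/concurrent | Flanker rt | negative | rho=+0.678 | p=0.0001
  cluster 2 | A/concurrent | N-Back accuracy | positive | rho=+0.694 | p=0.0001
  ...
clustering hold-out (80% train, 20 folds): mean test agreement 0.998
correlation hold-out for cluster 2 (N-Back accuracy, non-concurrent), M=200:
   80%: rho +0.629 (SD 0.047), corr p 0.0001 (SD 0.0006), ...
   40%: rho +0.617 (SD 0.118), corr p 0.0204 (SD 0.0416), ...
baseline structure check: 0 of 6 endpoints reject at alpha=0.05
```

Reading the numbers: both algorithms recover the four planted phenotypes
almost perfectly (adjusted Rand index ≥ 0.94); the labeling stage marks the
planted accuracy-responder cluster *positive* and the planted RT-responder
cluster *negative* and nothing else; hold-out agreement near 1 shows the
clustering is stable; the correlation's standard deviation grows (and its
p-value degrades) as the subsample shrinks from 80% to 40%, while the
baseline check confirms clusters differ only after stimulation, not before.

A `eegpheno` CLI wraps the same stages (`simulate`, `features`, `cluster`,
`label`, `run`); `eegpheno run --out runs/demo --seed 1` executes the whole
pipeline with a provenance manifest.

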