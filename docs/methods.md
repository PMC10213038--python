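# Methods

This note documents the models, parameter choices and numerical decisions
behind `eegpheno`, and what the synthetic-cohort results do and do not
show.

## Preprocessing and features

The feature pipeline is fixed by the analysis design: 1000-coefficient FIR
band-pass at 2–45 Hz, per-channel demean and linear detrend, exclusion of
AF4/Fp2/Fp1/AF3, epoch-level artifact rejection at 100 µV on 4-s windows
with 50% overlap, Cz re-reference (Cz then dropped), per-epoch relative
band power in the five canonical bands over the 2–45 Hz total, and the
elementwise median over retained epochs. Decisions where the design left
room:

- **PSD estimator.** A Welch estimate with a single 4-s segment reduces to
  a modified periodogram, so each epoch uses a Hann-windowed periodogram —
  the simplest estimator consistent with per-epoch band power.
- **Band edges.** Adjacent bands share edges (4, 8, 13, 30 Hz); intervals
  are half-open `[low, high)` so no frequency bin is counted twice.
- **Artifact granularity.** Rejection is per epoch, not per sample:
  features are epoch-based and partial epochs would bias the PSD. The
  threshold is applied after filtering and before re-referencing; the
  ordering is exposed in the parameters.
- **Filter delay.** The even-length (1000-tap) linear-phase design has a
  group delay of 499.5 samples; a single forward pass is compensated by a
  499-sample shift. The residual half-sample delay is irrelevant to
  spectral features.
- **Median renormalization.** Elementwise medians do not exactly preserve
  per-channel sum-to-one, so rows are renormalized after the median; the
  feature contract (each value in [0, 1], channel sums = 1 within 1e-9,
  length 135) is enforced on construction.
- **Feature order.** Channels in acquisition order minus exclusions, bands
  delta→gamma, flattened row-major; column names `<channel>_<band>`.

Relative powers are ratios, so features are invariant to any positive
rescaling of the input — a property test multiplies a recording by an
arbitrary constant and requires identical features.

## Clustering

FCM is implemented directly (alternating membership/center updates,
convergence when the maximum center displacement < 1e-6, objective
non-increasing by construction). Because the objective is non-convex, the
fit runs 5 k-means++-seeded restarts and keeps the lowest final objective.
A sample coincident with a center receives membership 1 there (the
standard singularity rule). Spectral clustering delegates to scikit-learn
on a precomputed RBF affinity with γ = 1/135 plus a 1e-12 uniform floor
(keeps the affinity graph connected); the embedding is clustered by
k-means with 10 seeded restarts.

The membership function for spectral clustering is the normalized inverse
Euclidean distance to the cluster prototypes, `u_ic = (1/d_ic)/Σ(1/d_ic')`,
chosen for its exact-prototype limit (membership 1 on a prototype) and its
equivalence to the m→2 FCM membership form; a `softmax(−d²/τ)` alternative
is available behind a keyword. Features are clustered raw (RBP fractions
are already scale-free); a standardization switch is deliberately absent
from the default path.

Validity indices (silhouette, Davies–Bouldin, Calinski–Harabasz, inertia,
and a spherical-Gaussian BIC of the x-means form, used only for relative
comparison across k) are reported for k = 2–6; a chord-distance elbow
suggestion is emitted but k is never auto-fixed — the analysis uses k = 4
as a configuration input. Singleton clusters contribute silhouette 0 (the
library convention).

Clusters are numbered 1..k everywhere; arg-max ties break toward the
lowest index.

## Response labeling

Active−sham deltas are computed per subject × task × metric × concurrency;
subjects missing an arm are excluded from that endpoint and counted in the
log. Outliers beyond ±2.5 sample SD of an endpoint's deltas are removed in
a single pass (SD = 0 keeps all).

The partial Spearman correlation rank-transforms x and y (average ranks on
ties), residualizes both ranked vectors on an intercept plus the raw
covariate matrix [age, sex as 0/1, IQ, EHI handedness], and correlates the
residuals; the p-value uses the t distribution with n − 2 − q degrees of
freedom, two-sided. With no covariates this reduces exactly to ordinary
Spearman (tested to 1e-12). Note one estimator subtlety: `pingouin`
rank-transforms the covariates as well; the two estimators coincide when
given pre-ranked covariates, which is how the cross-check test is written.

BH-FDR families are all cluster × endpoint tests within one
group × concurrency condition (4 clusters × 6 endpoints = 24 tests per
family at the defaults); family sizes are logged per run. The draft
verdict follows the sign rule — positive responder if (accuracy, ρ > 0) or
(RT, ρ < 0), negative for the reverse — and is confirmed only when the
members-vs-rest rank-sum test, BH-corrected within the condition, is also
significant; otherwise the cluster is a non-responder for that endpoint.
The rank-sum p-value is exact (full enumeration, via the exact
Mann–Whitney distribution) for combined n ≤ 12 without ties, and the
tie-corrected normal approximation otherwise. Correlation p-values are
two-sided; the significance threshold is 0.05 on adjusted p-values.

## Synthetic cohort generator

The generator emulates the study design: 56 adolescent subjects (ages
10–17, IQ ≥ 80, EHI in [−100, 100]), two stimulation groups (A/B), four
sessions per subject of 120-s, 32-channel, 500 Hz eyes-closed EEG, and a
behavioral table (Flanker, N-Back, CPT × accuracy, RT × active, sham ×
concurrent, non-concurrent).

**Spectral phenotypes.** Four archetypes are parameterized from their
qualitative descriptions: (1) neurotypical posterior-dominant alpha,
(2) theta-shifted "slowing", (3) low alpha with elevated beta/gamma,
(4) strong alpha with a 20 Hz beta peak and a flattened frontal–parietal
alpha gradient. Exact amplitudes are free parameters of this package.
Each subject expresses its archetype with an individual grade drawn from
U(0.4, 1.0): the subject's RBP topography is the archetype interpolated
toward the cohort-average profile. This makes cluster membership a
continuous individual trait — the property the membership-correlation
analysis presumes — rather than a binary one. Sessions add multiplicative
lognormal weight jitter with 5% CV, chosen so that the four sessions of a
subject sit much closer to each other than to other phenotypes (verified
by a dedicated test).

**EEG synthesis.** Sessions are stationary Gaussian processes built in the
frequency domain: a 1/f background carrying 5% of channel power, per-band
flat components scaled channel-wise by the phenotype topography, and
Gaussian-shaped narrowband peaks at the alpha (and optionally beta) peak
frequency carrying 30% of their band's budget. This is equivalent to
summing band-pass-filtered noise and narrowband oscillations but gives
exact control of band power. Two measurement-chain corrections make the
*measured* RBP hit the planted target: the PSD is pre-emphasized by the
inverse squared magnitude response of the analysis band-pass (whose 2 Hz
transition band would otherwise swallow a third of delta power), and the
per-band budgets solve a 5×5 linear system built from the expected
Hann-periodogram leakage of each spectral component (plateau edges at 2
and 45 Hz are also continued half a Hertz outward so edge bins are not
starved). The reference electrode Cz is synthesized at 2% power — the
idealization of a quiet reference — so re-referencing leaves per-channel
RBP essentially unchanged. With these corrections the extracted features
of a jitter-free 120-s session match the target topography within 0.05
absolute per channel and band (tested for all four archetypes); the
remaining error is periodogram estimator noise plus a small residual
median bias. Channel RMS defaults to 10 µV so recordings stay inside the
100 µV rejection threshold; optional high-amplitude bursts exercise the
rejection path.

**Behavioral model.** Sham values come from subject baselines — accuracy
via a logistic-bounded Gaussian latent (mean 1.2, SD 0.35 → accuracies
around 0.77), RT via a log-normal (median 450 ms, 6% between-subject SD)
— with per-arm latent noise (SD 0.15 accuracy, 0.08 log-RT). The planted
treatment effect is a **dose-response in phenotype membership**: every
responder plan (by default phenotype 2 positive on N-Back accuracy,
phenotype 3 negative on Flanker RT) shifts the active arm by
`effect_size × u_true[plan's phenotype]` latent-noise SDs of the delta,
where `u_true` is the subject's ground-truth soft membership (normalized
inverse squared distance of its profile to the archetypes; the squared
exponent counteracts distance concentration in 135 dimensions). Positive
responders gain accuracy and lose RT; negative responders the reverse.
A weak linear age confound acts on log-RT (level and delta) to exercise
the covariate adjustment. When no membership vector is supplied the dose
defaults to one-hot in the subject's own phenotype, so a non-responder
subject's expected delta is exactly zero.

`effect_size` defaults to 4.5. The study's real effect magnitudes are not
recoverable from published statistics, so the default is calibrated for
detectability under the cohort's own design: 28 subjects per group, BH
correction over 24 tests per family, and an outlier filter that trims the
strongest responders. With 4.5 the planted labels are recovered in well
over 80% of seeded cohorts while null cohorts stay at the q-level; this
value should be read as "a clearly responding subgroup", not as an
empirical estimate.

**What the generator does not emulate.** Real EEG nonstationarity, ocular
and myogenic artifact morphology, volume-conduction correlation between
channels (channels are independent processes), task-evoked activity,
electric-field physics of tDCS, and realistic trial-level behavioral
noise. Passing recovery tests therefore demonstrate that the *pipeline*
is correct and well-calibrated — not that real cohorts of this size carry
detectable responder structure.

## Validation procedures

Hold-outs move whole subjects (all four sessions together), stratified by
stimulation group. The clustering hold-out (default 20 folds at 80%
train) assigns held-out sessions to the nearest train prototype and
reports agreement with a full-data fit after Hungarian label matching.
The correlation hold-out repeats the partial Spearman and rank-sum tests
on M subject subsamples at 80/60/40% and summarizes the mean/SD of ρ and
the p-values; "distance to the original fit" is the mean absolute vertical
residual of the subsample's points to the full-data degree-1 least-squares
line of delta vs membership. The baseline structure check runs
Kruskal–Wallis across clusters per endpoint on pre-treatment values,
excluding clusters with fewer than 2 subjects and skipping endpoints with
fewer than 2 usable clusters.

## Problem sizes and runtime choices

The test suite and acceptance script use the feature-level fast path of
the generator (RBP vectors sampled directly from the jittered phenotype
topographies) for the Monte-Carlo recovery and power checks — the
waveform path and the preprocessing chain are exercised separately by the
spectral-fidelity and feature-contract tests, and the two paths share the
same jitter and dose models. Monte-Carlo sizes: 10 seeds for ARI
recovery, 50 (tests) / 25 (acceptance script) seeds for responder
recovery, 15–25 null cohorts, M = 200 hold-out repeats, 1000 rank-sum
null simulations. These sizes put Monte-Carlo error comfortably inside
the asserted margins while keeping a full run in tens of seconds.

## Determinism

Every stochastic component takes an explicit seed; cohorts are bit-identical
under a fixed seed, and the pipeline derives per-stage seeds from the global
seed by hashing the stage name, so stages are independently reproducible.
The one caveat inherited from upstream: scikit-learn's spectral embedding
can differ across library versions, so cross-version byte-identity of
cluster outputs is not promised — within an environment, reruns are
identical.

## Known limitations

- The spec of the membership function ("a probability function of the
  Euclidean distance") is inverse-distance by choice here; other monotone
  kernels are defensible and one (softmax) is provided.
- Internal validity indices are weakly informative in 135 dimensions; the
  scan reports them and an elbow suggestion but the analysis treats k as a
  design input.
- EDF export is not available in this environment's dependency set;
  recordings round-trip through MNE `RawArray`/FIF instead, and EDF input
  is supported via MNE's reader.
- The BH family composition (which tests share a family) materially
  affects which correlations survive; it is configurable and logged, with
  the group × concurrency matrix as the default.
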