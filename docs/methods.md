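# Methods

This note documents the models implemented in `wmosc`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Study design being emulated

A change-detection task: a sample array of 2/4/6 colored squares
(low/medium/high load) shown for 2250 ms, a retention interval, then a
test array identical to the sample on half of the trials. EEG is epoched
from 725 ms before sample onset to 4000 ms after retention onset at
250 Hz. The cohort is healthy elderly adults (n = 31, mean age 67.3,
SD 6.2). Two geometries are provided:

| parameter | scaled-down (default) | full scale |
|---|---|---|
| subjects | 12 | 31 |
| channels | 16 | 60 |
| trials per load | 20 | 60 |
| epoch (s, re retention onset) | −1.2 … +3.5 | −2.975 … +4.0 |
| sample onset (s) | −0.5 | −2.25 |
| frequency grid | 20 points, 4–30 Hz | 53 points, 0.5 Hz steps |
| TFR time step | 50 ms | 8 ms |
| permutations | 500 | 1000 |

The scaled-down epoch is longer than a naive miniature would be because
three time anchors must coexist: the pre-sample baseline (150–50 ms
before sample onset), the 1–3 s retention analysis window, and a 3σ_t
wavelet edge margin at 4 Hz (σ_t ≈ 0.159 s). −1.2…+3.5 s is the smallest
round window satisfying all three. All simulation studies in the test
suite use the scaled-down geometry; these problem sizes are the package's
default desk-scale choice.

## Behavior

Generation follows an equal-variance Gaussian signal-detection model:
with target sensitivity d′ and criterion c, change trials are hits with
probability Φ(d′/2 − c) and no-change trials false alarms with
probability Φ(−d′/2 − c). The scorer inverts exactly this model through
the count-corrected rates HR = (NH+0.5)/(NH+NM+1), FAR =
(NFA+0.5)/(NFA+NCR+1), so generator and scorer agree by construction
(verified by Monte Carlo at 10 000 trials). At 20–60 trials per cell the
corrected estimator is visibly shrunk toward 0 near ceiling — that is a
property of the correction, not a bug, and the reason the consistency
test uses a large trial count.

Default load effects: target d′ = 3.0/2.0/1.2 and median RT location
560/650/685 ms for low/medium/high — chosen so that accuracy falls and RT
rises with load, the low-load condition sits near ceiling (as in the
design being emulated, where most subjects exceeded 95% correct), and the
medium-vs-high RT contrast is weak. Subject ability is a shared Gaussian
factor (SD 0.4, 60% of its variance common across loads), which gives
across-load d′ correlations around 0.6. RTs are shifted log-normal
(shift 250 ms, σ = 0.30) with a per-subject log-location factor.

The load ANOVA is the classical one-way within-subject decomposition,
F = MS_load/MS_load×subject with df = (k−1, (k−1)(n−1)). No sphericity
correction is applied by default (none is part of the emulated analysis);
a Greenhouse–Geisser epsilon adjustment is available behind
``sphericity_correction=True``. With
k = 3, n = 31 this yields df = (2, 60). Published F statistics of this
kind are sometimes quoted with the between-subject error df (2, 90);
the package implements and reports the repeated-measures df. Planned
paired contrasts use 0.05/3; a constant non-zero difference vector has
zero variance and is reported as degenerate (p = NaN, flagged) rather
than inventing an infinite t. The 3-SD outlier rule is single-pass by
design: mean and SD are computed once over all subjects.

## EEG synthesis

Each trial is background noise plus a narrowband oscillation:

* **Background**: 1/f^β noise (β = 1) synthesized in the frequency
  domain with random phases, independent per channel, normalized to unit
  variance.
* **Oscillation**: band-pass-filtered white noise confined to the
  theta-alpha band (5–12 Hz) — amplitude-modulated noise rather than a
  pure sinusoid, so trial-to-trial phase varies realistically. Its
  amplitude is a0 before retention onset and γ afterwards.
* **Spatial structure**: one smoothing pass over the sensor adjacency
  graph, x ← 0.5·x + 0.5·(neighbor mean). Because background and
  oscillation are mixed identically, per-channel power scales cancel in
  the relative baseline change.

a0 is set by `oscillation_snr` (default 1: oscillatory band power equals
background band power in the baseline). γ is calibrated per subject and
load so that the *measured* band-mean relative change from baseline —
through the same wavelet response used by the analysis, with the
background's contribution included — equals the target in expectation.
The band-mean ratio is linear in γ², so the calibration is closed-form;
the recovery test confirms −0.25 injected → −0.25 ± 0.05 measured at 20
subjects. Because power cannot drop below the background floor, targets
below ≈ −snr/(1+snr) raise an error. Default targets −0.05/−0.15/−0.25
for low/medium/high load (the emulated effect's published form is a
cluster statistic, not an effect size; these magnitudes are chosen for
comfortable desk-scale detection power) with subject-level SD 0.05, 60%
shared across loads.

Sensor layouts are concentric rings covering the unit disc with a center
electrode; neighbors are pairs closer than `neighbor_radius` (0.70 for 16
channels, 0.35 for 60, giving minimum degree 3 — necessary for the
minimum-neighbor-channel rule to be satisfiable, and in the range of
typical montage neighbor counts).

What the generator does **not** emulate: eye blinks, muscle artifacts,
bad channels, trial rejection (preprocessing is out of scope — inputs are
clean by construction), volume conduction beyond the one smoothing pass,
1/f slope variation across subjects, and any topographic focality of the
load effect (it is injected on all channels). Passing tests therefore
validate the statistics under clean, exchangeable, spatially homogeneous
conditions; they do not certify behavior under artifact-laden recordings.

## Spectral analysis

Wavelets are unit-energy complex Morlets, σ_t = n_cycles/(2πf), truncated
at 5σ_t; convolution runs in the frequency domain (FFT zero-padded to the
next fast length). Unit energy makes white-noise expected power flat
across frequency — verified within 10% — since the emulated analysis does
not state a normalization. Output samples within 3σ_t of an epoch edge
are set to NaN rather than zero-filled; the 1–3 s analysis window never
touches them. Averaging is the arithmetic mean within condition; baseline
correction is relative change (P − P_b)/P_b with P_b from the same
condition's trials (condition-specific by design), guarded against double
application and non-positive baselines; a pure-ratio mode P/P_b is
available behind ``mode="ratio"``.

## Cluster permutation test

Paired t-values over subjects on per-condition trial-averaged maps;
zero-variance samples get t = 0 (they cannot enter clusters). Candidate
samples (|t| above the two-sided p < 0.05 threshold) are pruned first: a
sample survives only if ≥ `min_neighbor_channels` (default 3) neighboring
channels are simultaneously supra-threshold with the same sign at the
same (frequency, time). Cluster pipelines of this kind differ in whether
they prune before or after component formation, and the emulated
analysis does not pin this down; pruning-first is implemented, and the
parameter accepts 0 (off) or any other minimum for sensitivity analysis. Surviving
samples connect along one time step, one frequency step, or channel
adjacency at fixed (f, t); connected components are clusters, mass = Σt.

Permutation flips each subject's condition labels independently
(equivalently the sign of its difference map); the maximum cluster mass
per sign per permutation forms the reference distribution, and
p = (b + 1)/(m + 1) with ties counted as exceedances — slightly
conservative relative to a strict "proportion larger" rule, but strictly
positive and validly sized. With ≤ 3 subjects (or on request) all 2^n
sign assignments are enumerated instead and p = b/2^n including the
identity. Significance is declared at 0.025 per direction (0.05
Bonferroni over the two tails). Type-I calibration (200 null datasets) and
sensitivity (≥ 90% detection of the injected effect over 50 runs) are
asserted in the acceptance suite; the null datasets are generated at the
map level (smoothed Gaussian condition maps), which is the level the
permutation machinery operates on and is distribution-free for type-I
validity, while the sensitivity study runs the full synthesis chain.

Mean baseline-corrected power within the group significance mask is
extracted per subject and load, which intentionally reuses one
group-level mask for all conditions.

## Structure–function statistics

Structural scalars (age; parahippocampal and striatal gray matter; PHC–
parietal, PHC–frontal and frontal–parietal tract connectivity; seed-mask
sizes) are drawn from a multivariate normal matched to a target
correlation matrix (validated symmetric, unit-diagonal, PSD), conditioned
on the already-realized d′ and latent power columns, whose values are
left byte-identical. The conditional projection uses the *empirical*
correlation of the realized columns so the configured new-vs-existing
correlations are achieved without attenuation; if the empirical block
makes the residual covariance indefinite (small n), the configured block
— whose Schur complement is PSD by construction — is used instead. The
emulated study's whole-brain voxelwise regressions are deliberately
reduced to correlations on these extracted region-level scalars; mask
sizes enter only as covariates.

Partial correlation residualizes both variables against an intercept plus
covariates and tests r√(df/(1−r²)) against t(df), df = n − 2 − k.
Dependent correlations sharing one variable are compared with Steiger's Z
(Fisher-transformed, Dunn–Clark covariance evaluated at the pooled
correlation); the Williams-t variant is available behind a flag. The
empirical size of the default statistic is 5% ± 1% under a
trivariate-normal null (asserted at n = 50, 10 000 replicates).

The power analysis solves power(ρ) = 0.80 by bisection (tolerance 1e-6)
for the two-sided test at α = 0.05, n = 31, with the critical r from the
exact t transform. Three sampling models of r are implemented: exact
integration of its bivariate-normal density (the default; yields 0.478,
matching the classical G*Power computation), the bias-corrected Fisher-z
normal approximation (mean atanh ρ + ρ/(2(n−1)), SD 1/√(n−3); 0.479),
and the uncorrected Fisher approximation (0.486, kept for reference). A
100 000-replicate Monte Carlo confirms the rejection rate at the returned
ρ is 0.80 ± 0.01. n = 31 (the analyzed sample) is used, not the
pre-exclusion 32.

Batteries of tests apply per-column single-pass 3-SD exclusions,
pairwise-complete deletion per test, and per-family Bonferroni thresholds
(α/2 for the gray-matter families, α/4 for connectivity); low-load d′ is
computed but excluded from correlation stages by default (a config flag,
not hard-coded), mirroring the near-ceiling low-load condition.

## Pipeline, formats, determinism

All tables are TSV with headers; arrays are little-endian float32 with
JSON sidecars documenting dimension order and grids ([trial][channel]
[sample] for epochs, [channel][frequency][time] for maps). One global
seed drives everything; each stochastic operation derives a child RNG
from (seed, stage name, subject index) via SeedSequence, so stages are
reproducible in isolation and two runs with the same config produce
byte-identical stage outputs (the manifest records SHA-256 checksums;
wall-clock timings live only in the manifest). A run with no significant
clusters writes an empty mask-power table, the report states "no
significant clusters", and association tests requiring mask power are
skipped with a logged count rather than failing the run.

## Known limitations

* The generator's effect is spatially global; topographic specificity of
  the cluster test is not exercised.
* Trial counts are balanced by construction; the emulated study's
  per-subject trial rejection (unbalanced cells) is not simulated.
* Cluster inference operates on trial-averaged maps over subjects;
  trial-level permutation is out of scope.
* The d′ estimator's ceiling compression means generator targets and
  recovered values agree only asymptotically in trial count.
* `min_detectable_r` implements only the two-sided test.
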