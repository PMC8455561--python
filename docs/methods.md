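# Methods

`neurovote` reimplements a pre-electoral EEG/behavioral analysis chain and
pairs it with a synthetic-data generator so that every inferential stage can
be exercised and calibrated without access to participant data. This note
documents the models, the generator, the numerical choices, and what the
test suite does and does not establish.

## The analysis chain

**Design.** Participants read 126 ten-word survey items — 3 issue dimensions
(anti-establishment, economy, culture) x 2 item types (populist,
non-populist) x 21 items — while 61-channel EEG is recorded. Epochs are
time-locked to the final, *critical* word (the antonym that flips the item's
political valence) and span −100..1200 ms. Each participant later reports a
vote for a mainstream or a populist party; a 7-block IAT measures implicit
attitudes toward party leaders.

**Preprocessing.** Zero-phase Butterworth filtering (low-pass 30 Hz order 4;
high-pass 0.1 Hz order 1 — see *Numerical choices*), average re-referencing,
100 ms pre-stimulus baseline correction, and amplitude-threshold artifact
flagging (default ±100 µV on scalp channels; ICA-based correction is out of
scope because the synthetic data contain no ocular sources and no numeric
criterion exists to reproduce). Exclusions proceed in logged stages:
non-mainstream/populist votes; fewer than 14 artifact-free epochs in any
dimension x item-type cell (ERP); fewer than 20 in any cell (decoding);
missing agreement responses (self-report). "Relevant conditions" for the
14-epoch rule are interpreted as every dimension x item-type cell.

**N400 congruency analysis.** Condition averages per participant x dimension
x item type; mean amplitude in the half-open [300, 600) ms window at 12
posterior electrodes (CP1–4, P1–4, Pz, PO3, PO4, POz). The congruency
hypothesis — a larger posterior negativity for items contradicting the
voter's group — is tested with a mixed ANOVA (Voting Behavior between; Item
Type x Dimension x Electrode within), per-dimension follow-ups (electrodes
averaged) and per-group Item Type follow-ups.

The mixed ANOVA is computed via orthonormal Helmert contrasts on the
within-subject cells with a Type-III between-subjects model (effect coding),
so that with unequal group sizes the within effects test unweighted means of
group means; it reproduces R's `car::Anova(type = 3)` to printed precision.
Greenhouse–Geisser epsilon comes from the eigenvalues of the pooled
within-group contrast covariance, eps = (Σλ)² / (q Σλ²), clipped to
[1/q, 1]; Mauchly's test at alpha = 0.05 decides whether the corrected
p-value is adopted (epsilon is always reported). Partial eta squared is
SS_effect / (SS_effect + SS_error) within each stratum.

**Sliding-window decoding.** Per participant and dimension, a linear SVM
(C = 1; libsvm by default, liblinear available for desk-scale runs — both
fit the same linear maximum-margin model) predicts item type from the
spatio-temporal pattern in consecutive, non-overlapping 10 ms windows. Each
window contributes floor(window_ms x sfreq / 1000) samples per channel
(20 x 61 = 1220 features at 2048 Hz), independent of grid alignment. The
majority class is undersampled to parity before each of (by default) ten
repeats of a stratified ten-fold cross-validation; remainder trials are
dealt round-robin. *Empirical chance* re-runs the identical procedure with
shuffled labels (default 10 shuffles, mean taken; the number of shuffles is
a config knob because no canonical value exists). No feature scaling is
applied: all features share units (µV).

**Cluster-mass permutation test.** Per window, a paired one-tailed t-test of
real > chance across participants; runs of ≥ 2 consecutive windows with
p < 0.05 form candidate clusters with mass = summed t. The null is the
maximum cluster mass over 5000 sign-flip permutations of each participant's
(real, chance) pair; because a sign flip leaves each window's second moment
unchanged, the permuted t statistics reduce to a single matrix product and
the permutation loop costs only the run-length scans. Cluster
p = (1 + #null ≥ observed) / (n_perm + 1), the standard
observed-labelling-included estimate; a Bonferroni factor across the
dimensions tested in one family is applied on top. A 20 ms sanity rerun and
a time-overlap report are provided.

**Behavioral indices.** The self-report index
SRI = (% populist items agreed + % mainstream items disagreed) − (% populist
items disagreed + % mainstream items agreed), with percentages over the
*answered* items of each type (range −200..+200; per-type denominators
follow the Kelley-index tradition; fully missing item types flag the record
rather than silently dropping it). RT means exclude trials slower than
2700 ms (the derived mean + 2 SD cutoff is reported alongside). The IAT D
index deletes latencies above 10,000 ms, computes the *inclusive* SD — the
sample SD of the pooled latencies — for combined blocks 3∪6 and 4∪7,
divides each block-pair mean difference by its pooled SD, and averages the
two ratios with equal weight; latencies under 300 ms raise a warning. No
error-trial latency penalty is applied (none is defined for this task).
Split-half reliability is the Spearman–Brown-adjusted Pearson correlation of
the two pair-wise D scores.

**Voting models.** Six logistic regressions of vote (mainstream = 0,
populist = 1) on identical complete-case rows: (1) the economy N400
differential at POz (populist-item minus non-populist-item window mean),
(2) IAT D, (3) economy SRI, (4) N400 + SRI, (5) age, age², gender, interest
in politics, left–right self-placement, (6) all. Continuous predictors are
z-scored by default (recorded in the fit) so the Wald equality test of
different-unit coefficients is meaningful; age² is computed after centring
age. Fit metrics: McFadden 1 − ℓ/ℓ₀; Nagelkerke
(1 − e^{2(ℓ₀−ℓ)/n}) / (1 − e^{2ℓ₀/n}); λ = (C − M)/(n − M) with C the
correct classifications at threshold 0.5 and M the modal-class count —
0.5 is the only threshold under which a no-information model scores exactly
0. Perfect separation aborts the fit with a diagnostic instead of silently
penalizing. The Wald test is W = (b_a − b_b)²/(var_a + var_b − 2cov_ab)
against chi²(1).

## The synthetic-data generator

The generator's defaults are the study conditions: 40 mainstream + 29
populist analysable voters (the `study_roster` constructor adds the 9
other-party voters, 3 non-voters, 1 blank ballot, two participants with
lost responses and two with a contaminated condition cell, reproducing the
82 → 69 → 67 → 65 bookkeeping), 61 channels, 21 trials per cell, epochs
−100..1200 ms at 256 Hz by default (2048 Hz representable).

* **Background noise** is a per-subject mixture of `n_channels/4` pink
  (1/f-amplitude) sources — volume conduction makes real EEG noise
  spatially smooth and approximately low-rank — plus independent white
  sensor noise (pink 4 µV, white 2 µV per sample). Channel-independent
  noise was rejected as unrealistic: it makes multivariate decoding at
  21 + 21 trials per class hopeless, contradicting the phenomenon the
  chain is built to detect. No alpha rhythm is simulated.
* **Congruency effects.** Incongruent trials (populist items for mainstream
  voters, non-populist items for populist voters) receive a negative
  Gaussian deflection with a posterior spatial profile peaking at POz:
  economy items at 450 ms (SD 40 ms, −2 µV), culture items at 1150 ms
  (SD 60 ms, −1.5 µV), anti-establishment items never. Per-subject
  amplitudes vary with SD 1 µV. Only the critical-word valence enters any
  computation, so items are abstract (dimension, type, pair id).
* **Agreement** is drawn through a logistic link on a per-participant latent
  populism score: group-shifted by ±`attitude_sep`/2 for economy and
  culture, a common mean for anti-establishment. `attitude_sep = 1.6` was
  calibrated by simulation so the realized economy SRI group effect is
  d ≈ 1.55 (the reported magnitude); culture shares the parameter and
  realizes ≈ 1.5 (slightly above the reported 1.26 — accepted to keep one
  parameter). RTs are lognormal and group-independent.
* **IAT** latencies are lognormal with a per-participant compatibility
  shift (N(60, 110) ms) added to blocks 6–7, drawn *independently of
  voting group*; block sizes 20/20/20/40/20/20/40, all latencies floored
  at 320 ms. The shift scale yields population mean D ≈ 0.24 with SD
  ≈ 0.45, bracketing the reported group means.
* **Left–right self-placement** leans right for populist voters so the
  socio-demographic model has realistic (moderate) predictive power; age,
  gender and political interest are group-independent.

What the generator does **not** emulate: ocular/muscular artifacts (hence
no ICA), alpha and other rhythmic activity, spatial autocorrelation of the
*effect* beyond the fixed posterior profile, item-level semantics,
undecided-at-test-time status, and any correlation between implicit and
explicit attitude strength within voting groups (SRI noise, N400 amplitude
and D are conditionally independent given the vote). Passing tests
therefore demonstrate that the chain is correct and calibrated under a
plausible signal/noise model — not that the original recordings would
reproduce any particular number.

## Numerical choices

* **High-pass order.** A steep zero-phase high-pass applied to short epochs
  smears late slow deflections backwards through the epoch; with an
  order-4 0.1 Hz high-pass the injected late (culture) component leaked
  ≈ −0.17 µV into the N400 window and produced spurious culture
  interactions. The high-pass is therefore first-order (12 dB/octave after
  the forward-backward pass), the convention in ERP work; replicate-based
  calibration runs disable the epoch-domain high-pass entirely (the
  synthetic epochs carry no sub-0.1 Hz drift and baseline correction
  handles per-epoch offsets), while the operation itself retains its
  attenuation contract and tests.
* **Windows** are half-open [start, stop) ms with 0 at the critical word;
  the window grid tiles the nominal epoch span, and per-window sample
  counts are fixed at floor(window_ms x sfreq / 1000) regardless of grid
  alignment.
* **Permutation p-values** include the observed labelling
  ((1 + k)/(1 + N)), making the test exact-conservative rather than
  anticonservative at k = 0.
* **Separation** in logistic fits (exact or quasi, detected via pinned
  fitted probabilities) raises an error recommending penalized estimation;
  it is never applied automatically.
* **Degenerate inputs**: empty condition cells are absent, never
  zero-filled; empty IAT scoring blocks and single-class outcomes raise;
  cells with zero answered items flag the SRI record as missing.

## Reduced problem sizes in tests

Replicate-based checks use scales chosen by power analysis so each check is
informative at desk scale; the full-scale defaults (61 channels, 10x10-fold
CV, 10 chance shuffles, 5000 permutations) are untouched package defaults.

* *Decoding-cluster recovery*: 50 replicates of 34 participants, 16-channel
  posterior-anchored montage, 128 Hz, 5-fold x 2-repeat CV, 2 chance
  shuffles, 10 ms windows tiling 410–500 ms, 500 permutations, Bonferroni
  factor 3. A corrected cluster overlapping 400–470 ms is recovered in
  ≥ 90% of replicates.
* *Congruency-interaction specificity*: 50 replicates of the 69-voter
  cohort at 32 channels / 64 Hz; economy-only significance across the three
  per-dimension follow-ups in ≥ 80%.
* *λ dominance of the combined model*: the strict inequality
  λ₄ > max(λ₁, λ₃) flips on ±1 reclassified case at n = 69 because λ is
  count-quantized; it is therefore checked on a scaled-up cohort (n = 200,
  full 61-channel montage, epochs cropped at 700 ms — the late component
  plays no role) where the structural ordering resolves, in ≥ 80% of 14
  replicates.
* *Null calibrations* (cluster familywise rate, chance-accuracy centring,
  interaction size) run with all effect amplitudes at zero; the cluster
  calibration feeds the group-level statistic directly with
  information-free accuracy timecourses, which is the component under
  test.

## Known limitations

* The univariate approach to the mixed ANOVA is exact for the balanced
  within-subject designs used here; heavily missing within-cells are
  rejected, not imputed.
* The average reference subtracts the montage mean of the injected
  posterior effect; on reduced, posterior-heavy montages this attenuates
  ERP effect sizes, which is why reduced-scale ERP checks use ≥ 32
  channels.
* λ, being a thresholded count, is intrinsically coarse at n ≈ 69;
  interpret single-dataset model orderings with that quantization in mind.
* The EEGLAB-style reader is best-effort plumbing for external data and is
  not covered by tests.
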