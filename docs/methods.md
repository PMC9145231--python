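# Methods

`tntfusion` re-implements, as a tested pipeline, the analysis chain of a
simultaneous EEG-fMRI study of memory suppression in the think/no-think (TNT)
paradigm, and validates every stage against a synthetic-data generator that
injects the hypothesized effect structure with known ground truth. This note
documents the models, the generator, the numerical choices, and what the
validation does and does not establish.

## The scientific model under test

In the TNT task, a cue word instructs either retrieval (Think) or suppression
(No-Think) of a studied associate. The hypothesis chain the pipeline tests:

1. **Early proactive control.** No-Think cues evoke a frontocentral negative
   deflection (the suppression N2, ~300-450 ms) and a frontal-midline theta
   burst (4-8 Hz, ~250-800 ms), both generated partly in dorsal anterior
   cingulate cortex (dACC). Their single-trial strength indexes how early and
   strongly control is engaged.
2. **Less early control, more later demand.** Trials with strong early
   control show *lower* aggregate BOLD in dACC, right dorsolateral prefrontal
   cortex (rDLPFC) and hippocampus during No-Think, but not Think — negative
   single-trial EEG-BOLD coupling specific to suppression.
3. **Conflict signalling.** When suppression fails to prevent retrieval, a
   delayed dACC delta/theta deflection (~548-708 ms) marks conflict; on
   high-conflict trials dACC Granger-causes rDLPFC activity in the
   theta/alpha range (post-N2 window, 450-1450 ms).
4. **Top-down hippocampal downregulation.** During No-Think, rDLPFC
   Granger-causes right-hippocampal activity in the low beta band, and
   hippocampal theta (4-6 Hz, 650-1850 ms) is suppressed on large-N2 trials.
   Hippocampal theta couples positively to hippocampal BOLD.
5. **Behavioral consequence.** Recall of suppressed items falls below
   baseline (suppression-induced forgetting, SIF); participants with a larger
   N2 effect forget more (positive N2 / z-SIF correlation).

Real recordings of this kind are not publicly deposited, so no printed
statistic from human data is reproducible here. Validation is property-based:
the generator injects each effect at configurable strength; acceptance means
the matching pipeline arm detects it, null configurations stay null at the
nominal error rate, and analytic oracles agree.

## Synthetic-data generator

One participant is simulated as follows (all defaults in
`synth.GroundTruthConfig`).

**Design.** 16 Think, 16 No-Think and 8 perceptual-baseline items, each
repeated 12 times over 6 runs of 290 volumes at TR 1.5 s (435 s per run,
~80 trials per run with jittered onsets). Item-level learned flags
(p = 0.745 / 0.795) reproduce the published mean learned-trial counts of
~142 Think and ~152 No-Think per participant. A reduced configuration
(`reduced_config`: 12 participants, 8 items x 5 repetitions = 40 trials per
condition, 3 runs of 140 volumes, all items learned) is used throughout the
test suite; it is the size of the parameter-recovery study, chosen to keep a
full multi-seed validation within interactive runtimes.

**Latents.** A participant factor `g ~ N(1, 0.3)` scales control strength.
Per No-Think trial, the early-control latent `e ~ N(g, 0.35)` drives both the
N2 depth (6.0 + 4.5(e-1) µV at the source) and the theta-burst amplitude
(3.0·e); a conflict latent `k`, anticorrelated with `e` (ρ = -0.4), scales
the delayed dACC deflection (6.5·k µV) and gates the directed coupling.
Hippocampal theta amplitude in 650-1850 ms falls linearly with `e`
(slope 0.7). Think trials get smaller, condition-constant evoked amplitudes
and sustained retrieval theta.

**Sources and oscillators.** Each ROI (dACC, rDLPFC, hippocampus) is one
active source at its centroid plus two silent neighbor grid points; coherent
copies at several points would be suppressed as correlated sources by the
beamformer, so the ROI average attenuates but never cancels the signal.
Stochastic oscillations are unit-variance AR(2) resonators (radius 0.92) at
6 / 9 / 15 / 5 Hz. Directed influences are injected into the receiver's
innovations at a 20 ms lag: dACC theta -> rDLPFC with strength
2.4·max(k - 1.25, 0) (a dead zone, so the low-conflict stratum carries
essentially no influence even when a noisy conflict measure misclassifies
borderline trials), and rDLPFC beta -> hippocampus with strength 1.0 on
No-Think trials only. rDLPFC also receives its own conflict-scaled delayed
deflection, which keeps the transient (evoked-residual) content of the two
regions comparable — an asymmetry there produces spurious GC dominance that
only the time-reversal control can unmask.

**Forward model.** Gain columns are unit-norm draws from a spatial Gaussian
process over a schematic 32-channel 10-20 layout. ROI centroids additionally
receive a characteristic topography on their dominant orientation
(frontocentral blob for dACC, right-frontal for rDLPFC, left-temporal for the
hippocampus), sign-aligned so the dACC deflection is negative-going at the
pooled frontocentral channel — without this the N2 would not reach the
sensors it is measured at, as it does in vivo. Sensor data =
gain · sources + white noise (0.8 µV) on top of smooth background source
activity (47 background sources, one-pole low-passed noise).

**BOLD.** Per-trial neural amplitude = condition mean + signed coupling x
centered latent (negative couplings of `e` in all three ROIs during
No-Think; positive coupling of the hippocampal theta latent to hippocampal
BOLD), convolved with the canonical SPM double-gamma HRF (peak 6 s,
undershoot 16 s, ratio 6; unit-peak scaling) and sampled at TR, plus AR(1)
noise (ρ = 0.3, SD 0.85) and a random linear drift. Single-trial coupling
contrast-to-noise is ~0.5-0.7 at defaults. Six random-walk "motion"
regressors are generated as nuisance covariates only.

**Behavior.** Per item and test (same probe SP / independent probe IP),
recall is Bernoulli with Baseline probabilities 0.82 (SP) and 0.62 (IP),
group-specific memorability offsets (removed by z-SIF), and a No-Think
deficit of 0.12 + 0.45(g - 1) — the injected SIF and its link to the
participant's control strength.

All randomness flows through `numpy.random.Generator` streams keyed by
(config seed, participant, stream id); identical configurations reproduce
identical datasets bit for bit, and fixture round trips are bit-exact.

## Analysis stages and numerical choices

**ERP.** Evoked responses are baseline-corrected trial means (250 ms precue
window). Filtering is zero-phase FIR (Hamming/firwin design); because 0.5 Hz
band edges require filters longer than one epoch, signals are reflect-padded
and convolved with the symmetric taps directly. Single-trial N2: the search
window runs from the pre-N2 positive peak (P2) to the post-N2 positive peak
(P3) of the participant's grand-average pooled ERP within 150-600 ms
(fallback 250-500 ms); latency is the interior minimum of the 8 Hz low-passed
pooled signal (ties resolved toward earlier latency), amplitude the mean of
the 0.5-30 Hz signal in a 100 ms window around it; trials whose minimum sits
on a window edge are invalid. Downstream analyses use the *depth*
(negated amplitude), so "larger N2" is a larger positive number and coupling
signs read as in the hypothesis.

**Time-frequency.** Morlet wavelets (3 cycles for low-frequency/source
analyses, 6 for sensor maps) on mirror-padded epochs (-3000..5500 ms),
power averaged into 1 Hz x 50 ms bins and cropped to -500..3000 ms. The
single-trial z-baseline pools the mean and SD over trials AND time points per
channel x frequency, then averages trials, then subtracts the mean baseline
z-power (-500..0 ms); pooling over trials alone at each bin would force the
trial average to zero everywhere, so the full-epoch pooling is the only
self-consistent reading. Condition contrasts share one normalization
(`z_baseline_by_condition`). The normalization is exactly zero-mean over the
baseline and invariant to per-channel rescaling.

**Beamformer.** LCMV with unit-gain constraint per source triplet;
covariance is the empirical covariance over the stated window with diagonal
loading λ = 1e-5 x largest eigenvalue (the 0.001% rule), no further
shrinkage. Evoked contrasts use epoch-average subtraction (filters computed
on the 300-570 ms No-Think-minus-Think difference). Orientation collapse
projects onto the leading eigenvector of the pooled 3x3 covariance; its sign
is aligned to positive correlation with the pooled frontocentral evoked
reference where one exists.

**Permutation statistics.** Cluster-forming threshold is the t quantile at
α = 0.05 per declared tail; adjacency is orthogonal-neighbor on grids, with
an optional channel adjacency matrix merged via connected components.
Participant-level tests permute by sign flips of paired differences
(vectorized: sign flips leave Σd² invariant), trial-level tests by label
exchange. p-values use the (1 + #{null ≥ obs}) / (n_perm + 1) convention. The
two-step sliding-window procedure runs one-tailed cluster tests in every
300 ms window, collects bins of significant clusters, and tests the union as
a unified cluster; its null replays the entire two-step selection on each
permutation (each permutation forms its own step-1 union before the maximal
mass is taken), which removes the selection bias a naive fixed-union null
would have — without this, the false-positive rate under the null is ~60%
rather than 5%. The modulator-shuffling cluster-size correction thresholds at
|z| > 2.57 and uses the smallest cluster size whose null exceedance is ≤ 5%
(a plain 95th percentile is degenerate when null sizes tie at small
integers). Robust correlation is the skipped-Pearson convention: project all
points onto directions through the coordinatewise median, flag by the
1.5-IQR boxplot rule, correlate the remainder. Median splits assign ties to
the lower set.

**Granger causality.** Multitaper CSD on the 1 s post-N2 window (450-1450
ms) with ±2 Hz DPSS smoothing, per-condition ERP removed first. Wilson's
minimum-phase factorization iterates ψ ← ψ·[ψ⁻¹Sψ⁻* + I]₊ with the
zero-lag term halved and restricted to its upper triangle (the uniqueness
gauge), after extending the CSD two-sidedly with S(-f) = S(f)ᵀ; a tiny
diagonal loading (1e-10 x mean trace) guards degenerate frequencies, and the
relative reconstruction error is always reported. Geweke spectra follow
F(i→j) = ln(Sjj / (Sjj - (Σii - Σji²/Σjj)|Hji|²)) per ordered pair on
pairwise factorizations. Group inference is participant-level (per-
participant spectra first, cluster test over frequency second). A directed
effect is accepted only when the forward-vs-backward cluster test is
significant AND the time-reversed dominance flips sign with magnitude at
least a quarter of the forward dominance — beamformer leakage between ROIs
with different transient content produces dominance that survives a bare
sign check but not this flip-consistency requirement.

**EEG-informed fMRI.** Condition onset regressors plus per-condition
parametric modulators (mean-centered per condition and run, hence orthogonal
to their own onset column); artifact / unlearned / |z| > 3 SD trials move to
a no-interest regressor; motion and linear drift are nuisance columns. Runs
are fit separately by OLS without prewhitening (the generator's AR(1) is
mild; a documented divergence knob), contrasts averaged across runs, group
inference by one-sample and paired t tests. "Suppression-specific coupling"
means: significantly negative in No-Think with no significant negative
coupling in Think (an incidental positive Think coupling does not count
against specificity).

**Behavior.** Accuracy is conditionalized on learning; SIF = Baseline -
No-Think accuracy averaged over SP and IP (the standard TNT definition);
z-SIF standardizes within counterbalancing group; the condition x test
comparison is a two-way repeated-measures ANOVA plus paired t contrasts. The
forgetter split is a median split on SIF with the median in the low group.

## Validation design and problem sizes

* **Type-I error** (`validation.type1_*`): ≥300 null simulations per
  procedure at 12 units, 500 permutations (100 for the modulator
  correction), asserting the empirical rate lies in [0.03, 0.08]. The
  modulator null uses spatially smoothed noise, matching preprocessed BOLD;
  on unsmoothed noise the discrete cluster-size threshold is conservative.
* **Oracles**: exhaustive 2⁵ sign-flip enumeration vs Monte-Carlo (gap ≤
  0.02); closed-form FDR step-up (exact); noiseless GLM betas (≤1% relative
  error); analytic VAR(1) CSD factorization (residual ≤ 1e-3, innovation
  covariance ≤ 5%).
* **Parameter recovery**: seeds 1-5 of the reduced configuration; each of
  the seven effect arms must be detected in ≥80% of seeds.
* **Mechanical contracts**: unit gain ≤ 1e-6, exact single-source
  localization, exact zero-mean baselines, multiset-preserving shuffles,
  bit-exact round trips, seed determinism.
* **Time reversal**: a unidirectional VAR flips dominance; a shared signal
  observed at two SNRs (causally silent) does not.

## What the generator does not emulate

Scanner gradient/ballistocardiogram artifacts, ocular/muscular components,
realistic head geometry and leadfields, volume conduction beyond the random
smooth topographies, fMRI spatial preprocessing, physiological noise
structure beyond AR(1)+drift, intrusion reports, and item-level semantics.
Passing tests therefore demonstrate that the *analysis chain* is correct,
calibrated, and able to recover this effect structure at realistic
single-trial SNR — not that the underlying neuroscience would replicate in
new human data.

## Known limitations

* Beamformer cross-talk between ROIs is the dominant nuisance for GC; the
  flip-consistency control rejects it but also costs sensitivity when true
  couplings are weak.
* The conflict stratum is recovered by a median split on a noisy single-trial
  measure; with the dead-zone gating this is reliable, but a generator
  configured with graded (no-dead-zone) coupling will show weak directed
  influence in the low stratum — that is a property of median splits, not a
  pipeline defect.
* The repeated-measures ANOVA requires complete cells; empty cells are
  reported as missing, never imputed.
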