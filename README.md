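# tntfusion

Analysis pipeline for simultaneous EEG-fMRI studies of memory suppression in
the think/no-think (TNT) paradigm, validated end-to-end on a synthetic
generator with known ground truth.

In the TNT task, participants see cue words and either recall the associated
word (Think) or suppress its retrieval (No-Think); a final memory test
measures suppression-induced forgetting (SIF), the below-baseline recall of
suppressed items. The pipeline implements the full analysis chain linking
inhibitory-control electrophysiology to hemodynamics and behavior:

* **ERP** — pooled frontocentral (Fz/FC1/FC2) evoked responses and
  single-trial suppression-N2 extraction (latency from the 8 Hz low-passed
  minimum inside a P2-P3 search window; amplitude from the 0.5-30 Hz signal).
* **Spectral** — Morlet time-frequency power on a 1 Hz x 50 ms grid with the
  single-trial z-baseline (z over trials and time per channel x frequency,
  trial average, baseline subtraction).
* **Inverse** — LCMV beamformer with the unit-gain constraint
  `W = (LᵀC⁻¹L)⁻¹LᵀC⁻¹`, regularized at 0.001% of the largest covariance
  eigenvalue, epoch-average subtraction for evoked contrasts, and
  principal-orientation collapse of dipole momentum.
* **Stats** — cluster-mass and max-statistic permutation tests, the two-step
  sliding-window cluster procedure, Benjamini-Hochberg FDR, skipped (robust)
  Pearson correlation, correlation-difference contrasts, median splits.
* **Connectivity** — nonparametric spectral Granger causality: multitaper
  cross-spectra (450-1450 ms, ±2 Hz smoothing, ERP removed), Wilson
  minimum-phase factorization `S(f) = H(f) Σ H(f)*`, Geweke spectra
  `F(i→j) = ln(Sjj/(Sjj − (Σii − Σji²/Σjj)|Hji|²))`, and the time-reversal
  control for spurious (SNR-driven) directionality.
* **Fusion** — EEG-informed fMRI: single-trial parametric modulators in
  run-wise GLMs with the canonical double-gamma HRF, ±3 SD trial exclusion,
  and modulator-shuffling cluster-size correction.
* **Behavior** — conditionalized recall, SIF and z-SIF (standardized within
  counterbalancing group), condition x test-type repeated-measures ANOVA.
* **Synth** — the ground-truth generator: seeded multi-participant datasets
  (EEG epochs, gain matrices, ROI BOLD, recall tables) carrying every
  hypothesized effect with recorded per-trial latents.

Because raw recordings of this kind are not publicly deposited, validation is
property-based: the generator injects each effect at configurable strength
and the test suite verifies that each pipeline arm recovers it, that null
configurations stay null at nominal error rates, and that analytic oracles
(enumeration, closed forms, VAR spectra) agree.

## Worked example

```python
import numpy as np
from tntfusion import synth, pipeline

cfg = synth.reduced_config(seed=1)          # 12 participants, 40 trials/cond
parts = synth.simulate_dataset(cfg)
summary = pipeline.analyze_dataset(parts, n_perm=500, seed=101)

print(pipeline.recovery_flags(summary))
print("N2 effect: %.2f µV (t=%.2f, p=%.4f)" % (
    summary["n2"]["mean_uv"], summary["n2"]["t"], summary["n2"]["p"]))
print("theta cluster min p:", summary["theta_cluster"]["min_p"])
print("N2 vs z-SIF rho: %.2f" % summary["sif"]["rho"])
```

prints (seed 1):

```
{'theta_cluster': True, 'n2': True, 'coupling': True, 'gc_dacc_rdlpfc': True, 'gc_rdlpfc_hipp': True, 'hipp_theta_split': True, 'sif': True}
N2 effect: 0.62 µV (t=4.89, p=0.0005)
theta cluster min p: 0.003992015968063872
N2 vs z-SIF rho: 0.43
```

meaning: the No-Think>Think frontal theta cluster, the suppression N2, the
negative No-Think-specific EEG-BOLD couplings, both directed GC effects
(dACC→rDLPFC in the high-conflict stratum, rDLPFC→hippocampus in low beta),
the hippocampal theta reduction on large-N2 trials, and the positive N2/z-SIF
correlation were all detected on this simulated study.

The numbered drivers under `analysis/` run the same stages as standalone
scripts (`01_simulate_dataset.py` … `06_behavior.py`) and write their tables
under `results/`.

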