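"""Synthetic multi-participant EEG-fMRI datasets with known ground truth.

The generator emulates a think/no-think (TNT) retrieval-suppression study:
cue-locked EEG epochs, a sensor-by-source gain matrix, ROI BOLD runs and
final-test recall, with every hypothesized effect injected at configurable
strength and its per-trial latent values recorded for parameter-recovery
tests.

Injected structure, per No-Think learned trial:

* an "early control" latent ``e`` (the trial's proactive-control strength)
  drives both the depth of the frontocentral N2 deflection generated in dACC
  (300-450 ms) and the amplitude of the dACC theta burst (5 Hz, 250-800 ms);
* a "conflict" latent ``k``, anticorrelated with ``e``, scales a delayed
  negative dACC delta/theta deflection (548-708 ms) and gates the lagged
  dACC -> rDLPFC theta/alpha coupling;
* hippocampal retrieval theta in 650-1850 ms decreases with ``e`` (stronger
  early control, stronger later hippocampal downregulation), while Think
  trials keep sustained retrieval theta;
* a lagged rDLPFC -> hippocampus low-beta coupling is active during No-Think;
* ROI BOLD couples negatively to ``e`` in dACC/rDLPFC/hippocampus during
  No-Think only, and positively to the hippocampal theta latent everywhere;
* per-participant suppression-induced forgetting grows with the participant's
  mean control strength, yielding the N2-effect/SIF correlation.

All randomness is routed through ``numpy.random.Generator`` streams derived
from ``(config.seed, participant_index)``, so identical configs reproduce
identical datasets bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .containers import EpochedEEG, GainMatrix, THINK, NOTHINK, PERCEPTUAL
from .fusion import hrf_convolve_sticks

# approximate 10-20 layout (2-D schematic positions, head radius 1)
CHANNELS_32: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95), "F7": (-0.81, 0.59),
    "F3": (-0.45, 0.55), "Fz": (0.0, 0.52), "F4": (0.45, 0.55),
    "F8": (0.81, 0.59), "FC5": (-0.69, 0.28), "FC1": (-0.23, 0.26),
    "FC2": (0.23, 0.26), "FC6": (0.69, 0.28), "T7": (-1.0, 0.0),
    "C3": (-0.52, 0.0), "Cz": (0.0, 0.0), "C4": (0.52, 0.0),
    "T8": (1.0, 0.0), "TP9": (-1.05, -0.36), "CP5": (-0.69, -0.28),
    "CP1": (-0.23, -0.26), "CP2": (0.23, -0.26), "CP6": (0.69, -0.28),
    "TP10": (1.05, -0.36), "P7": (-0.81, -0.59), "P3": (-0.45, -0.55),
    "Pz": (0.0, -0.52), "P4": (0.45, -0.55), "P8": (0.81, -0.59),
    "PO9": (-0.55, -0.85), "O1": (-0.31, -0.95), "Oz": (0.0, -0.98),
    "O2": (0.31, -0.95), "PO10": (0.55, -0.85),
}

ROI_NAMES = ("dACC", "rDLPFC", "hipp")


@dataclass
class ThetaBurst:
    band_hz: tuple[float, float] = (4.0, 8.0)
    center_hz: float = 5.0
    window_ms: tuple[float, float] = (250.0, 800.0)
    amp_think: float = 1.2
    amp_nothink: float = 3.0
    trial_sd: float = 0.35  # SD of the early-control latent


@dataclass
class N2Template:
    latency_ms: float = 340.0
    latency_jitter_ms: float = 12.0
    width_ms: float = 45.0  # Gaussian sigma
    amp_think: float = 3.0
    amp_nothink: float = 6.0
    control_gain: float = 4.5  # extra depth per unit early-control latent


@dataclass
class LateEvoked:
    window_ms: tuple[float, float] = (548.0, 708.0)
    width_ms: float = 70.0
    amp_per_conflict: float = 6.5


@dataclass
class HippTheta:
    band_hz: tuple[float, float] = (2.0, 8.0)
    center_hz: float = 5.0
    retrieval_amp: float = 2.6
    retrieval_window_ms: tuple[float, float] = (300.0, 2500.0)
    suppression_window_ms: tuple[float, float] = (650.0, 1850.0)
    suppression_slope: float = 0.7   # fractional reduction per unit latent


@dataclass
class MVARCoupling:
    dacc_to_rdlpfc: float = 3.0   # theta/alpha channel, conflict-gated
    rdlpfc_to_hipp: float = 1.0   # low-beta channel, No-Think gate
    lag_ms: float = 20.0
    osc_radius: float = 0.92
    dacc_osc_hz: float = 6.0
    rdlpfc_osc_hz: float = 9.0
    rdlpfc_beta_hz: float = 15.0
    hipp_osc_hz: float = 5.0
    osc_amp: float = 1.0


@dataclass
class BoldCoupling:
    # condition mean neural amplitudes (arbitrary units)
    mean_amp: dict = field(default_factory=lambda: {
        "dACC": {THINK: 1.0, NOTHINK: 1.8, PERCEPTUAL: 0.6},
        "rDLPFC": {THINK: 1.0, NOTHINK: 1.7, PERCEPTUAL: 0.6},
        "hipp": {THINK: 1.6, NOTHINK: 0.9, PERCEPTUAL: 0.8},
    })
    # signed couplings to the centered early-control latent, No-Think only
    beta_control: dict = field(default_factory=lambda: {
        "dACC": -1.8, "rDLPFC": -1.8, "hipp": -1.5,
    })
    # positive coupling of hippocampal BOLD to the hippocampal theta latent
    beta_hipp_theta: float = 1.5


@dataclass
class SIFLink:
    base_forgetting: float = 0.12  # mean Baseline-minus-No-Think recall drop
    slope: float = 0.45            # extra forgetting per unit control factor
    recall_sp: float = 0.82        # Baseline same-probe recall probability
    recall_ip: float = 0.62        # Baseline independent-probe recall
    group_sd: float = 0.06         # item-memorability SD across groups


@dataclass
class NoiseConfig:
    sensor_sd: float = 0.8        # white sensor noise, µV
    background_amp: float = 0.4   # per background source
    bold_sd: float = 0.85
    bold_ar1: float = 0.3
    drift_amp: float = 0.5
    artifact_rate: float = 0.02


@dataclass
class GroundTruthConfig:
    """Full parameterization of one synthetic study."""

    n_participants: int = 24
    n_items: tuple[int, int, int] = (16, 16, 8)   # Think / No-Think / Perceptual
    n_baseline_items: int = 16
    n_repetitions: int = 12
    learned_prob: tuple[float, float] = (0.745, 0.795)  # Think / No-Think items
    baseline_learned_prob: float = 0.77
    sfreq: float = 250.0
    epoch_window_ms: tuple[float, float] = (-500.0, 3000.0)
    n_runs: int = 6
    volumes_per_run: int = 290
    tr: float = 1.5
    n_sources: int = 48
    n_counterbalancing_groups: int = 4
    participant_factor_sd: float = 0.3
    conflict_anticorr: float = -0.4
    theta_burst: ThetaBurst = field(default_factory=ThetaBurst)
    n2_template: N2Template = field(default_factory=N2Template)
    late_evoked: LateEvoked = field(default_factory=LateEvoked)
    hipp_theta: HippTheta = field(default_factory=HippTheta)
    mvar: MVARCoupling = field(default_factory=MVARCoupling)
    bold: BoldCoupling = field(default_factory=BoldCoupling)
    sif: SIFLink = field(default_factory=SIFLink)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lo, hi = self.epoch_window_ms
        nyq = self.sfreq / 2
        if min(self.n_items) <= 0 or self.n_repetitions <= 0:
            raise ValueError("counts must be positive")
        for w in (self.theta_burst.window_ms, self.late_evoked.window_ms,
                  self.hipp_theta.suppression_window_ms):
            if w[0] < lo or w[1] > hi:
                raise ValueError(f"window {w} exceeds epoch {self.epoch_window_ms}")
        for b in (self.theta_burst.band_hz, self.hipp_theta.band_hz):
            if not (0 < b[0] < b[1] < nyq):
                raise ValueError(f"band {b} outside (0, Nyquist)")
        if self.run_duration_s <= 0:
            raise ValueError("invalid run geometry")

    @property
    def run_duration_s(self) -> float:
        return self.tr * self.volumes_per_run

    @property
    def n_trials(self) -> tuple[int, int, int]:
        r = self.n_repetitions
        return tuple(n * r for n in self.n_items)

    @property
    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.sfreq
        lo, hi = self.epoch_window_ms
        return np.arange(lo, hi + dt / 2, dt)

    def null_effects(self) -> "GroundTruthConfig":
        """Copy with every condition difference and coupling removed."""
        import copy

        c = copy.deepcopy(self)
        c.theta_burst.amp_nothink = c.theta_burst.amp_think
        c.n2_template.amp_nothink = c.n2_template.amp_think
        c.n2_template.control_gain = 0.0
        c.late_evoked.amp_per_conflict = 0.0
        c.hipp_theta.suppression_slope = 0.0
        c.mvar.dacc_to_rdlpfc = 0.0
        c.mvar.rdlpfc_to_hipp = 0.0
        for roi in c.bold.beta_control:
            c.bold.beta_control[roi] = 0.0
        c.bold.beta_hipp_theta = 0.0
        for roi in c.bold.mean_amp:
            v = np.mean(list(c.bold.mean_amp[roi].values()))
            c.bold.mean_amp[roi] = {k: float(v) for k in c.bold.mean_amp[roi]}
        c.sif.base_forgetting = 0.0
        c.sif.slope = 0.0
        return c


def reduced_config(seed: int = 0, n_participants: int = 12,
                   **overrides) -> GroundTruthConfig:
    """Parameter-recovery scale: ~40 Think/No-Think trials per participant."""
    cfg = GroundTruthConfig(
        n_participants=n_participants,
        n_items=(8, 8, 4),
        n_baseline_items=8,
        n_repetitions=5,
        learned_prob=(1.0, 1.0),
        n_runs=3,
        volumes_per_run=140,
        n_sources=30,
        seed=seed,
        **overrides,
    )
    return cfg


def _stream_rng(config, participant, stream_id: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, participant, stream_id])
    )


# stream ids (stable across sessions, unlike hash())
_S_EVENTS, _S_LATENT, _S_SOURCE, _S_GAIN, _S_SENSOR, _S_BOLD, _S_BEHAV, _S_ART = range(8)


# ---------------------------------------------------------------------------
# events and latents
# ---------------------------------------------------------------------------

def simulate_events(config: GroundTruthConfig, participant: int) -> pd.DataFrame:
    """Trial table: item/condition schedule over runs with onsets.

    Items repeat ``n_repetitions`` times; repetitions are split evenly over
    runs and shuffled within run. Learned flags are drawn per item.
    """
    rng = _stream_rng(config, participant, _S_EVENTS)
    conds = (THINK, NOTHINK, PERCEPTUAL)
    items = []
    for ci, (cond, n) in enumerate(zip(conds, config.n_items)):
        for i in range(n):
            if cond == PERCEPTUAL:
                learned = True
            else:
                learned = bool(rng.random() < config.learned_prob[ci])
            items.append((cond, f"{cond[:2]}{i:02d}", learned))
    reps_per_run = config.n_repetitions / config.n_runs
    rows = []
    for run in range(config.n_runs):
        k0 = int(round(run * reps_per_run))
        k1 = int(round((run + 1) * reps_per_run))
        run_trials = [(c, it, lr) for (c, it, lr) in items
                      for _ in range(k1 - k0)]
        order = rng.permutation(len(run_trials))
        n_tr = len(run_trials)
        if n_tr == 0:
            continue
        # trial onsets: cue 3 s + blank 1.5 s + jittered fixation
        span = config.run_duration_s - 12.0
        spacing = span / n_tr
        if spacing < 4.6:
            raise ValueError("run too short for the trial count")
        base = 2.0 + spacing * np.arange(n_tr)
        jit = rng.uniform(0.0, min(spacing - 4.5, 0.7), size=n_tr)
        for t_i, oi in enumerate(order):
            c, it, lr = run_trials[oi]
            rows.append({
                "run": run, "onset_s": base[t_i] + jit[t_i], "condition": c,
                "item": it, "learned": lr, "block": run,
            })
    ev = pd.DataFrame(rows)
    art = _stream_rng(config, participant, _S_ART)
    ev["artifact"] = art.random(len(ev)) < config.noise.artifact_rate
    return ev


def simulate_latents(config: GroundTruthConfig, participant: int,
                     events: pd.DataFrame) -> dict:
    """Per-participant control factor and per-trial latents."""
    rng = _stream_rng(config, participant, _S_LATENT)
    g = 1.0 + config.participant_factor_sd * rng.standard_normal()
    g = max(g, 0.2)
    n = len(events)
    cond = events["condition"].to_numpy()
    e = np.zeros(n)
    k = np.zeros(n)
    tb = config.theta_burst
    nt = cond == NOTHINK
    th = cond == THINK
    z_e = rng.standard_normal(n)
    rho = config.conflict_anticorr
    z_k = rho * z_e + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    # early-control latent: mean scales with the participant factor (No-Think)
    e[nt] = np.maximum(g + tb.trial_sd * z_e[nt], 0.05)
    e[th] = np.maximum(0.45 + tb.trial_sd * 0.6 * z_e[th], 0.05)
    # conflict latent, No-Think only
    k[nt] = np.maximum(1.0 + 0.5 * z_k[nt], 0.0)
    n2 = config.n2_template
    n2amp = np.zeros(n)
    n2amp[th] = n2.amp_think
    n2amp[nt] = n2.amp_nothink + n2.control_gain * (e[nt] - 1.0)
    n2amp = np.maximum(n2amp, 0.0)
    lat = n2.latency_ms + n2.latency_jitter_ms * rng.standard_normal(n)
    lat = np.clip(lat, 305.0, 390.0)
    ht = config.hipp_theta
    hipp_env = np.zeros(n)
    hipp_env[th] = 1.0
    hipp_env[nt] = np.maximum(1.0 - ht.suppression_slope * (e[nt] - 0.4), 0.05)
    hipp_env[cond == PERCEPTUAL] = 0.35
    return {
        "participant_factor": g,
        "early_control": e,
        "conflict": k,
        "n2_amp": n2amp,
        "n2_latency_ms": lat,
        "hipp_env": hipp_env,
    }


# ---------------------------------------------------------------------------
# source signals
# ---------------------------------------------------------------------------

def _ar2_coeffs(f0: float, radius: float, sfreq: float) -> np.ndarray:
    w = 2 * np.pi * f0 / sfreq
    return np.array([1.0, -2 * radius * np.cos(w), radius**2])


def _gauss(t_ms: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - mu) / sigma) ** 2)


def _window_env(t_ms: np.ndarray, lo: float, hi: float, ramp: float = 100.0) -> np.ndarray:
    """Smooth plateau envelope over [lo, hi] with cosine ramps."""
    env = np.zeros_like(t_ms)
    core = (t_ms >= lo) & (t_ms <= hi)
    env[core] = 1.0
    up = (t_ms > lo - ramp) & (t_ms < lo)
    env[up] = 0.5 * (1 + np.cos(np.pi * (lo - t_ms[up]) / ramp))
    dn = (t_ms > hi) & (t_ms < hi + ramp)
    env[dn] = 0.5 * (1 + np.cos(np.pi * (t_ms[dn] - hi) / ramp))
    return env


def simulate_sources(
    config: GroundTruthConfig, participant: int,
    events: pd.DataFrame | None = None, latents: dict | None = None,
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Per-trial source momentum for the full grid.

    Returns ``(sources, events, truth)`` with ``sources`` of shape
    (trials, n_sources, 3, samples). Sources 0-8 are the ROI members (three
    per ROI in the order dACC, rDLPFC, hippocampus); the rest carry smooth
    background noise. Each ROI's signal lives mostly on one dominant
    orientation.
    """
    if events is None:
        events = simulate_events(config, participant)
    if latents is None:
        latents = simulate_latents(config, participant, events)
    rng = _stream_rng(config, participant, _S_SOURCE)
    t = config.times_ms
    n_samp = t.size
    n = len(events)
    cond = events["condition"].to_numpy()
    nt = cond == NOTHINK
    sf = config.sfreq
    mv = config.mvar
    lag = max(int(round(mv.lag_ms / 1000.0 * sf)), 1)

    def ar2(f0, size):
        eps = rng.standard_normal(size)
        return lfilter([1.0], _ar2_coeffs(f0, mv.osc_radius, sf), eps, axis=-1)

    def ar2_sd(f0):
        # stationary SD of the resonator for unit white input
        imp = np.zeros(4096)
        imp[0] = 1.0
        h = lfilter([1.0], _ar2_coeffs(f0, mv.osc_radius, sf), imp)
        return float(np.sqrt(np.sum(h**2)))

    # oscillatory (stochastic) components carrying the directed couplings;
    # each resonator is normalized to unit stationary SD, then scaled by
    # osc_amp. Couplings inject the (unit-SD) driver into the receiver's
    # innovations with the configured strength and lag; conflict gating is
    # binary (active stratum = trials whose conflict latent exceeds its
    # population median of 1), so the directed link exists only in that
    # stratum.
    x_dacc = ar2(mv.dacc_osc_hz, (n, n_samp)) / ar2_sd(mv.dacc_osc_hz)
    eps_r = rng.standard_normal((n, n_samp))
    # coupling strength grows with conflict above the population median, so
    # the lower stratum carries essentially no directed influence even when a
    # noisy conflict measure misclassifies trials near the threshold
    gate1 = mv.dacc_to_rdlpfc * np.where(
        nt, np.maximum(latents["conflict"] - 1.25, 0.0), 0.0)
    drive1 = np.zeros_like(x_dacc)
    drive1[:, lag:] = x_dacc[:, :-lag]
    x_r_theta = lfilter(
        [1.0], _ar2_coeffs(mv.rdlpfc_osc_hz, mv.osc_radius, sf),
        eps_r + gate1[:, None] * drive1,
        axis=-1,
    ) / ar2_sd(mv.rdlpfc_osc_hz)
    x_r_beta = ar2(mv.rdlpfc_beta_hz, (n, n_samp)) / ar2_sd(mv.rdlpfc_beta_hz)
    gate2 = np.where(nt, mv.rdlpfc_to_hipp, 0.0)
    drive2 = np.zeros_like(x_r_beta)
    drive2[:, lag:] = x_r_beta[:, :-lag]
    eps_h = rng.standard_normal((n, n_samp))
    x_hipp_osc = lfilter(
        [1.0], _ar2_coeffs(mv.hipp_osc_hz, mv.osc_radius, sf),
        eps_h + gate2[:, None] * drive2,
        axis=-1,
    ) / ar2_sd(mv.hipp_osc_hz)
    x_dacc = x_dacc * mv.osc_amp
    x_r_theta = x_r_theta * mv.osc_amp
    x_r_beta = x_r_beta * mv.osc_amp
    x_hipp_osc = x_hipp_osc * mv.osc_amp

    # deterministic evoked parts
    tb = config.theta_burst
    n2 = config.n2_template
    le = config.late_evoked
    ht = config.hipp_theta
    burst_env = _window_env(t, *tb.window_ms)
    phase = rng.uniform(0, 2 * np.pi, size=n)
    burst = np.sin(2 * np.pi * tb.center_hz * (t / 1000.0)[None, :]
                   + phase[:, None]) * burst_env[None, :]
    burst_amp = np.where(nt, latents["early_control"] * tb.amp_nothink, 0.0)
    burst_amp = np.where(cond == THINK,
                         latents["early_control"] * tb.amp_think, burst_amp)
    n2_wave = -latents["n2_amp"][:, None] * np.exp(
        -0.5 * ((t[None, :] - latents["n2_latency_ms"][:, None]) / n2.width_ms) ** 2
    )
    late_mid = 0.5 * (le.window_ms[0] + le.window_ms[1])
    late_wave = -(le.amp_per_conflict * latents["conflict"] * nt)[:, None] \
        * _gauss(t[None, :], late_mid, le.width_ms)
    # rDLPFC shows its own delayed evoked deflection (504-640 ms) scaled by
    # the same conflict latent
    late_wave_r = -(0.6 * le.amp_per_conflict * latents["conflict"] * nt)[:, None] \
        * _gauss(t[None, :], 572.0, le.width_ms)

    dacc_sig = n2_wave + burst_amp[:, None] * burst + late_wave + 2.0 * x_dacc
    rdlpfc_sig = 2.2 * (x_r_theta + x_r_beta) + late_wave_r
    hipp_early = _window_env(t, ht.retrieval_window_ms[0],
                             ht.suppression_window_ms[0])
    hipp_late = _window_env(t, ht.suppression_window_ms[0],
                            ht.retrieval_window_ms[1])
    hipp_env_t = (
        np.where(cond == THINK, 1.0, np.where(nt, 0.9, 0.35))[:, None]
        * hipp_early[None, :]
        + latents["hipp_env"][:, None] * hipp_late[None, :]
    )
    hipp_sig = (ht.retrieval_amp * hipp_env_t + 0.35) * x_hipp_osc

    # assemble grid: ROI members share their signal with graded strength,
    # on a dominant orientation; background sources carry smooth noise
    n_src = config.n_sources
    sources = np.zeros((n, n_src, 3, n_samp))
    bg = rng.standard_normal((n, n_src - 9, 3, n_samp))
    bg = lfilter([1.0], [1.0, -0.7], bg, axis=-1) * config.noise.background_amp * 0.7
    sources[:, 9:] = bg
    roi_orients = {
        "dACC": np.array([0.9, 0.33, 0.28]),
        "rDLPFC": np.array([0.3, 0.9, 0.32]),
        "hipp": np.array([0.3, 0.28, 0.92]),
    }
    # one active source per ROI (the centroid); the other two members are
    # silent neighbors, so ROI averaging attenuates but never cancels the
    # signal (coherent copies at several grid points would be suppressed by
    # the beamformer as correlated sources)
    signals = {"dACC": dacc_sig, "rDLPFC": rdlpfc_sig, "hipp": hipp_sig}
    for r_i, roi in enumerate(ROI_NAMES):
        u = roi_orients[roi] / np.linalg.norm(roi_orients[roi])
        for m_i in range(3):
            s_idx = 3 * r_i + m_i
            if m_i == 0:
                sources[:, s_idx] = signals[roi][:, None, :] * u[:, None]
            # small independent activity on all orientations
            extra = rng.standard_normal((n, 3, n_samp)) * 0.15
            sources[:, s_idx] += extra

    truth = dict(latents)
    truth["roi_members"] = {roi: list(range(3 * i, 3 * i + 3))
                            for i, roi in enumerate(ROI_NAMES)}
    truth["roi_orientations"] = roi_orients
    truth["gates"] = {"dacc_to_rdlpfc": gate1, "rdlpfc_to_hipp": gate2}
    truth["signals"] = signals
    return sources, events, truth


# ---------------------------------------------------------------------------
# forward model and sensors
# ---------------------------------------------------------------------------

def make_gain(config: GroundTruthConfig, participant: int) -> GainMatrix:
    """Seeded smooth random topographies: gain columns are draws from a
    spatial Gaussian-process over the sensor layout, unit-norm per column.
    The dACC dominant-orientation column is sign-aligned to be positive over
    the frontocentral sensors (sensor-space N2 polarity convention)."""
    rng = _stream_rng(config, participant, _S_GAIN)
    names = list(CHANNELS_32)
    pos = np.array([CHANNELS_32[c] for c in names])
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    K = np.exp(-d2 / (2 * 0.35**2)) + 1e-6 * np.eye(len(names))
    L = np.linalg.cholesky(K)
    n_col = config.n_sources * 3
    cols = L @ rng.standard_normal((len(names), n_col))
    cols /= np.linalg.norm(cols, axis=0, keepdims=True)
    # ROI centroids get a characteristic topography on their dominant
    # orientation (frontocentral for dACC, right-frontal for rDLPFC,
    # left-temporal for the hippocampus), blended with the random component:
    # the N2/frontal-midline-theta effects must actually reach the pooled
    # frontocentral channel, as they do in vivo
    blob_centers = {"dACC": (0.0, 0.38), "rDLPFC": (0.78, 0.45),
                    "hipp": (-0.9, -0.42)}
    orients = {"dACC": np.array([0.9, 0.33, 0.28]),
               "rDLPFC": np.array([0.3, 0.9, 0.32]),
               "hipp": np.array([0.3, 0.28, 0.92])}
    for r_i, roi in enumerate(ROI_NAMES):
        s = 3 * r_i  # centroid source of the ROI
        u = orients[roi] / np.linalg.norm(orients[roi])
        c = np.array(blob_centers[roi])
        tmpl = np.exp(-np.sum((pos - c) ** 2, axis=1) / (2 * 0.28**2))
        tmpl /= np.linalg.norm(tmpl)
        B = cols[:, 3 * s: 3 * s + 3]
        mix = 0.85 * tmpl + 0.35 * (B @ u)
        B += np.outer(mix - B @ u, u)
    gain = GainMatrix(matrix=cols, positions=_source_grid(config),
                      ch_names=names)
    # polarity convention: frontocentral positivity for the dACC sources
    fc = [names.index(c) for c in ("Fz", "FC1", "FC2")]
    orients = {"dACC": np.array([0.9, 0.33, 0.28]),
               "rDLPFC": np.array([0.3, 0.9, 0.32]),
               "hipp": np.array([0.3, 0.28, 0.92])}
    for r_i, roi in enumerate(ROI_NAMES):
        u = orients[roi] / np.linalg.norm(orients[roi])
        for m_i in range(3):
            s = 3 * r_i + m_i
            eff = gain.source_block(s) @ u
            if eff[fc].mean() < 0:
                gain.matrix[:, 3 * s: 3 * s + 3] *= -1
    return gain


def _source_grid(config: GroundTruthConfig) -> np.ndarray:
    """Regular-ish 3-D grid of source positions (meters)."""
    n = config.n_sources
    side = int(np.ceil(n ** (1 / 3)))
    pts = np.array(np.meshgrid(*[np.arange(side)] * 3,
                               indexing="ij")).reshape(3, -1).T[:n]
    return pts * 0.01  # 1 cm spacing


def project_to_sensors(
    sources: np.ndarray, gain: GainMatrix, sensor_noise_sd: float,
    events: pd.DataFrame, config: GroundTruthConfig,
    participant: int = 0,
) -> EpochedEEG:
    """Forward-project sources and add white sensor noise.

    ``sensor = gain @ sources + noise``; trial metadata is carried through.
    """
    if sensor_noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    n, n_src, n_or, n_samp = sources.shape
    if n_src * n_or != gain.matrix.shape[1]:
        raise ValueError("gain/source dimension mismatch")
    flat = sources.reshape(n, n_src * n_or, n_samp)
    data = np.einsum("cs,nst->nct", gain.matrix, flat)
    if sensor_noise_sd > 0:
        rng = _stream_rng(config, participant, _S_SENSOR)
        data = data + sensor_noise_sd * rng.standard_normal(data.shape)
    meta = events.copy().reset_index(drop=True)
    return EpochedEEG(data=data, sfreq=config.sfreq, times=config.times_ms,
                      ch_names=list(gain.ch_names), metadata=meta)


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def _ar1_noise(rng, shape, rho, sd):
    eps = rng.standard_normal(shape)
    return lfilter([1.0], [1.0, -rho], eps, axis=-1) * sd * np.sqrt(1 - rho**2)


def neural_amplitudes(config: GroundTruthConfig, events: pd.DataFrame,
                      latents: dict) -> dict[str, np.ndarray]:
    """Ground-truth per-trial neural amplitude per ROI (the BOLD model input)."""
    cond = events["condition"].to_numpy()
    nt = cond == NOTHINK
    amps = {}
    e_cent = latents["early_control"].copy()
    if nt.any():
        e_cent = e_cent - np.where(nt, e_cent[nt].mean(), 0.0)
    h_cent = latents["hipp_env"] - latents["hipp_env"].mean()
    for roi in ROI_NAMES:
        base = np.array([config.bold.mean_amp[roi][c] for c in cond])
        a = base + np.where(nt, config.bold.beta_control[roi] * e_cent, 0.0)
        if roi == "hipp":
            a = a + config.bold.beta_hipp_theta * h_cent
        amps[roi] = a
    return amps


def simulate_bold(
    config: GroundTruthConfig, participant: int, events: pd.DataFrame,
    latents: dict,
) -> tuple[np.ndarray, np.ndarray]:
    """ROI BOLD runs: (n_runs, volumes_per_run, n_rois) plus motion params.

    Neural amplitude per trial = condition mean + signed coupling x centered
    latent; stick trains are convolved with the canonical HRF, sampled at TR,
    with AR(1) noise and a random linear drift added.
    """
    rng = _stream_rng(config, participant, _S_BOLD)
    amps = neural_amplitudes(config, events, latents)
    n_vols, tr = config.volumes_per_run, config.tr
    bold = np.zeros((config.n_runs, n_vols, len(ROI_NAMES)))
    motion = 0.05 * np.cumsum(
        rng.standard_normal((config.n_runs, n_vols, 6)), axis=1
    )
    for run in range(config.n_runs):
        sel = (events["run"] == run).to_numpy()
        onsets = events.loc[sel, "onset_s"].to_numpy()
        if np.any(onsets >= config.run_duration_s):
            raise ValueError("onset outside run")
        for j, roi in enumerate(ROI_NAMES):
            sig = hrf_convolve_sticks(onsets, amps[roi][sel], n_vols, tr)
            noise = _ar1_noise(rng, n_vols, config.noise.bold_ar1,
                               config.noise.bold_sd)
            drift = config.noise.drift_amp * rng.standard_normal() \
                * np.linspace(-1, 1, n_vols)
            bold[run, :, j] = sig + noise + drift
    return bold, motion


def simulate_bold_grid(
    config: GroundTruthConfig, participant: int, events: pd.DataFrame,
    latents: dict, grid_shape: tuple[int, int, int] = (8, 8, 8),
    blob_size: int = 2,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Voxel-grid BOLD for the cluster-correction path.

    Each ROI's signal occupies a ``blob_size``-cube; all other voxels are
    noise. Returns (runs, n_vols, n_vox) data and per-ROI flat voxel indices.
    """
    rng = _stream_rng(config, participant, _S_BOLD + 100)
    amps = neural_amplitudes(config, events, latents)
    n_vox = int(np.prod(grid_shape))
    corners = {"dACC": (1, 1, 1), "rDLPFC": (5, 5, 1), "hipp": (3, 3, 5)}
    roi_vox: dict[str, np.ndarray] = {}
    for roi, c0 in corners.items():
        ii, jj, kk = np.meshgrid(*[np.arange(c, c + blob_size) for c in c0],
                                 indexing="ij")
        roi_vox[roi] = np.ravel_multi_index(
            (ii.ravel(), jj.ravel(), kk.ravel()), grid_shape
        )
    n_vols, tr = config.volumes_per_run, config.tr
    data = np.zeros((config.n_runs, n_vols, n_vox))
    for run in range(config.n_runs):
        sel = (events["run"] == run).to_numpy()
        onsets = events.loc[sel, "onset_s"].to_numpy()
        noise = _ar1_noise(rng, (n_vox, n_vols), config.noise.bold_ar1,
                           config.noise.bold_sd).T
        data[run] = noise
        for roi in ROI_NAMES:
            sig = hrf_convolve_sticks(onsets, amps[roi][sel], n_vols, tr)
            data[run][:, roi_vox[roi]] += sig[:, None]
    return data, roi_vox


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(
    config: GroundTruthConfig, participant: int, latents_factor: float,
) -> pd.DataFrame:
    """Final-test recall outcomes (item x condition x test type).

    No-Think recall drops below Baseline by ``base_forgetting`` plus
    ``slope x (participant control factor - 1)``; Think recall matches
    Baseline on the same probe. Item memorability varies by counterbalancing
    group, which the z-SIF correction removes.
    """
    if not np.isfinite(latents_factor):
        raise ValueError("participant factor must be finite")
    rng = _stream_rng(config, participant, _S_BEHAV)
    group = participant % config.n_counterbalancing_groups
    g_off = config.sif.group_sd * np.sin(
        2 * np.pi * group / config.n_counterbalancing_groups
    )
    forget = config.sif.base_forgetting + config.sif.slope * (latents_factor - 1.0)
    forget = float(np.clip(forget, 0.0, 0.6))
    rows = []
    spec_items = [
        (THINK, config.n_items[0], config.learned_prob[0], 0.0),
        (NOTHINK, config.n_items[1], config.learned_prob[1], -forget),
        ("Baseline", config.n_baseline_items, config.baseline_learned_prob, 0.0),
    ]
    for cond, n_items, lp, delta in spec_items:
        for i in range(n_items):
            learned = bool(rng.random() < lp)
            for test, pbase in (("SP", config.sif.recall_sp),
                                ("IP", config.sif.recall_ip)):
                p = np.clip(pbase + g_off + delta, 0.02, 0.98)
                recalled = bool(rng.random() < p) and learned
                rows.append({
                    "participant": participant, "item": f"{cond[:2]}{i:02d}",
                    "condition": cond, "test": test, "learned": learned,
                    "recalled": recalled, "group": group,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# participant / dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SimulatedParticipant:
    index: int
    tr: float
    epochs: EpochedEEG
    gain: GainMatrix
    bold_runs: np.ndarray          # (n_runs, n_vols, n_rois)
    motion: np.ndarray             # (n_runs, n_vols, 6)
    events: pd.DataFrame
    behavior: pd.DataFrame
    truth: dict
    roi_members: dict[str, list[int]]

    def __post_init__(self) -> None:
        if self.epochs.n_trials != len(self.events):
            raise ValueError("epochs/events trial mismatch")


def simulate_participant(config: GroundTruthConfig, participant: int,
                         keep_sources: bool = False) -> SimulatedParticipant:
    sources, events, truth = simulate_sources(config, participant)
    gain = make_gain(config, participant)
    epochs = project_to_sensors(sources, gain, config.noise.sensor_sd,
                                events, config, participant)
    latents = {k: truth[k] for k in
               ("participant_factor", "early_control", "conflict",
                "n2_amp", "n2_latency_ms", "hipp_env")}
    bold, motion = simulate_bold(config, participant, events, latents)
    behavior = simulate_behavior(config, participant,
                                 truth["participant_factor"])
    if not keep_sources:
        truth = {k: v for k, v in truth.items() if k != "signals"}
    roi_members = truth["roi_members"]
    return SimulatedParticipant(
        index=participant, tr=config.tr, epochs=epochs, gain=gain, bold_runs=bold,
        motion=motion, events=events, behavior=behavior, truth=truth,
        roi_members=roi_members,
    )


def simulate_dataset(config: GroundTruthConfig,
                     keep_sources: bool = False) -> list[SimulatedParticipant]:
    return [simulate_participant(config, p, keep_sources=keep_sources)
            for p in range(config.n_participants)]
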