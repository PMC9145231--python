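"""Evoked responses and single-trial N2 extraction.

The suppression N2 is a frontocentral negative deflection at roughly
300-450 ms after cue onset that is deeper on No-Think (suppression) than on
Think (retrieval) trials. Analyses run on a pooled frontocentral virtual
channel (unweighted mean of Fz, FC1, FC2). Single-trial N2 latencies are the
minimum of the 8 Hz low-passed pooled signal inside a participant-specific
search window bracketed by the flanking P2/P3 positivities of the
grand-average ERP; amplitudes are the mean of the 0.5-30 Hz signal in a
100 ms window centered on each latency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from mne.filter import create_filter
from scipy.signal import fftconvolve

from .containers import EpochedEEG

POOLED_FRONTOCENTRAL = ("Fz", "FC1", "FC2")


@dataclass
class SingleTrialN2:
    trial: int
    latency_ms: float
    amplitude_uv: float
    search_window_ms: tuple[float, float]
    valid: bool


def average_erp(
    epochs: EpochedEEG,
    condition: str | None = None,
    baseline_window_ms: tuple[float, float] = (-250.0, 0.0),
    learned_only: bool = True,
) -> np.ndarray:
    """Baseline-corrected trial-average evoked response (channels x samples).

    Averages non-artifact trials of ``condition`` (all conditions when None)
    and subtracts the per-channel mean over ``baseline_window_ms``.
    """
    mask = ~epochs.metadata["artifact"].to_numpy(dtype=bool)
    if condition is not None:
        mask &= (epochs.metadata["condition"] == condition).to_numpy()
    if learned_only and "learned" in epochs.metadata:
        mask &= epochs.metadata["learned"].to_numpy(dtype=bool)
    if not mask.any():
        raise ValueError(f"no usable trials for condition {condition!r}")
    evoked = epochs.data[mask].mean(axis=0)
    bmask = epochs.time_mask(baseline_window_ms)
    if not bmask.any():
        raise ValueError("baseline window outside epoch")
    return evoked - evoked[:, bmask].mean(axis=1, keepdims=True)


def pool_channels(data: np.ndarray, ch_names: list[str],
                  pool: tuple[str, ...] = POOLED_FRONTOCENTRAL) -> np.ndarray:
    """Unweighted mean over the named channels along the channel axis.

    ``data`` may be (channels, samples) or (trials, channels, samples).
    """
    missing = [n for n in pool if n not in ch_names]
    if missing:
        raise ValueError(f"unknown channels: {missing}")
    idx = [ch_names.index(n) for n in pool]
    axis = 0 if data.ndim == 2 else 1
    return np.take(data, idx, axis=axis).mean(axis=axis)


def zero_phase_fir(
    data: np.ndarray, sfreq: float, lo: float | None, hi: float | None
) -> np.ndarray:
    """Zero-phase FIR filtering along the last axis.

    Uses a Hamming-window (firwin) design from MNE; the signal is
    reflect-padded so that filters longer than one epoch (needed for 0.5 Hz
    band edges) remain applicable, then convolved with the symmetric taps,
    which is phase-free by construction.
    """
    taps = create_filter(
        None, sfreq, lo, hi, method="fir", fir_design="firwin",
        phase="zero", verbose=False,
    )
    pad = len(taps) // 2 + 1
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)],
                    mode="reflect")
    shape = [1] * (data.ndim - 1) + [len(taps)]
    out = fftconvolve(padded, taps.reshape(shape), mode="same", axes=-1)
    return out[..., pad:-pad]


def bandpass_filter_epochs(
    epochs: EpochedEEG, band_hz: tuple[float, float]
) -> EpochedEEG:
    """Zero-phase FIR (Hamming) band-pass copy of the epochs; metadata kept."""
    lo, hi = band_hz
    if not (0 < lo < hi < epochs.sfreq / 2):
        raise ValueError(f"band {band_hz} invalid for sfreq {epochs.sfreq}")
    return replace(epochs, data=zero_phase_fir(epochs.data, epochs.sfreq, lo, hi))


def find_search_window(
    group_erp_pooled: np.ndarray,
    times_ms: np.ndarray,
    peak_range_ms: tuple[float, float] = (150.0, 600.0),
    fallback_ms: tuple[float, float] = (250.0, 500.0),
) -> tuple[float, float]:
    """Participant N2 search window from the grand-average pooled ERP.

    The window runs from the pre-N2 positive peak (P2) to the post-N2 positive
    peak (P3): within ``peak_range_ms``, locate the deepest local minimum and
    take the flanking local maxima. Falls back to ``fallback_ms`` when the
    bracketing positivities cannot be identified.
    """
    sel = (times_ms >= peak_range_ms[0]) & (times_ms <= peak_range_ms[1])
    x = group_erp_pooled[sel]
    t = times_ms[sel]
    interior = np.arange(1, x.size - 1)
    mins = interior[(x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:])]
    maxs = interior[(x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])]
    if mins.size == 0 or maxs.size == 0:
        return fallback_ms
    n2 = mins[np.argmin(x[mins])]
    before = maxs[maxs < n2]
    after = maxs[maxs > n2]
    if before.size == 0 or after.size == 0:
        return fallback_ms
    p2 = before[np.argmax(x[before])]
    p3 = after[np.argmax(x[after])]
    return float(t[p2]), float(t[p3])


def extract_single_trial_n2(
    epochs: EpochedEEG,
    search_window_ms: tuple[float, float],
    pool: tuple[str, ...] = POOLED_FRONTOCENTRAL,
    amp_halfwidth_ms: float = 50.0,
) -> list[SingleTrialN2]:
    """Per-trial N2 latency and amplitude on the pooled frontocentral channel.

    Latency: interior minimum of the 8 Hz low-passed pooled signal inside the
    search window (ties broken toward earlier latency). Amplitude: mean of the
    0.5-30 Hz pooled signal within latency +- ``amp_halfwidth_ms``. Trials
    whose minimum falls on a window edge are flagged invalid.
    """
    lo, hi = search_window_ms
    wmask = epochs.time_mask(search_window_ms)
    if wmask.sum() < 3:
        raise ValueError("search window empty or outside epoch")
    pooled = pool_channels(epochs.data, epochs.ch_names, pool)
    smooth = zero_phase_fir(pooled, epochs.sfreq, None, 8.0)
    broad = zero_phase_fir(pooled, epochs.sfreq, 0.5, 30.0)
    widx = np.flatnonzero(wmask)
    out: list[SingleTrialN2] = []
    for tr in range(epochs.n_trials):
        seg = smooth[tr, widx]
        imin = int(np.argmin(seg))  # argmin returns the first (earliest) tie
        interior = 0 < imin < seg.size - 1
        lat = float(epochs.times[widx[imin]])
        amask = epochs.time_mask((lat - amp_halfwidth_ms, lat + amp_halfwidth_ms))
        amp = float(broad[tr, amask].mean()) if interior else np.nan
        out.append(
            SingleTrialN2(
                trial=tr, latency_ms=lat if interior else np.nan,
                amplitude_uv=amp, search_window_ms=(lo, hi),
                valid=bool(interior),
            )
        )
    return out


def n2_table(n2s: list[SingleTrialN2]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": [s.trial for s in n2s],
            "latency_ms": [s.latency_ms for s in n2s],
            "amplitude_uv": [s.amplitude_uv for s in n2s],
            "valid": [s.valid for s in n2s],
        }
    )


def n2_effect(
    think_evoked_pooled: np.ndarray,
    nothink_evoked_pooled: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float] = (300.0, 450.0),
) -> float:
    """Think-minus-No-Think mean amplitude in ``window_ms`` (µV).

    Positive when the No-Think waveform is more negative (larger N2).
    """
    mask = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not mask.any():
        raise ValueError("window outside epoch")
    return float(
        think_evoked_pooled[mask].mean() - nothink_evoked_pooled[mask].mean()
    )
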