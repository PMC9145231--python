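"""Morlet wavelet time-frequency analysis on the 1 Hz x 50 ms grid.

Power is computed with 6-cycle (sensor) or 3-cycle (low-frequency / source)
complex Morlet wavelets on padded epochs, then decimated to 50 ms bins and
cropped to -500..3000 ms. Normalization follows the single-trial baseline
scheme: per channel and frequency, (1) z-transform all power samples using the
mean and SD pooled over trials AND time points, (2) average over trials,
(3) subtract the mean z-power of the precue baseline. Pooling over time as
well as trials is what keeps the trial average informative; pooling over
trials alone at each time bin would force it to zero everywhere.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .containers import EpochedEEG, TFRPower

DEFAULT_FREQS = np.arange(2.0, 31.0)
GRID_STEP_MS = 50.0
GRID_WINDOW_MS = (-500.0, 3000.0)
PAD_WINDOW_MS = (-3000.0, 5500.0)


def _mirror_pad(epochs: EpochedEEG) -> tuple[np.ndarray, np.ndarray]:
    """Mirror-pad epochs out to the wide analysis window when the generator
    did not supply padded data."""
    dt = 1000.0 / epochs.sfreq
    need_lo = int(np.ceil((epochs.times[0] - PAD_WINDOW_MS[0]) / dt))
    need_hi = int(np.ceil((PAD_WINDOW_MS[1] - epochs.times[-1]) / dt))
    need_lo, need_hi = max(need_lo, 0), max(need_hi, 0)
    data = np.pad(epochs.data, [(0, 0), (0, 0), (need_lo, need_hi)],
                  mode="reflect")
    times = epochs.times[0] - dt * np.arange(need_lo, 0, -1)
    times = np.concatenate(
        [times, epochs.times, epochs.times[-1] + dt * np.arange(1, need_hi + 1)]
    )
    return data, times


def morlet_tfr(
    epochs: EpochedEEG,
    freqs: np.ndarray = DEFAULT_FREQS,
    cycles: float = 6.0,
    average: bool = False,
    crop_ms: tuple[float, float] = GRID_WINDOW_MS,
) -> TFRPower:
    """Raw Morlet power on the 1 Hz x 50 ms grid.

    Magnitude-squared wavelet coefficients are averaged within consecutive
    50 ms bins (bin centers at -475, -425, ... ms) and cropped to ``crop_ms``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= epochs.sfreq / 2:
        raise ValueError("frequency above Nyquist")
    if cycles not in (3.0, 6.0, 3, 6):
        # both wavelet families from the analysis are allowed; anything else
        # is probably a typo
        raise ValueError("cycles must be 3 or 6")
    data, times = _mirror_pad(epochs)
    min_len = cycles / freqs.min() * epochs.sfreq
    if data.shape[-1] < min_len:
        raise ValueError("epoch too short for the lowest frequency")
    # decimate to the 50 ms grid by averaging samples within each bin
    edges = np.arange(crop_ms[0], crop_ms[1] + GRID_STEP_MS, GRID_STEP_MS)
    centers = edges[:-1] + GRID_STEP_MS / 2
    which = np.searchsorted(edges, times, side="right") - 1
    nbin = centers.size
    bin_masks = [(which == b) for b in range(nbin)]
    n_tr, n_ch = data.shape[:2]
    binned = np.zeros((n_tr, n_ch, freqs.size, nbin))
    for c0 in range(0, n_ch, 4):  # chunk channels to bound memory
        power = tfr_array_morlet(
            data[:, c0: c0 + 4], sfreq=epochs.sfreq, freqs=freqs,
            n_cycles=cycles, output="power", zero_mean=True, verbose=False,
        )
        for b, m in enumerate(bin_masks):
            binned[:, c0: c0 + 4, :, b] = power[..., m].mean(axis=-1)
    tfr = TFRPower(
        data=binned, freqs=freqs, times=centers,
        ch_names=list(epochs.ch_names), state="raw", cycles=float(cycles),
    )
    if average:
        tfr = replace(tfr, data=tfr.data.mean(axis=0, keepdims=True))
    return tfr


def single_trial_z_baseline(
    tfr: TFRPower, baseline_ms: tuple[float, float] = (-500.0, 0.0)
) -> TFRPower:
    """Single-trial z-transform, trial average, baseline subtraction.

    Returns a trial-averaged TFR in state ``zbaselined`` whose mean over the
    baseline bins is exactly zero for every channel and frequency.
    """
    if tfr.state != "raw":
        raise ValueError("expects raw power")
    if tfr.data.shape[0] < 2:
        raise ValueError("needs at least 2 trials to pool statistics")
    # step 1: pooled z over trials and time per (channel, freq)
    mu = tfr.data.mean(axis=(0, 3), keepdims=True)
    sd = tfr.data.std(axis=(0, 3), keepdims=True, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero pooled SD for some channel x frequency")
    z = (tfr.data - mu) / sd
    # step 2: trial average
    z = z.mean(axis=0, keepdims=True)
    # step 3: subtract mean baseline z-power
    bmask = tfr.window_mask(baseline_ms)
    if not bmask.any():
        raise ValueError("baseline window outside TFR grid")
    z = z - z[..., bmask].mean(axis=-1, keepdims=True)
    out = replace(tfr, data=z, state="ztransformed")
    out.advance_state("zbaselined")
    return out


def z_baseline_by_condition(
    tfr: TFRPower,
    conditions: np.ndarray,
    baseline_ms: tuple[float, float] = (-500.0, 0.0),
) -> dict[str, TFRPower]:
    """Condition-wise z-baselined averages with SHARED normalization.

    The z statistics (mean/SD per channel x frequency, pooled over trials and
    time) are computed across all trials, then each condition subset is
    averaged and baseline-subtracted separately — condition contrasts stay on
    one common scale.
    """
    if tfr.state != "raw":
        raise ValueError("expects raw power")
    conditions = np.asarray(conditions)
    mu = tfr.data.mean(axis=(0, 3), keepdims=True)
    sd = tfr.data.std(axis=(0, 3), keepdims=True, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero pooled SD for some channel x frequency")
    bmask = tfr.window_mask(baseline_ms)
    out = {}
    for cond in np.unique(conditions):
        z = (tfr.data[conditions == cond] - mu) / sd
        z = z.mean(axis=0, keepdims=True)
        z = z - z[..., bmask].mean(axis=-1, keepdims=True)
        res = replace(tfr, data=z, state="ztransformed")
        res.advance_state("zbaselined")
        out[str(cond)] = res
    return out


def single_trial_z_power(tfr: TFRPower) -> TFRPower:
    """Per-trial z-scored power (shared pooled statistics), trials kept.

    Used for single-trial modulators on the z scale; state advances to
    ``ztransformed`` only.
    """
    if tfr.state != "raw":
        raise ValueError("expects raw power")
    mu = tfr.data.mean(axis=(0, 3), keepdims=True)
    sd = tfr.data.std(axis=(0, 3), keepdims=True, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero pooled SD")
    return replace(tfr, data=(tfr.data - mu) / sd, state="ztransformed")


def window_band_power(
    tfr: TFRPower,
    band_hz: tuple[float, float],
    window_ms: tuple[float, float],
    channels: list[str] | None = None,
) -> np.ndarray:
    """Mean power over a band x window x channel selection, one value per
    trial (per-trial modulators and split variables)."""
    fmask = tfr.band_mask(band_hz)
    tmask = tfr.window_mask(window_ms)
    if not fmask.any() or not tmask.any():
        raise ValueError("band/window outside the TFR grid")
    if channels is None:
        cidx = np.arange(len(tfr.ch_names))
    else:
        missing = [c for c in channels if c not in tfr.ch_names]
        if missing:
            raise ValueError(f"unknown channels {missing}")
        cidx = np.array([tfr.ch_names.index(c) for c in channels])
    if cidx.size == 0:
        raise ValueError("empty channel selection")
    sub = tfr.data[:, cidx][:, :, fmask][:, :, :, tmask]
    return sub.mean(axis=(1, 2, 3))
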