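"""LCMV beamformer source reconstruction.

Spatial filters minimize output variance subject to unit gain at each source:
``W_s = (L_s' C^-1 L_s)^-1 L_s' C^-1`` with the sensor covariance regularized
as ``C + lambda I``, ``lambda = reg_fraction x max eigenvalue(C)`` (the
0.001% rule corresponds to ``reg_fraction = 1e-5``). For evoked contrasts the
filters are computed on the Think/No-Think difference of trial-averaged data
(epoch-average subtraction), which suppresses strong sources common to both
conditions. Per-source dipole momentum is reconstructed on 3 Cartesian
orientations and may be collapsed onto the principal orientation; the
collapsed trace's sign is aligned with the sensor-space frontocentral
convention (negative-going N2).
"""

from __future__ import annotations

import numpy as np

from .containers import EpochedEEG, GainMatrix, SpatialFilterSet


def sensor_covariance(
    epochs_or_evoked: np.ndarray, times_ms: np.ndarray,
    window_ms: tuple[float, float] | None = None,
) -> np.ndarray:
    """Empirical sensor covariance over a time window.

    Accepts (trials, channels, samples) epochs (trials concatenated) or a
    (channels, samples) evoked array.
    """
    x = np.asarray(epochs_or_evoked, dtype=float)
    if window_ms is not None:
        mask = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
        x = x[..., mask]
    if x.ndim == 3:
        x = np.moveaxis(x, 1, 0).reshape(x.shape[1], -1)
    x = x - x.mean(axis=1, keepdims=True)
    return x @ x.T / x.shape[1]


def lcmv_filters(
    data: np.ndarray,
    times_ms: np.ndarray,
    gain: GainMatrix,
    window_ms: tuple[float, float] | None = None,
    reg_fraction: float = 1e-5,
) -> SpatialFilterSet:
    """LCMV spatial filters from epochs or evoked data.

    ``reg_fraction`` scales the largest covariance eigenvalue to give the
    diagonal-loading lambda (default 1e-5, i.e. 0.001%).
    """
    C = sensor_covariance(data, times_ms, window_ms)
    n_samp = (np.count_nonzero((times_ms >= window_ms[0]) & (times_ms <= window_ms[1]))
              if window_ms is not None else len(times_ms))
    if np.asarray(data).ndim == 2 and n_samp < C.shape[0]:
        import warnings

        warnings.warn("covariance window has fewer samples than sensors",
                      RuntimeWarning, stacklevel=2)
    lam = reg_fraction * float(np.linalg.eigvalsh(C).max())
    Creg = C + lam * np.eye(C.shape[0])
    try:
        Cinv = np.linalg.inv(Creg)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "regularized covariance is singular"
        ) from err
    n_src = gain.n_sources
    W = np.empty((3 * n_src, C.shape[0]))
    for s in range(n_src):
        L = gain.source_block(s)  # sensors x 3
        A = L.T @ Cinv
        W[3 * s: 3 * s + 3] = np.linalg.solve(A @ L, A)
    win = window_ms if window_ms is not None else (times_ms[0], times_ms[-1])
    return SpatialFilterSet(filters=W, lam=lam, window_ms=tuple(win),
                            ch_names=list(gain.ch_names))


def subtract_epoch_average(
    epochs_a: EpochedEEG, epochs_b: EpochedEEG, condition_a: str | None = None,
    condition_b: str | None = None,
) -> np.ndarray:
    """Trial-average(A) minus trial-average(B) sensor data (channels x samples).

    Used to compute covariance/filters for evoked contrasts so that dominant
    sources common to both conditions cancel before beamforming.
    """
    if epochs_a.ch_names != epochs_b.ch_names or not np.array_equal(
        epochs_a.times, epochs_b.times
    ):
        raise ValueError("mismatched channel/time axes")

    def _avg(ep, cond):
        mask = np.ones(ep.n_trials, dtype=bool)
        if cond is not None:
            mask &= (ep.metadata["condition"] == cond).to_numpy()
        return ep.data[mask].mean(axis=0)

    return _avg(epochs_a, condition_a) - _avg(epochs_b, condition_b)


def apply_filters(
    filters: SpatialFilterSet, data: np.ndarray
) -> np.ndarray:
    """Project sensor data through the filters.

    (trials, channels, samples) -> (trials, sources, 3, samples);
    (channels, samples) -> (sources, 3, samples).
    """
    W = filters.filters
    x = np.asarray(data, dtype=float)
    if x.shape[-2] != W.shape[1]:
        raise ValueError("filter/channel dimension mismatch")
    proj = np.einsum("ks,...st->...kt", W, x)
    n_src = filters.n_sources
    return proj.reshape(proj.shape[:-2] + (n_src, 3, proj.shape[-1]))


def principal_orientation_collapse(
    momentum: np.ndarray, reference: np.ndarray | None = None
) -> np.ndarray:
    """Collapse 3-orientation momentum onto its principal axis.

    ``momentum``: (..., sources, 3, samples) or (sources, 3, samples); the
    principal axis is the leading eigenvector of the per-source 3x3 covariance
    pooled over trials and samples. When a ``reference`` (samples,) trace is
    given, the sign of each collapsed source is flipped so its trial-average
    correlates positively with it (sensor-space polarity convention);
    otherwise the dominant eigenvector's largest component is made positive.
    """
    x = np.asarray(momentum, dtype=float)
    single = x.ndim == 3
    if single:
        x = x[None]
    n_tr, n_src, _, n_samp = x.shape
    out = np.empty((n_tr, n_src, n_samp))
    for s in range(n_src):
        sig = x[:, s]  # trials x 3 x samples
        flat = np.moveaxis(sig, 1, 0).reshape(3, -1)
        cov = flat @ flat.T / flat.shape[1]
        if np.allclose(cov, 0):
            raise ValueError(f"zero-variance source {s}")
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, -1]
        proj = np.einsum("o,tos->ts", v, sig)
        if reference is not None:
            c = np.corrcoef(proj.mean(axis=0), reference)[0, 1]
            if c < 0:
                proj = -proj
        elif v[np.argmax(np.abs(v))] < 0:
            proj = -proj
        out[:, s] = proj
    return out[0] if single else out


def explained_variance_ratio(momentum_3d: np.ndarray) -> float:
    """Fraction of variance carried by the principal orientation of one
    (3, samples) or (trials, 3, samples) momentum array."""
    x = np.asarray(momentum_3d, dtype=float)
    flat = np.moveaxis(x.reshape(-1, 3, x.shape[-1]), 1, 0).reshape(3, -1)
    cov = flat @ flat.T / flat.shape[1]
    evals = np.linalg.eigvalsh(cov)
    return float(evals[-1] / evals.sum())


def roi_aggregate(
    per_source: np.ndarray, roi_members: np.ndarray, axis: int
) -> np.ndarray:
    """Mean across the member sources of one ROI along ``axis``."""
    roi_members = np.asarray(roi_members)
    if roi_members.size == 0:
        raise ValueError("empty ROI")
    return np.take(per_source, roi_members, axis=axis).mean(axis=axis)


def source_power_map(
    filters: SpatialFilterSet, data: np.ndarray, times_ms: np.ndarray,
    window_ms: tuple[float, float],
) -> np.ndarray:
    """Per-source output power (summed over orientations) in a window —
    the quantity mapped over the grid for localization contrasts."""
    mask = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    proj = apply_filters(filters, np.asarray(data)[..., mask])
    return np.sum(proj**2, axis=(-2, -1)) if proj.ndim == 3 else np.sum(
        proj**2, axis=(-2, -1)
    ).mean(axis=0)
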