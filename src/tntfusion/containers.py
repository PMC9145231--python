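"""Shared in-memory containers for the EEG-fMRI suppression pipeline.

All stages exchange a small set of typed containers: epoched sensor EEG,
time-frequency power on the analysis grid, the forward (gain) matrix and
LCMV filter sets, Granger-causality spectra, and permutation-test results.
Arrays are plain numpy; trial metadata is a pandas DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical condition labels
THINK, NOTHINK, PERCEPTUAL = "Think", "No-Think", "Perceptual"


@dataclass
class EpochedEEG:
    """Epoched multichannel EEG: ``data`` is (trials, channels, samples) in µV.

    ``times`` is in milliseconds relative to cue onset. ``metadata`` carries one
    row per trial with at least ``condition``, ``learned``, ``block``,
    ``onset_s`` and ``artifact`` columns.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    ch_names: list[str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        n_tr, n_ch, n_sm = self.data.shape
        if n_ch != len(self.ch_names):
            raise ValueError("channel-name count does not match data")
        if n_sm != self.times.size:
            raise ValueError("times length does not match data")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.metadata) != n_tr:
            raise ValueError("metadata rows must match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def pick_channels(self, names: list[str]) -> "EpochedEEG":
        idx = [self.ch_names.index(n) for n in names]
        return replace(self, data=self.data[:, idx, :], ch_names=list(names))

    def select_trials(self, mask: np.ndarray) -> "EpochedEEG":
        """Boolean mask or index array over trials."""
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            metadata=self.metadata.iloc[mask].reset_index(drop=True),
        )

    def crop(self, tmin_ms: float, tmax_ms: float) -> "EpochedEEG":
        keep = (self.times >= tmin_ms) & (self.times <= tmax_ms)
        return replace(self, data=self.data[:, :, keep], times=self.times[keep])

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        lo, hi = window_ms
        return (self.times >= lo) & (self.times <= hi)


@dataclass
class TFRPower:
    """Time-frequency power on the 1 Hz x 50 ms analysis grid.

    ``data`` is (trials, channels, freqs, timebins); after trial averaging the
    first axis has length 1. ``state`` tracks the normalization stage and may
    only advance raw -> ztransformed -> zbaselined.
    """

    data: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # bin centers, ms
    ch_names: list[str]
    state: str = "raw"
    cycles: float | None = None

    _STATES = ("raw", "ztransformed", "zbaselined")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be (trials, channels, freqs, times)")
        if self.state not in self._STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "raw" and self.data.size and self.data.min() < 0:
            raise ValueError("raw power must be non-negative")

    def advance_state(self, new: str) -> None:
        if self._STATES.index(new) != self._STATES.index(self.state) + 1:
            raise ValueError(f"illegal state transition {self.state} -> {new}")
        self.state = new

    def band_mask(self, band_hz: tuple[float, float]) -> np.ndarray:
        return (self.freqs >= band_hz[0]) & (self.freqs <= band_hz[1])

    def window_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        return (self.times >= window_ms[0]) & (self.times <= window_ms[1])


@dataclass
class GainMatrix:
    """Forward model: ``matrix`` is (sensors, sources * 3) with orientation
    triplets stored contiguously; ``positions`` are source grid coordinates
    in meters."""

    matrix: np.ndarray
    positions: np.ndarray
    ch_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("gain must be finite")
        if self.matrix.shape[1] % 3:
            raise ValueError("gain columns must come in orientation triplets")
        norms = np.linalg.norm(
            self.matrix.reshape(self.matrix.shape[0], -1, 3), axis=(0, 2)
        )
        if np.any(norms == 0):
            raise ValueError("all-zero source triplet in gain")

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1] // 3

    def source_block(self, s: int) -> np.ndarray:
        return self.matrix[:, 3 * s : 3 * s + 3]


@dataclass
class SpatialFilterSet:
    """LCMV filters: ``filters`` is (sources * 3, sensors)."""

    filters: np.ndarray
    lam: float
    window_ms: tuple[float, float]
    ch_names: list[str]

    @property
    def n_sources(self) -> int:
        return self.filters.shape[0] // 3

    def source_block(self, s: int) -> np.ndarray:
        return self.filters[3 * s : 3 * s + 3, :]


@dataclass
class GCSpectrum:
    """Geweke spectral Granger causality per ordered ROI pair.

    ``values`` maps ``(from, to)`` -> array over ``freqs`` (natural-log units,
    non-negative). ``residual`` is the relative CSD reconstruction error of the
    factorization that produced the spectra.
    """

    values: dict[tuple[str, str], np.ndarray]
    freqs: np.ndarray
    residual: float
    window_ms: tuple[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.size and v.min() < -1e-10:
                raise ValueError(f"negative GC for {k}")
            self.values[k] = np.maximum(v, 0.0)


@dataclass
class Cluster:
    """One supra-threshold cluster: flat bin indices into the tested map."""

    bins: np.ndarray
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    """Outcome of a cluster/max-statistic permutation test."""

    clusters: list[Cluster]
    stat_map: np.ndarray
    threshold: float
    tails: str
    n_permutations: int
    seed: int | None = None
    mode: str = "cluster_mass"

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < 0.05]

    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        mask = np.zeros(self.stat_map.size, dtype=bool)
        for c in self.clusters:
            if c.p_value < alpha:
                mask[c.bins] = True
        return mask.reshape(self.stat_map.shape)
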