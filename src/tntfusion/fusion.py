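"""EEG-informed fMRI: parametric-modulator GLMs and cluster-size correction.

Single-trial EEG measures (N2 amplitude, dACC theta power, hippocampal theta
power) enter first-level GLMs as parametric modulators: each condition
contributes an onset regressor (stick functions convolved with the canonical
SPM double-gamma HRF) plus a modulator regressor whose stick amplitudes are
the mean-centered single-trial values. Trials flagged as artifacts, not
learned, or with measures beyond +-3 SD of their condition are moved to a
no-interest regressor. Runs are fit separately by OLS; contrasts are averaged
across runs per participant; group inference uses one-sample/paired t tests
on participant contrasts. Whole-grid maps are corrected with the
modulator-shuffling cluster-size permutation: the modulator values are
reassigned to different trials' onsets (multiset preserved), everything is
refit, and the 95th percentile of the maximal null cluster size thresholds
the observed map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import spm_hrf
from scipy import ndimage, stats as sps

HRF_DT = 0.1  # s, oversampled grid for stick convolution
Z_EXCLUDE_SD = 3.0


def hrf_kernel(dt: float = HRF_DT) -> np.ndarray:
    """Canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6)
    sampled every ``dt`` seconds and scaled to unit peak, so a unit stick
    produces a unit-height response."""
    h = spm_hrf(1.0, oversampling=int(round(1.0 / dt)))
    return h / h.max()


def hrf_convolve_sticks(
    onsets_s: np.ndarray,
    amplitudes: np.ndarray,
    n_vols: int,
    tr: float,
    dt: float = HRF_DT,
) -> np.ndarray:
    """HRF-convolved stick train sampled at volume times (length ``n_vols``)."""
    onsets_s = np.atleast_1d(np.asarray(onsets_s, float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, float))
    dur = n_vols * tr
    if np.any(onsets_s < 0) or np.any(onsets_s >= dur):
        raise ValueError("onset outside run")
    n_hi = int(np.ceil(dur / dt)) + 1
    sticks = np.zeros(n_hi)
    idx = np.round(onsets_s / dt).astype(int)
    np.add.at(sticks, idx, amplitudes)
    resp = np.convolve(sticks, hrf_kernel(dt))[:n_hi]
    frame_idx = np.round(np.arange(n_vols) * tr / dt).astype(int)
    return resp[frame_idx]


def trial_response_matrix(
    onsets_s: np.ndarray, n_vols: int, tr: float, dt: float = HRF_DT
) -> np.ndarray:
    """(n_vols, n_trials) matrix of unit-amplitude per-trial HRF responses."""
    onsets_s = np.asarray(onsets_s, float)
    return np.column_stack(
        [hrf_convolve_sticks([o], [1.0], n_vols, tr, dt) for o in onsets_s]
    ) if onsets_s.size else np.zeros((n_vols, 0))


@dataclass
class RunDesign:
    """First-level design matrix for one run."""

    matrix: pd.DataFrame
    excluded_trials: np.ndarray  # event-row indices moved to no-interest
    modulator_values: dict[str, np.ndarray]  # centered values actually used


@dataclass
class FusionDesign:
    runs: list[RunDesign]
    modulator_name: str
    conditions: tuple[str, ...]


def flag_outlier_measures(measures: np.ndarray, cond: np.ndarray,
                          sd: float = Z_EXCLUDE_SD) -> np.ndarray:
    """True where a finite measure lies beyond ``sd`` SDs of its condition."""
    out = np.zeros(measures.size, dtype=bool)
    for c in np.unique(cond):
        sel = (cond == c) & np.isfinite(measures)
        if sel.sum() < 2:
            continue
        mu, s = measures[sel].mean(), measures[sel].std()
        if s > 0:
            out[sel] = np.abs(measures[sel] - mu) > sd * s
    return out


def build_parametric_design(
    events: pd.DataFrame,
    measures: np.ndarray,
    n_vols: int,
    tr: float,
    modulated_conditions: tuple[str, ...] = ("Think", "No-Think"),
    modulator_name: str = "eeg",
    motion: np.ndarray | None = None,
    dt: float = HRF_DT,
) -> FusionDesign:
    """Build the per-run parametric design from one participant's events.

    ``events`` needs columns ``onset_s``, ``condition``, ``run``, ``learned``,
    ``artifact``; ``measures`` is the per-trial EEG value (NaN allowed, such
    trials are excluded). Outliers beyond +-3 SD of their condition (computed
    across the participant's included trials) join the no-interest regressor.
    Modulators are mean-centered per condition and run, which makes them
    orthogonal to their own onset column.
    """
    events = events.reset_index(drop=True)
    measures = np.asarray(measures, float)
    if len(measures) != len(events):
        raise ValueError("one measure per event row required")
    cond = events["condition"].to_numpy()
    usable = (
        events["learned"].to_numpy(dtype=bool)
        & ~events["artifact"].to_numpy(dtype=bool)
    )
    # perceptual trials are never modulated but stay usable
    needs_measure = np.isin(cond, modulated_conditions)
    usable_mod = usable & needs_measure & np.isfinite(measures)
    outlier = flag_outlier_measures(
        np.where(usable_mod, measures, np.nan), cond
    )
    include_mod = usable_mod & ~outlier
    no_interest = ~usable | (needs_measure & usable & ~include_mod)

    runs: list[RunDesign] = []
    for run_id in sorted(events["run"].unique()):
        rsel = (events["run"] == run_id).to_numpy()
        cols: dict[str, np.ndarray] = {}
        modvals: dict[str, np.ndarray] = {}
        for c in ("Think", "No-Think", "Perceptual"):
            csel = rsel & (cond == c) & usable & ~no_interest
            if csel.any():
                cols[f"onset_{c}"] = hrf_convolve_sticks(
                    events.loc[csel, "onset_s"].to_numpy() - 0.0,
                    np.ones(csel.sum()), n_vols, tr, dt,
                )
        for c in modulated_conditions:
            csel = rsel & (cond == c) & include_mod
            if not csel.any():
                raise ValueError(
                    f"all {c} trials excluded in run {run_id}"
                )
            vals = measures[csel]
            centered = vals - vals.mean()
            modvals[c] = centered
            cols[f"mod_{c}_{modulator_name}"] = hrf_convolve_sticks(
                events.loc[csel, "onset_s"].to_numpy(), centered,
                n_vols, tr, dt,
            )
        nsel = rsel & no_interest
        if nsel.any():
            cols["no_interest"] = hrf_convolve_sticks(
                events.loc[nsel, "onset_s"].to_numpy(),
                np.ones(nsel.sum()), n_vols, tr, dt,
            )
        if motion is not None:
            for k in range(motion.shape[-1]):
                cols[f"motion_{k}"] = motion[run_id][:, k] if motion.ndim == 3 \
                    else motion[:, k]
        cols["drift"] = np.linspace(-0.5, 0.5, n_vols)
        cols["constant"] = np.ones(n_vols)
        runs.append(
            RunDesign(
                matrix=pd.DataFrame(cols),
                excluded_trials=np.flatnonzero(rsel & no_interest),
                modulator_values=modvals,
            )
        )
    return FusionDesign(runs=runs, modulator_name=modulator_name,
                        conditions=modulated_conditions)


@dataclass
class CouplingResult:
    """Per-run betas averaged to participant level."""

    betas: pd.DataFrame  # index: regressor, columns: ROI/voxel
    run_betas: list[pd.DataFrame] = field(default_factory=list)


def fit_glm(bold_runs: list[np.ndarray], design: FusionDesign) -> CouplingResult:
    """Run-wise OLS fits; betas averaged across runs (fixed effects).

    ``bold_runs[r]`` is (n_vols, n_series) for run r; series may be ROIs or
    voxels. Raises on rank-deficient designs, naming the offending columns.
    """
    if len(bold_runs) != len(design.runs):
        raise ValueError("run count mismatch between BOLD and design")
    per_run = []
    for r, (y, rd) in enumerate(zip(bold_runs, design.runs)):
        X = rd.matrix.to_numpy()
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify near-collinear columns by QR diagonal
            qr_d = np.abs(np.diag(np.linalg.qr(X, mode="r")))
            bad = [rd.matrix.columns[i] for i in np.where(qr_d < 1e-10)[0]]
            raise ValueError(f"rank-deficient design in run {r}: {bad}")
        beta, *_ = np.linalg.lstsq(X, np.asarray(y, float), rcond=None)
        per_run.append(pd.DataFrame(beta, index=rd.matrix.columns))
    avg = (
        pd.concat(per_run).groupby(level=0).mean()
    )
    return CouplingResult(betas=avg, run_betas=per_run)


def group_ttest(values: np.ndarray, popmean: float = 0.0) -> dict:
    t, p = sps.ttest_1samp(np.asarray(values, float), popmean)
    return {"t": float(t), "p": float(p), "mean": float(np.mean(values))}


def paired_ttest(a: np.ndarray, b: np.ndarray) -> dict:
    t, p = sps.ttest_rel(np.asarray(a, float), np.asarray(b, float))
    return {"t": float(t), "p": float(p),
            "mean_diff": float(np.mean(np.asarray(a) - np.asarray(b)))}


def roi_coupling_summary(
    participant_betas: list[CouplingResult],
    regressors: list[str],
    roi_names: list[str],
) -> pd.DataFrame:
    """Group table: per (regressor, ROI) mean beta, one-sample t/p; plus the
    paired contrast between the two modulated conditions when both present."""
    rows = []
    for reg in regressors:
        mat = np.array([c.betas.loc[reg].to_numpy() for c in participant_betas])
        for j, roi in enumerate(roi_names):
            g = group_ttest(mat[:, j])
            rows.append({"regressor": reg, "roi": roi, **g})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# modulator-shuffling cluster-size correction on a voxel grid
# ---------------------------------------------------------------------------

@dataclass
class ModulatorRunData:
    """Pre-residualized quantities for fast modulator refits in one run."""

    R: np.ndarray        # (n_vols, n_trials) residualized trial responses
    Y: np.ndarray        # (n_vols, n_vox) residualized BOLD
    values: np.ndarray   # centered modulator values (the multiset to shuffle)


def prepare_modulator_run(
    bold: np.ndarray,
    events_onsets_s: np.ndarray,
    values: np.ndarray,
    other_regressors: np.ndarray,
    tr: float,
    dt: float = HRF_DT,
) -> ModulatorRunData:
    """Residualize BOLD and per-trial responses against the non-modulator
    design columns so that permuted modulator fits reduce to projections."""
    n_vols = bold.shape[0]
    R = trial_response_matrix(events_onsets_s, n_vols, tr, dt)
    X = np.asarray(other_regressors, float)
    pinv = np.linalg.pinv(X)
    resid = lambda M: M - X @ (pinv @ M)
    v = np.asarray(values, float)
    return ModulatorRunData(R=resid(R), Y=resid(np.asarray(bold, float)),
                            values=v - v.mean())


def _participant_map(runs: list[ModulatorRunData],
                     perms: list[np.ndarray] | None = None) -> np.ndarray:
    """Average across runs of the modulator beta per voxel."""
    betas = []
    for k, rd in enumerate(runs):
        v = rd.values if perms is None else rd.values[perms[k]]
        m = rd.R @ v
        denom = float(m @ m)
        if denom <= 0:
            betas.append(np.zeros(rd.Y.shape[1]))
            continue
        betas.append((m @ rd.Y) / denom)
    return np.mean(betas, axis=0)


def _group_zmap(maps: np.ndarray) -> np.ndarray:
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    # t -> z via matched tail probabilities
    p = sps.t.sf(np.abs(t), n - 1)
    p = np.clip(p, 1e-300, 0.5)
    return np.sign(t) * sps.norm.isf(p)


def _max_cluster_size(zmap_grid: np.ndarray, z_thresh: float) -> int:
    struct = ndimage.generate_binary_structure(zmap_grid.ndim, 1)
    best = 0
    for mask in (zmap_grid > z_thresh, zmap_grid < -z_thresh):
        lab, n = ndimage.label(mask, structure=struct)
        if n:
            best = max(best, int(np.bincount(lab.ravel())[1:].max()))
    return best


def permutation_cluster_correct(
    participants: list[list[ModulatorRunData]],
    grid_shape: tuple[int, ...],
    n_perm: int = 100,
    z_thresh: float = 2.57,
    seed: int | None = None,
) -> dict:
    """Modulator-shuffling cluster-size correction of the group z map.

    For each permutation, every run's modulator values are reassigned to
    different trials' onsets (the multiset is preserved), all first-level fits
    are redone, and the maximal supra-threshold cluster size of the group
    z map is recorded. The observed clusters are flagged significant when
    their size reaches the 95th percentile of that null.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives an unstable percentile; refused")
    rng = np.random.default_rng(seed)
    obs_maps = np.array([_participant_map(p) for p in participants])
    z_obs = _group_zmap(obs_maps).reshape(grid_shape)
    null_sizes = np.empty(n_perm, dtype=int)
    for k in range(n_perm):
        maps = []
        for p in participants:
            perms = [rng.permutation(rd.values.size) for rd in p]
            maps.append(_participant_map(p, perms))
        z = _group_zmap(np.array(maps)).reshape(grid_shape)
        null_sizes[k] = _max_cluster_size(z, z_thresh)
    # smallest cluster size whose null exceedance probability is <= 5%
    # (a plain percentile is degenerate when null sizes tie at small integers)
    size_thresh = 1
    while np.mean(null_sizes >= size_thresh) > 0.05:
        size_thresh += 1
    struct = ndimage.generate_binary_structure(len(grid_shape), 1)
    surviving = np.zeros(grid_shape, dtype=bool)
    clusters = []
    for sign, mask in (("pos", z_obs > z_thresh), ("neg", z_obs < -z_thresh)):
        lab, n = ndimage.label(mask, structure=struct)
        for c in range(1, n + 1):
            size = int((lab == c).sum())
            ok = size >= size_thresh and size > 0
            clusters.append({"sign": sign, "size": size, "significant": ok})
            if ok:
                surviving |= lab == c
    return {
        "z_map": z_obs,
        "cluster_size_threshold": size_thresh,
        "null_max_sizes": null_sizes,
        "clusters": clusters,
        "surviving_mask": surviving,
    }
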