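"""End-to-end analysis arms over simulated datasets.

`compute_participant_features` runs the full per-participant chain (sensor
ERP/TFR, LCMV source momentum, single-trial measures, GC spectra, modulator
GLMs); `analyze_dataset` performs the group-level inference for each
hypothesis arm and returns a dict of effect summaries used by the
parameter-recovery suite and the acceptance script:

* ``theta_cluster`` — No-Think > Think frontal theta cluster (4-6 Hz,
  250-800 ms expected);
* ``n2`` — pooled-channel N2 effect (No-Think more negative, 300-450 ms);
* ``coupling`` — EEG-informed fMRI: negative No-Think-specific coupling of
  early dACC theta and N2 depth with dACC/rDLPFC/hippocampal BOLD, positive
  hippocampal theta-BOLD coupling;
* ``gc_dacc_rdlpfc`` — dACC -> rDLPFC low-frequency GC dominance in the
  high-conflict stratum only;
* ``gc_rdlpfc_hipp`` — rDLPFC -> hippocampus low-beta GC dominance during
  No-Think;
* ``hipp_theta_split`` — lower hippocampal 4-6 Hz power in large-N2 than
  small-N2 trials (650-1850 ms);
* ``sif`` — positive robust correlation between the N2 effect and z-SIF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import behavior as beh
from . import connectivity as conn
from . import erp, fusion, inverse, spectral, stats
from .containers import NOTHINK, THINK
from .synth import ROI_NAMES, SimulatedParticipant

THETA_BAND = (4.0, 8.0)
THETA_CLUSTER_BAND = (4.0, 6.0)
THETA_WINDOW = (250.0, 800.0)
N2_WINDOW = (300.0, 450.0)
CONFLICT_WINDOW = (428.0, 728.0)
HIPP_WINDOW = (650.0, 1850.0)
HIPP_BAND = (4.0, 6.0)
GC_LOW_BAND = (2.0, 13.0)
GC_BETA_BAND = (12.0, 18.0)


@dataclass
class ParticipantFeatures:
    index: int
    tfr_nothink: np.ndarray      # (freqs, times) z-baselined pooled channel
    tfr_think: np.ndarray
    tfr_freqs: np.ndarray
    tfr_times: np.ndarray
    n2_effect_uv: float
    n2_depth: np.ndarray         # per-trial N2 depth (µV, positive = deeper)
    dacc_theta: np.ndarray       # per-trial early dACC theta power (z)
    conflict: np.ndarray         # per-trial delayed dACC deflection measure
    hipp_theta: np.ndarray       # per-trial hippocampal theta power (z)
    gc: dict                     # {(pair, stratum): GCSpectrum}
    gc_rev: dict                 # same, computed on time-reversed windows
    gc_freqs: np.ndarray
    betas: dict                  # modulator -> {roi: {cond: beta}}
    events: pd.DataFrame


def _pooled_epochs(part: SimulatedParticipant):
    pooled = erp.pool_channels(part.epochs.data, part.epochs.ch_names)
    from dataclasses import replace

    return replace(part.epochs, data=pooled[:, None, :], ch_names=["FCpool"])


def _trace_tfr(data_1ch: np.ndarray, part: SimulatedParticipant,
               name: str) -> spectral.TFRPower:
    from .containers import EpochedEEG

    ep = EpochedEEG(
        data=data_1ch[:, None, :], sfreq=part.epochs.sfreq,
        times=part.epochs.times, ch_names=[name],
        metadata=part.epochs.metadata,
    )
    return spectral.morlet_tfr(ep, cycles=3.0)


def compute_participant_features(
    part: SimulatedParticipant, n2_window: tuple[float, float] = N2_WINDOW,
) -> ParticipantFeatures:
    meta = part.epochs.metadata
    usable = (
        meta["learned"].to_numpy(dtype=bool)
        & ~meta["artifact"].to_numpy(dtype=bool)
    )
    cond = meta["condition"].to_numpy()
    nt_mask = usable & (cond == NOTHINK)
    th_mask = usable & (cond == THINK)

    # --- sensor TFR on the pooled frontocentral channel ------------------
    pooled_ep = _pooled_epochs(part)
    keep = nt_mask | th_mask
    sub = pooled_ep.select_trials(np.flatnonzero(keep))
    tfr = spectral.morlet_tfr(sub, cycles=3.0)
    zmaps = spectral.z_baseline_by_condition(
        tfr, sub.metadata["condition"].to_numpy()
    )
    tfr_nt = zmaps[NOTHINK].data[0, 0]
    tfr_th = zmaps[THINK].data[0, 0]

    # --- ERP and single-trial N2 -----------------------------------------
    ev_t = erp.average_erp(part.epochs, THINK)
    ev_nt = erp.average_erp(part.epochs, NOTHINK)
    pooled_t = erp.pool_channels(ev_t, part.epochs.ch_names)
    pooled_nt = erp.pool_channels(ev_nt, part.epochs.ch_names)
    n2_eff = erp.n2_effect(pooled_t, pooled_nt, part.epochs.times, n2_window)
    grand = erp.pool_channels(erp.average_erp(part.epochs, None),
                              part.epochs.ch_names)
    search = erp.find_search_window(grand, part.epochs.times)
    n2s = erp.extract_single_trial_n2(part.epochs, search)
    n2_amp = np.array([s.amplitude_uv for s in n2s])
    n2_depth = -n2_amp  # positive = deeper (more negative) N2
    n2_depth[~usable] = np.nan

    # --- LCMV source momentum for the three ROIs --------------------------
    filt = inverse.lcmv_filters(part.epochs.data[usable], part.epochs.times,
                                part.gain)
    momentum = inverse.apply_filters(filt, part.epochs.data)
    roi_mom = {}
    for roi in ROI_NAMES:
        agg = inverse.roi_aggregate(momentum, part.roi_members[roi], axis=1)
        collapsed = inverse.principal_orientation_collapse(
            agg[:, None, :, :], reference=pooled_nt
        )[:, 0]
        roi_mom[roi] = collapsed

    # --- single-trial source measures -------------------------------------
    tfr_dacc = spectral.single_trial_z_power(
        _trace_tfr(roi_mom["dACC"], part, "dACC")
    )
    dacc_theta = spectral.window_band_power(tfr_dacc, THETA_BAND, n2_window)
    dacc_theta[~usable] = np.nan
    tfr_hipp = spectral.single_trial_z_power(
        _trace_tfr(roi_mom["hipp"], part, "hipp")
    )
    hipp_theta = spectral.window_band_power(tfr_hipp, HIPP_BAND, HIPP_WINDOW)
    hipp_theta[~usable] = np.nan
    # delayed conflict signal: negative-going 0.5-8 Hz dACC deflection
    slow = erp.zero_phase_fir(roi_mom["dACC"], part.epochs.sfreq, 0.5, 8.0)
    wmask = part.epochs.time_mask(CONFLICT_WINDOW)
    conflict = -slow[:, wmask].mean(axis=1)
    conflict[~usable] = np.nan

    # --- Granger causality -------------------------------------------------
    roi_series = np.stack([roi_mom[r] for r in ROI_NAMES], axis=1)
    gc = {}
    nt_idx = np.flatnonzero(nt_mask)
    lo_idx, hi_idx = stats.median_split(
        np.where(nt_mask, conflict, np.nan)
    )
    pairs = {
        ("dacc_rdlpfc", "high"): (hi_idx, (0, 1), ("dACC", "rDLPFC")),
        ("dacc_rdlpfc", "low"): (lo_idx, (0, 1), ("dACC", "rDLPFC")),
        ("rdlpfc_hipp", "nothink"): (nt_idx, (1, 2), ("rDLPFC", "hipp")),
        ("rdlpfc_hipp", "think"): (np.flatnonzero(th_mask), (1, 2),
                                   ("rDLPFC", "hipp")),
    }
    gc_freqs = None
    gc_rev = {}
    win = part.epochs.time_mask(conn.GC_WINDOW_MS)
    for (name, stratum), (idx, pidx, pnames) in pairs.items():
        xw = roi_series[idx][:, :, win]
        spec_gc = conn.pairwise_gc(
            xw, part.epochs.sfreq, pidx, pnames,
            times_ms=None, label=f"{name}:{stratum}",
        )
        gc[(name, stratum)] = spec_gc
        # time-reversed control: genuine lagged influence flips direction
        gc_rev[(name, stratum)] = conn.pairwise_gc(
            xw[..., ::-1], part.epochs.sfreq, pidx, pnames,
            times_ms=None, label=f"{name}:{stratum}:reversed",
        )
        gc_freqs = spec_gc.freqs

    # --- EEG-informed fMRI -------------------------------------------------
    betas: dict = {}
    modulators = {
        "dacc_theta": dacc_theta,
        "n2_depth": n2_depth,
        "hipp_theta": hipp_theta,
    }
    for mname, meas in modulators.items():
        design = fusion.build_parametric_design(
            part.events, meas, part.bold_runs.shape[1],
            tr=_tr_from(part), modulator_name=mname, motion=part.motion,
        )
        res = fusion.fit_glm(list(part.bold_runs), design)
        betas[mname] = {
            roi: {
                c: float(res.betas.loc[f"mod_{c}_{mname}"].iloc[j])
                for c in (THINK, NOTHINK)
            }
            for j, roi in enumerate(ROI_NAMES)
        }

    return ParticipantFeatures(
        index=part.index,
        tfr_nothink=tfr_nt, tfr_think=tfr_th,
        tfr_freqs=tfr.freqs, tfr_times=tfr.times,
        n2_effect_uv=n2_eff, n2_depth=n2_depth, dacc_theta=dacc_theta,
        conflict=conflict, hipp_theta=hipp_theta,
        gc=gc, gc_rev=gc_rev, gc_freqs=gc_freqs, betas=betas,
        events=part.events,
    )


def _tr_from(part: SimulatedParticipant) -> float:
    return float(part.tr)


def _gc_matrix(feats: list[ParticipantFeatures], name: str, stratum: str,
               direction: tuple[str, str]) -> np.ndarray:
    return np.array([f.gc[(name, stratum)].values[direction] for f in feats])


def _cluster_overlaps(result, freqs, times, band, window) -> bool:
    """Any significant positive cluster containing a bin inside band x window."""
    shape = (freqs.size, times.size)
    for c in result.significant:
        if c.mass <= 0:
            continue
        fi, ti = np.unravel_index(c.bins, shape)
        ok = (
            (freqs[fi] >= band[0]) & (freqs[fi] <= band[1])
            & (times[ti] >= window[0]) & (times[ti] <= window[1])
        )
        if ok.any():
            return True
    return False


def analyze_dataset(
    parts: list[SimulatedParticipant],
    n_perm: int = 500,
    seed: int = 0,
) -> dict:
    """Group-level inference for every hypothesis arm; returns summaries."""
    feats = [compute_participant_features(p) for p in parts]
    out: dict = {}

    # (a) frontal theta cluster, No-Think > Think
    nt_maps = np.stack([f.tfr_nothink for f in feats])
    th_maps = np.stack([f.tfr_think for f in feats])
    res_a = stats.cluster_permutation_test(
        nt_maps, th_maps, unit="participant", n_perm=n_perm, tails="two",
        seed=seed,
    )
    f0 = feats[0]
    out["theta_cluster"] = {
        "significant_overlap": _cluster_overlaps(
            res_a, f0.tfr_freqs, f0.tfr_times, THETA_CLUSTER_BAND, THETA_WINDOW
        ),
        "min_p": res_a.min_p(),
    }

    # (b) N2 effect
    n2_effects = np.array([f.n2_effect_uv for f in feats])
    t, p = sps.ttest_1samp(n2_effects, 0.0)
    out["n2"] = {
        "mean_uv": float(n2_effects.mean()), "t": float(t), "p": float(p),
        "detected": bool(n2_effects.mean() > 0 and p < 0.05),
    }

    # (c) EEG-informed fMRI couplings
    coupling: dict = {}
    for mname in ("dacc_theta", "n2_depth"):
        coupling[mname] = {}
        for j, roi in enumerate(ROI_NAMES):
            nt_b = np.array([f.betas[mname][roi][NOTHINK] for f in feats])
            th_b = np.array([f.betas[mname][roi][THINK] for f in feats])
            g_nt = fusion.group_ttest(nt_b)
            g_th = fusion.group_ttest(th_b)
            coupling[mname][roi] = {
                "nothink_mean": g_nt["mean"], "nothink_p": g_nt["p"],
                "think_mean": g_th["mean"], "think_p": g_th["p"],
                # suppression-specific: significant negative coupling in
                # No-Think, and no significant negative coupling in Think
                "detected": bool(
                    g_nt["mean"] < 0 and g_nt["p"] < 0.05
                    and not (g_th["mean"] < 0 and g_th["p"] < 0.05)
                ),
            }
    hip_b = np.array(
        [f.betas["hipp_theta"]["hipp"][c] for f in feats for c in (THINK, NOTHINK)]
    ).reshape(len(feats), 2).mean(axis=1)
    g_hip = fusion.group_ttest(hip_b)
    coupling["hipp_theta_positive"] = {
        "mean": g_hip["mean"], "p": g_hip["p"],
        "detected": bool(g_hip["mean"] > 0 and g_hip["p"] < 0.05),
    }
    out["coupling"] = coupling

    # (d, e) directed GC arms. An arm counts as a directed effect when the
    # forward-vs-backward cluster test is significant inside the target band
    # AND the time-reversed control shows the inversion expected of a genuine
    # lagged interaction (group-mean reversed dominance in the band < 0).
    def _gc_arm(name, stratum, direction, band, perm_seed):
        a, b = direction
        fwd = _gc_matrix(feats, name, stratum, (a, b))
        bwd = _gc_matrix(feats, name, stratum, (b, a))
        res, fgrid = conn.gc_contrast(fwd, bwd, feats[0].gc_freqs,
                                      n_perm=n_perm, seed=perm_seed)
        sig = [c for c in res.significant if c.mass > 0
               and np.any((fgrid[c.bins] >= band[0])
                          & (fgrid[c.bins] <= band[1]))]
        bmask = (feats[0].gc_freqs >= band[0]) & (feats[0].gc_freqs <= band[1])
        rev_dom = np.array([
            (f.gc_rev[(name, stratum)].values[(a, b)][bmask]
             - f.gc_rev[(name, stratum)].values[(b, a)][bmask]).mean()
            for f in feats
        ])
        fwd_dom = np.array([
            (f.gc[(name, stratum)].values[(a, b)][bmask]
             - f.gc[(name, stratum)].values[(b, a)][bmask]).mean()
            for f in feats
        ])
        # flip-consistent inversion: the reversed dominance must change sign
        # with a magnitude commensurate with the forward dominance, not just
        # hover below zero (an SNR asymmetry leaves dominance unflipped)
        inverted = bool(
            rev_dom.mean() < 0
            and rev_dom.mean() < -0.25 * max(fwd_dom.mean(), 0.0)
        )
        return {
            "significant": bool(sig), "min_p": res.min_p(),
            "forward_dominance": float(fwd_dom.mean()),
            "reversed_dominance": float(rev_dom.mean()),
            "inverted": inverted,
            "directed": bool(sig) and inverted,
        }

    gc_out = {
        s: _gc_arm("dacc_rdlpfc", s, ("dACC", "rDLPFC"), GC_LOW_BAND,
                   seed + 1)
        for s in ("high", "low")
    }
    gc_out["detected"] = bool(
        gc_out["high"]["directed"] and not gc_out["low"]["directed"]
    )
    out["gc_dacc_rdlpfc"] = gc_out

    gc_b = {
        s: _gc_arm("rdlpfc_hipp", s, ("rDLPFC", "hipp"), GC_BETA_BAND,
                   seed + 2)
        for s in ("nothink", "think")
    }
    gc_b["detected"] = bool(gc_b["nothink"]["directed"])
    out["gc_rdlpfc_hipp"] = gc_b

    # (f) hippocampal theta, large- vs small-N2 No-Think trials
    diffs = []
    for f in feats:
        meta_cond = f.events["condition"].to_numpy()
        nt_sel = np.isfinite(f.n2_depth) & (meta_cond == NOTHINK)
        depth = np.where(nt_sel, f.n2_depth, np.nan)
        low, high = stats.median_split(depth)
        diffs.append(np.nanmean(f.hipp_theta[high])
                     - np.nanmean(f.hipp_theta[low]))
    diffs = np.array(diffs)
    t, p = sps.ttest_1samp(diffs, 0.0)
    out["hipp_theta_split"] = {
        "mean_diff": float(diffs.mean()), "t": float(t), "p": float(p),
        "detected": bool(diffs.mean() < 0 and p < 0.05),
    }

    # (g) N2 effect vs z-SIF
    recall = pd.concat([p.behavior for p in parts], ignore_index=True)
    acc = beh.recall_accuracy(recall)
    groups = {p.index: int(p.behavior["group"].iloc[0]) for p in parts}
    sif = beh.sif_and_zsif(acc, groups)
    sif = sif.set_index("participant").loc[[f.index for f in feats]]
    rp = stats.robust_pearson(n2_effects, sif["zsif"].to_numpy())
    out["sif"] = {
        "rho": rp["rho"], "p": rp["p"],
        "mean_sif": float(sif["sif"].mean()),
        "detected": bool(rp["rho"] > 0),
    }
    out["n2_effects"] = n2_effects.tolist()
    return out


def recovery_flags(summary: dict) -> dict[str, bool]:
    """Collapse an `analyze_dataset` summary to the seven detection flags."""
    coup = summary["coupling"]
    coupling_ok = all(
        coup[m][roi]["detected"]
        for m in ("dacc_theta", "n2_depth") for roi in ROI_NAMES
    )
    return {
        "theta_cluster": summary["theta_cluster"]["significant_overlap"],
        "n2": summary["n2"]["detected"],
        "coupling": coupling_ok,
        "gc_dacc_rdlpfc": summary["gc_dacc_rdlpfc"]["detected"],
        "gc_rdlpfc_hipp": summary["gc_rdlpfc_hipp"]["detected"],
        "hipp_theta_split": summary["hipp_theta_split"]["detected"],
        "sif": summary["sif"]["detected"],
    }
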