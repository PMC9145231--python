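"""Statistical validation harness: type-I error simulations, analytic
oracles and parameter-recovery rates.

These routines drive both the acceptance test suite and the acceptance
script. Each simulation draws data under an exchangeable null (or from the
ground-truth generator) and pushes it through the same inference code used in
the analyses, so the reported rates measure the pipeline as deployed.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from . import connectivity as conn
from . import fusion, pipeline, stats, synth

NULL_SIM_UNITS = 12
NULL_SIM_PERMS = 500


# ---------------------------------------------------------------------------
# type-I error rates at nominal alpha = 0.05
# ---------------------------------------------------------------------------

def type1_cluster(n_sim: int = 400, seed: int = 0,
                  n_units: int = NULL_SIM_UNITS,
                  shape: tuple[int, int] = (7, 20),
                  n_perm: int = NULL_SIM_PERMS) -> float:
    """Fraction of null datasets with any cluster p < 0.05 (paired test)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for s in range(n_sim):
        d = rng.standard_normal((n_units,) + shape)
        res = stats.cluster_permutation_test(
            d, None, unit="participant", n_perm=n_perm,
            seed=int(rng.integers(2**31)))
        hits += res.min_p() < 0.05
    return hits / n_sim


def type1_sliding(n_sim: int = 300, seed: int = 1,
                  n_units: int = NULL_SIM_UNITS,
                  n_perm: int = NULL_SIM_PERMS) -> float:
    """Fraction of null datasets where the two-step sliding-window procedure
    reports a significant unified cluster."""
    rng = np.random.default_rng(seed)
    freqs = np.arange(2.0, 9.0)
    times = np.arange(25.0, 1200.0, 50.0)
    hits = 0
    for s in range(n_sim):
        d = rng.standard_normal((n_units, freqs.size, times.size))
        res = stats.sliding_window_cluster(
            d, None, times, freqs, time_range_ms=(0.0, 1200.0),
            n_perm=n_perm, seed=int(rng.integers(2**31)))
        hits += bool(res.significant)
    return hits / n_sim


def _null_gc_spectra(rng, n_units, n_freq=29):
    base = np.abs(rng.standard_normal((n_units, n_freq + 2))) * 0.05
    # mild spectral smoothing, as real GC spectra are correlated across bins
    sm = lfilter(np.ones(3) / 3, [1.0], base, axis=1)[:, 2:]
    return sm + 0.02


def type1_gc_contrast(n_sim: int = 400, seed: int = 2,
                      n_units: int = NULL_SIM_UNITS,
                      n_perm: int = NULL_SIM_PERMS) -> float:
    """Directional GC contrast on exchangeable (no-dominance) spectra."""
    rng = np.random.default_rng(seed)
    freqs = np.arange(2.0, 31.0)
    hits = 0
    for s in range(n_sim):
        fwd = _null_gc_spectra(rng, n_units)
        bwd = _null_gc_spectra(rng, n_units)
        res, _ = conn.gc_contrast(fwd, bwd, freqs, n_perm=n_perm,
                                  seed=int(rng.integers(2**31)), tails="one")
        hits += bool(res.significant)
    return hits / n_sim


def type1_modulator_cluster(n_sim: int = 300, seed: int = 3,
                            n_units: int = NULL_SIM_UNITS,
                            grid: tuple[int, int, int] = (6, 6, 6),
                            n_trials: int = 40,
                            n_perm: int = 100) -> float:
    """Modulator-shuffling cluster-size correction under null coupling."""
    rng = np.random.default_rng(seed)
    n_vols, tr = 90, 1.5
    other = np.column_stack([np.ones(n_vols), np.linspace(-1, 1, n_vols)])
    hits = 0
    for s in range(n_sim):
        parts = []
        for p in range(n_units):
            onsets = np.sort(rng.uniform(2, n_vols * tr - 25, n_trials))
            values = rng.standard_normal(n_trials)
            # spatially smoothed noise, matching preprocessed BOLD
            y = gaussian_filter(
                rng.standard_normal((n_vols,) + grid), sigma=(0, 1, 1, 1)
            ).reshape(n_vols, -1)
            parts.append([fusion.prepare_modulator_run(
                y, onsets, values, other, tr)])
        out = fusion.permutation_cluster_correct(
            parts, grid, n_perm=n_perm, seed=int(rng.integers(2**31)))
        hits += bool(out["surviving_mask"].any())
    return hits / n_sim


# ---------------------------------------------------------------------------
# analytic oracles
# ---------------------------------------------------------------------------

def mc_vs_enumeration_gap(seed: int = 4, n_perm: int = 5000) -> float:
    """|Monte-Carlo - exhaustive| p-value gap for n = 5 paired units.

    Draws are retried deterministically until the observed effect crosses the
    cluster-forming threshold (otherwise there is no cluster whose p-value
    could be compared)."""
    for attempt in range(20):
        rng = np.random.default_rng(seed + 1000 * attempt)
        d = rng.standard_normal((5, 1)) + 2.0
        res = stats.cluster_permutation_test(
            d, None, unit="participant", n_perm=n_perm, seed=seed + 1)
        if res.clusters:
            break
    else:  # pragma: no cover - 20 misses in a row is effectively impossible
        raise RuntimeError("no supra-threshold draw found")

    def tstat(x):
        return x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))

    t_obs = abs(tstat(d[:, 0]))
    count = sum(
        abs(tstat(np.array([1 if b >> k & 1 else -1
                            for k in range(5)]) * d[:, 0])) >= t_obs - 1e-12
        for b in range(32)
    )
    p_exact = count / 32
    return abs(res.clusters[0].p_value - p_exact)


def fdr_matches_stepup(seed: int = 5, n_rep: int = 50) -> bool:
    """Exact agreement of fdr_bh with the closed-form step-up rule."""
    rng = np.random.default_rng(seed)
    for _ in range(n_rep):
        p = rng.random(rng.integers(1, 40))
        mask = stats.fdr_bh(p, q=0.05)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        below = p[order] <= 0.05 * np.arange(1, m + 1) / m
        expected = np.zeros(m, dtype=bool)
        if below.any():
            expected[order[: np.max(np.flatnonzero(below)) + 1]] = True
        if mask.tolist() != expected.tolist():
            return False
    return True


def glm_noiseless_relative_error(seed: int = 6) -> float:
    """Relative beta error of the parametric GLM on a noiseless fixture."""
    cfg = synth.reduced_config(seed=seed, n_participants=1)
    cfg.noise.bold_sd = 0.0
    cfg.noise.drift_amp = 0.0
    cfg.noise.artifact_rate = 0.0
    ev = synth.simulate_events(cfg, 0)
    lat = synth.simulate_latents(cfg, 0, ev)
    bold, _ = synth.simulate_bold(cfg, 0, ev, lat)
    design = fusion.build_parametric_design(
        ev, lat["early_control"], cfg.volumes_per_run, tr=cfg.tr)
    res = fusion.fit_glm(list(bold), design)
    got = float(res.betas.loc["mod_No-Think_eeg"].iloc[0])
    truth = cfg.bold.beta_control["dACC"]
    return abs(got - truth) / abs(truth)


def wilson_var1_errors(seed: int = 7) -> dict:
    """Factorization of the analytic VAR(1) CSD: reconstruction residual and
    innovation-covariance error."""
    A = np.array([[0.55, 0.0], [0.45, 0.5]])
    sigma = np.diag([1.0, 0.7])
    freqs = np.fft.rfftfreq(256, 1 / 250.0)
    S = np.empty((freqs.size, 2, 2), dtype=complex)
    for i, f in enumerate(freqs):
        H = np.linalg.inv(np.eye(2) - A * np.exp(-2j * np.pi * f / 250.0))
        S[i] = H @ sigma @ H.conj().T
    H_est, sig_est, resid = conn.wilson_factorize(S)
    sig_err = np.abs(sig_est - sigma).max() / np.abs(sigma).max()
    return {"residual": resid, "sigma_rel_err": float(sig_err)}


# ---------------------------------------------------------------------------
# parameter recovery and time reversal
# ---------------------------------------------------------------------------

def recovery_rates(seeds=(1, 2, 3, 4, 5), n_perm: int = 500,
                   n_participants: int = 12) -> dict:
    """Per-arm detection rates of the full pipeline over generator seeds."""
    counts: dict[str, int] = {}
    details = []
    for seed in seeds:
        cfg = synth.reduced_config(seed=seed, n_participants=n_participants)
        parts = synth.simulate_dataset(cfg)
        summ = pipeline.analyze_dataset(parts, n_perm=n_perm, seed=100 + seed)
        flags = pipeline.recovery_flags(summ)
        details.append({"seed": seed, "flags": flags, "summary": summ})
        for k, v in flags.items():
            counts[k] = counts.get(k, 0) + bool(v)
    rates = {k: v / len(seeds) for k, v in counts.items()}
    return {"rates": rates, "details": details, "n_seeds": len(seeds)}


def time_reversal_checks(seed: int = 8) -> dict:
    """The two time-reversal controls: a genuine unidirectional interaction
    flips its dominance; an SNR asymmetry on a shared signal does not."""
    rng = np.random.default_rng(seed)
    # unidirectional VAR(1)
    A = np.array([[0.55, 0.0], [0.45, 0.5]])
    L = np.linalg.cholesky(np.diag([1.0, 0.7]))
    n, ns, burn = 200, 250, 150
    x = np.zeros((n, 2, ns + burn))
    eps = np.einsum("ij,ntj->nit", L, rng.standard_normal((n, ns + burn, 2)))
    for t in range(1, ns + burn):
        x[:, :, t] = x[:, :, t - 1] @ A.T + eps[:, :, t]
    causal = conn.time_reversed_control(x[:, :, burn:], 250.0, (0, 1),
                                        ("x", "y"), band_hz=(2.0, 30.0))
    # SNR-asymmetric shared signal, causally silent
    s = lfilter([1.0], [1.0, -1.2, 0.8],
                rng.standard_normal((200, 300)), axis=-1)[:, 50:]
    mix = np.stack([s + 0.05 * rng.standard_normal(s.shape),
                    0.8 * s + 1.5 * rng.standard_normal(s.shape)], axis=1)
    spurious = conn.time_reversed_control(mix, 250.0, (0, 1),
                                          ("clean", "noisy"),
                                          band_hz=(2.0, 30.0))
    return {
        "causal_dominance": causal["dominance"],
        "causal_verdict": causal["verdict"],
        "spurious_dominance": spurious["dominance"],
        "spurious_verdict": spurious["verdict"],
    }
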