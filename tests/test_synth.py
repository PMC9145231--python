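"""Ground-truth generator: injected effects measured directly on the source
traces (independently of the analysis modules), forward-model linearity,
BOLD model, behavior link, determinism and fixture round trips."""

import numpy as np
import pytest
from scipy.signal import butter, filtfilt, hilbert

from tntfusion import fixtures, synth


def band_envelope(x, lo, hi, sfreq=250.0):
    """Direct band-power oracle: Butterworth bandpass + Hilbert envelope."""
    b, a = butter(4, [lo / (sfreq / 2), hi / (sfreq / 2)], btype="band")
    return np.abs(hilbert(filtfilt(b, a, x, axis=-1), axis=-1))


class TestSimulateSources:
    def test_null_config_pure_noise(self):
        cfg = synth.reduced_config(seed=1, n_participants=1).null_effects()
        cfg.n2_template.amp_think = 0.0
        cfg.n2_template.amp_nothink = 0.0
        cfg.theta_burst.amp_think = 0.0
        cfg.theta_burst.amp_nothink = 0.0
        sources, events, truth = synth.simulate_sources(cfg, 0)
        # trial-average evoked of the dACC centroid ~ 0 within MC error
        u = truth["roi_orientations"]["dACC"]
        u = u / np.linalg.norm(u)
        evoked = np.einsum("o,tos->ts", u, sources[:, 0]).mean(axis=0)
        mc_se = np.einsum("o,tos->ts", u, sources[:, 0]).std() \
            / np.sqrt(len(events))
        assert np.abs(evoked).max() < 6 * mc_se

    def test_nothink_theta_burst_positive(self):
        # oracle: bandpass envelope on raw source traces, before projection
        hits = 0
        for seed in range(8):
            cfg = synth.reduced_config(seed=20 + seed, n_participants=1)
            sources, events, truth = synth.simulate_sources(cfg, 0)
            sig = truth["signals"]["dACC"]
            env = band_envelope(sig, 4.0, 6.0)
            t = cfg.times_ms
            win = (t >= 250) & (t <= 800)
            cond = events["condition"].to_numpy()
            diff = env[cond == "No-Think"][:, win].mean() \
                - env[cond == "Think"][:, win].mean()
            hits += diff > 0
        assert hits >= 8 * 0.95 - 1e-9

    def test_directed_lag_asymmetry_high_conflict(self):
        # oracle: sample cross-correlation of the generated signals at the
        # configured lag, high-conflict No-Think trials only
        cfg = synth.reduced_config(seed=3, n_participants=1)
        sources, events, truth = synth.simulate_sources(cfg, 0)
        nt = (events["condition"] == "No-Think").to_numpy()
        high = nt & (truth["conflict"] > 1.25)
        x = truth["signals"]["dACC"][high]
        y = truth["signals"]["rDLPFC"][high]
        lag = int(round(cfg.mvar.lag_ms / 1000 * cfg.sfreq))

        def xcorr(a, b, k):
            # correlation between a(t - k) and b(t)
            aa = a[:, :-k].ravel()
            bb = b[:, k:].ravel()
            return np.corrcoef(aa, bb)[0, 1]

        assert xcorr(x, y, lag) > xcorr(y, x, lag) + 0.02

    def test_hippocampal_theta_decreases_with_n2(self):
        cfg = synth.reduced_config(seed=4, n_participants=1)
        sources, events, truth = synth.simulate_sources(cfg, 0)
        nt = (events["condition"] == "No-Think").to_numpy()
        env = band_envelope(truth["signals"]["hipp"], 4.0, 6.0)
        t = cfg.times_ms
        win = (t >= 650) & (t <= 1850)
        late = env[:, win].mean(axis=1)
        n2 = truth["n2_amp"]
        r = np.corrcoef(late[nt], n2[nt])[0, 1]
        assert r < -0.3

    def test_burst_window_validation(self):
        with pytest.raises(ValueError, match="exceeds"):
            cfg = synth.reduced_config(seed=0)
            cfg.theta_burst.window_ms = (250.0, 9000.0)
            cfg.validate()


class TestProjectToSensors:
    def test_unit_impulse_gives_gain_column(self, tiny_config):
        gain = synth.make_gain(tiny_config, 0)
        events = synth.simulate_events(tiny_config, 0).iloc[:1]
        sources = np.zeros((1, tiny_config.n_sources, 3,
                            tiny_config.times_ms.size))
        sources[0, 5, 1, 100] = 1.0
        ep = synth.project_to_sensors(sources, gain, 0.0, events,
                                      tiny_config, 0)
        assert np.allclose(ep.data[0, :, 100], gain.matrix[:, 5 * 3 + 1])
        assert np.allclose(np.delete(ep.data[0], 100, axis=1), 0.0)

    def test_superposition(self, tiny_config):
        gain = synth.make_gain(tiny_config, 0)
        events = synth.simulate_events(tiny_config, 0).iloc[:1]
        shape = (1, tiny_config.n_sources, 3, tiny_config.times_ms.size)
        s1 = np.zeros(shape)
        s2 = np.zeros(shape)
        s1[0, 2, 0, 50] = 1.0
        s2[0, 8, 2, 50] = 2.0
        e1 = synth.project_to_sensors(s1, gain, 0.0, events, tiny_config, 0)
        e2 = synth.project_to_sensors(s2, gain, 0.0, events, tiny_config, 0)
        e12 = synth.project_to_sensors(s1 + s2, gain, 0.0, events,
                                       tiny_config, 0)
        assert np.allclose(e12.data, e1.data + e2.data)

    def test_sensor_covariance_structure(self, tiny_config):
        # cov(sensors) ~ G cov(sources) G' + sigma^2 I over many samples
        rng = np.random.default_rng(5)
        gain = synth.make_gain(tiny_config, 0)
        events = synth.simulate_events(tiny_config, 0).iloc[:30]
        n_src = tiny_config.n_sources
        n_samp = tiny_config.times_ms.size
        sources = rng.standard_normal((30, n_src, 3, n_samp))
        sd = 0.5
        ep = synth.project_to_sensors(sources, gain, sd, events,
                                      tiny_config, 0)
        x = np.moveaxis(ep.data, 1, 0).reshape(len(gain.ch_names), -1)
        C = np.cov(x)
        C_expected = gain.matrix @ gain.matrix.T + sd**2 * np.eye(len(C))
        assert np.abs(C - C_expected).max() < 0.1

    def test_dimension_mismatch_rejected(self, tiny_config):
        gain = synth.make_gain(tiny_config, 0)
        events = synth.simulate_events(tiny_config, 0).iloc[:1]
        with pytest.raises(ValueError):
            synth.project_to_sensors(np.zeros((1, 3, 3, 10)), gain, 0.0,
                                     events, tiny_config, 0)


class TestSimulateBold:
    def test_zero_coupling_ignores_measures(self):
        cfg = synth.reduced_config(seed=6, n_participants=1)
        cfg.noise.bold_sd = 0.0
        cfg.noise.drift_amp = 0.0
        for roi in cfg.bold.beta_control:
            cfg.bold.beta_control[roi] = 0.0
        cfg.bold.beta_hipp_theta = 0.0
        ev = synth.simulate_events(cfg, 0)
        lat_a = synth.simulate_latents(cfg, 0, ev)
        lat_b = {k: (v * 3.0 if isinstance(v, np.ndarray) else v)
                 for k, v in lat_a.items()}
        lat_b["hipp_env"] = lat_a["hipp_env"]  # hipp env feeds no coupling now
        bold_a, _ = synth.simulate_bold(cfg, 0, ev, lat_a)
        bold_b, _ = synth.simulate_bold(cfg, 0, ev, lat_b)
        assert np.allclose(bold_a, bold_b)

    def test_injected_coupling_signs(self):
        cfg = synth.reduced_config(seed=7, n_participants=1)
        ev = synth.simulate_events(cfg, 0)
        lat = synth.simulate_latents(cfg, 0, ev)
        amps = synth.neural_amplitudes(cfg, ev, lat)
        nt = (ev["condition"] == "No-Think").to_numpy()
        e = lat["early_control"]
        r = np.corrcoef(amps["dACC"][nt], e[nt])[0, 1]
        assert r < -0.5  # negative early-control coupling in No-Think
        h = np.corrcoef(amps["hipp"], lat["hipp_env"])[0, 1]
        assert h > 0.3   # positive hippocampal theta coupling

    def test_onset_outside_run_rejected(self):
        cfg = synth.reduced_config(seed=8, n_participants=1)
        ev = synth.simulate_events(cfg, 0)
        lat = synth.simulate_latents(cfg, 0, ev)
        ev.loc[0, "onset_s"] = 1e4
        with pytest.raises(ValueError):
            synth.simulate_bold(cfg, 0, ev, lat)


class TestSimulateBehavior:
    def test_null_link_no_correlation(self):
        cfg = synth.reduced_config(seed=9, n_participants=1)
        cfg.sif.slope = 0.0
        from tntfusion import behavior as beh
        import pandas as pd
        factors, sifs = [], []
        for p in range(200):
            g = 1.0 + 0.3 * np.random.default_rng(p).standard_normal()
            tab = synth.simulate_behavior(cfg, p, g)
            acc = beh.recall_accuracy(tab)
            wide = acc.pivot_table(index="participant",
                                   columns=["condition", "test"],
                                   values="accuracy")
            sif = wide["Baseline"].mean(axis=1) - wide["No-Think"].mean(axis=1)
            factors.append(g)
            sifs.append(float(sif.iloc[0]))
        r = np.corrcoef(factors, sifs)[0, 1]
        assert abs(r) < 0.15

    def test_positive_link_rank_correlation(self):
        from scipy.stats import spearmanr
        cfg = synth.reduced_config(seed=10, n_participants=1)
        from tntfusion import behavior as beh
        factors, sifs = [], []
        for p in range(200):
            g = 1.0 + 0.3 * np.random.default_rng(1000 + p).standard_normal()
            tab = synth.simulate_behavior(cfg, p, g)
            acc = beh.recall_accuracy(tab)
            wide = acc.pivot_table(index="participant",
                                   columns=["condition", "test"],
                                   values="accuracy")
            sif = wide["Baseline"].mean(axis=1) - wide["No-Think"].mean(axis=1)
            factors.append(g)
            sifs.append(float(sif.iloc[0]))
        rho, _ = spearmanr(factors, sifs)
        assert rho > 0.2

    def test_forgetting_below_baseline(self, tiny_config):
        import pandas as pd
        from tntfusion import behavior as beh
        tabs = [synth.simulate_behavior(tiny_config, p, 1.0)
                for p in range(8)]
        acc = beh.recall_accuracy(pd.concat(tabs, ignore_index=True))
        means = acc.groupby("condition")["accuracy"].mean()
        assert means["No-Think"] < means["Baseline"]

    def test_nonfinite_factor_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            synth.simulate_behavior(tiny_config, 0, np.nan)


class TestDeterminismAndFixtures:
    def test_identical_config_identical_data(self, tiny_config):
        a = synth.simulate_participant(tiny_config, 1)
        b = synth.simulate_participant(tiny_config, 1)
        assert np.array_equal(a.epochs.data, b.epochs.data)
        assert np.array_equal(a.bold_runs, b.bold_runs)
        assert a.behavior.equals(b.behavior)

    def test_different_seeds_different_data_same_shapes(self):
        c1 = synth.reduced_config(seed=11, n_participants=1)
        c2 = synth.reduced_config(seed=12, n_participants=1)
        a = synth.simulate_participant(c1, 0)
        b = synth.simulate_participant(c2, 0)
        assert a.epochs.data.shape == b.epochs.data.shape
        assert not np.array_equal(a.epochs.data, b.epochs.data)

    def test_fixture_round_trip_bit_exact(self, one_participant, tmp_path):
        fixtures.write_fixture_set(one_participant, tmp_path / "p0")
        back = fixtures.read_fixture_set(tmp_path / "p0")
        assert np.array_equal(back["epochs"].data, one_participant.epochs.data)
        assert np.array_equal(back["gain"].matrix,
                              one_participant.gain.matrix)
        assert np.array_equal(back["bold_runs"], one_participant.bold_runs)
        assert np.array_equal(back["truth"]["early_control"],
                              one_participant.truth["early_control"])

    def test_same_seed_same_manifest(self, tiny_config, tmp_path):
        a = synth.simulate_participant(tiny_config, 2)
        b = synth.simulate_participant(tiny_config, 2)
        m1 = fixtures.write_fixture_set(a, tmp_path / "a")
        m2 = fixtures.write_fixture_set(b, tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_learned_counts_scale_with_study_size(self):
        # at the full study size the expected learned trial counts match the
        # observed group means (~142 Think / ~152 No-Think)
        cfg = synth.GroundTruthConfig(seed=13, n_participants=1)
        n_think = cfg.n_items[0] * cfg.n_repetitions * cfg.learned_prob[0]
        n_nothink = cfg.n_items[1] * cfg.n_repetitions * cfg.learned_prob[1]
        assert n_think == pytest.approx(143, abs=2)
        assert n_nothink == pytest.approx(152.6, abs=2)
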