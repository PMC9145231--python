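#!/usr/bin/env python
"""Sensor-space ERP and frontal-midline-theta analyses.

For each simulated participant: pooled frontocentral (Fz/FC1/FC2) evoked
responses per condition, the N2 effect (Think minus No-Think mean amplitude,
300-450 ms), and z-baselined time-frequency power. Group level: one-sample t
on the N2 effect and the No-Think vs Think cluster permutation test on the
TFR maps. Writes results/sensor_level/{n2_effects.tsv, theta_cluster.json}.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tntfusion import pipeline, stats, synth

OUT = Path(__file__).resolve().parent.parent / "results" / "sensor_level"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synth.reduced_config(seed=SEED)
    feats = [pipeline.compute_participant_features(
        synth.simulate_participant(cfg, p))
        for p in range(cfg.n_participants)]

    n2 = pd.DataFrame({
        "participant": [f.index for f in feats],
        "n2_effect_uv": [f.n2_effect_uv for f in feats],
    })
    n2.to_csv(OUT / "n2_effects.tsv", sep="\t", index=False)
    from scipy import stats as sps
    t, p = sps.ttest_1samp(n2["n2_effect_uv"], 0.0)

    nt = np.stack([f.tfr_nothink for f in feats])
    th = np.stack([f.tfr_think for f in feats])
    res = stats.cluster_permutation_test(nt, th, unit="participant",
                                         n_perm=1000, seed=SEED)
    f0 = feats[0]
    report = {
        "n2_group_mean_uv": float(n2["n2_effect_uv"].mean()),
        "n2_t": float(t), "n2_p": float(p),
        "theta_cluster_min_p": res.min_p(),
        "theta_cluster_overlaps_4to6hz_250to800ms": bool(
            pipeline._cluster_overlaps(
                res, f0.tfr_freqs, f0.tfr_times, (4.0, 6.0), (250.0, 800.0))),
    }
    (OUT / "theta_cluster.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
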