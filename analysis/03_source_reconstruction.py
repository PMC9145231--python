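#!/usr/bin/env python
"""LCMV source reconstruction and the hippocampal theta split.

Computes beamformer filters per participant, reconstructs dACC / rDLPFC /
hippocampal momentum, verifies localization of the No-Think-vs-Think evoked
contrast (epoch-average subtraction, filters on the 300-570 ms difference
window), and runs the large-vs-small-N2 hippocampal theta comparison
(4-6 Hz, 650-1850 ms). Writes results/source_level/source_report.json.
"""

import json
from pathlib import Path

import numpy as np
from scipy import stats as sps

from tntfusion import inverse, pipeline, stats, synth

OUT = Path(__file__).resolve().parent.parent / "results" / "source_level"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synth.reduced_config(seed=SEED)
    maps = []
    diffs = []
    dacc_members = None
    for p in range(cfg.n_participants):
        part = synth.simulate_participant(cfg, p)
        dacc_members = part.roi_members["dACC"]
        # evoked-contrast localization with epoch-average subtraction;
        # per-participant maps are noisy at this trial count, so (as in the
        # group analyses) the N2-window power maps are averaged across
        # participants before taking the peak
        diff = inverse.subtract_epoch_average(
            part.epochs, part.epochs, "No-Think", "Think")
        filt = inverse.lcmv_filters(diff, part.epochs.times, part.gain,
                                    window_ms=(300.0, 570.0))
        power = inverse.source_power_map(filt, diff, part.epochs.times,
                                         (300.0, 450.0))
        base = inverse.source_power_map(filt, diff, part.epochs.times,
                                        (-450.0, -50.0))
        maps.append((power - base) / max(base.mean(), 1e-12))
        # hippocampal theta, large vs small N2 trials
        f = pipeline.compute_participant_features(part)
        nt = (f.events["condition"] == "No-Think").to_numpy()
        depth = np.where(nt & np.isfinite(f.n2_depth), f.n2_depth, np.nan)
        low, high = stats.median_split(depth)
        diffs.append(np.nanmean(f.hipp_theta[high])
                     - np.nanmean(f.hipp_theta[low]))
    t, pval = sps.ttest_1samp(diffs, 0.0)
    group_peak = int(np.argmax(np.mean(maps, axis=0)))
    report = {
        "group_n2_peak_source": group_peak,
        "group_n2_peak_in_dacc": bool(group_peak in dacc_members),
        "hipp_theta_largeN2_minus_smallN2": float(np.mean(diffs)),
        "hipp_theta_split_t": float(t),
        "hipp_theta_split_p": float(pval),
    }
    (OUT / "source_report.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
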