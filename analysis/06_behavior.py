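#!/usr/bin/env python
"""Behavioral analysis: recall accuracy, SIF / z-SIF and the N2 link.

Scores conditionalized recall per condition and test type, runs the
condition x test-type repeated-measures ANOVA, computes per-participant SIF
and z-SIF, and correlates z-SIF with the N2 effect (robust Pearson).
Writes results/behavior/{recall_accuracy.tsv, behavior_report.json}.
"""

import json
from pathlib import Path

import pandas as pd

from tntfusion import behavior, pipeline, stats, synth

OUT = Path(__file__).resolve().parent.parent / "results" / "behavior"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synth.reduced_config(seed=SEED)
    parts = synth.simulate_dataset(cfg)
    recall = pd.concat([p.behavior for p in parts], ignore_index=True)
    acc = behavior.recall_accuracy(recall)
    acc.to_csv(OUT / "recall_accuracy.tsv", sep="\t", index=False)
    anova = behavior.condition_test_anova(acc)
    groups = {p.index: int(p.behavior["group"].iloc[0]) for p in parts}
    sif = behavior.sif_and_zsif(acc, groups)
    n2 = [pipeline.compute_participant_features(p).n2_effect_uv
          for p in parts]
    rp = stats.robust_pearson(
        n2, sif.set_index("participant")["zsif"].to_numpy())
    report = {
        "mean_recall_pct": {
            c: float(100 * acc[acc["condition"] == c]["accuracy"].mean())
            for c in ("Think", "No-Think", "Baseline")
        },
        "anova": anova,
        "sif_mean": float(sif["sif"].mean()),
        "n2_zsif_rho": rp["rho"], "n2_zsif_p": rp["p"],
    }
    (OUT / "behavior_report.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
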