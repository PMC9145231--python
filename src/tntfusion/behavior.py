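"""Recall scoring and suppression-induced forgetting (SIF).

Final-test recall is conditionalized on learning: only word pairs learned
before the think/no-think phase count. Accuracy is the proportion of learned
pairs recalled, per condition (Think / No-Think / Baseline) and test type
(same probe SP / independent probe IP). SIF is below-baseline recall of
suppressed items, Baseline minus No-Think accuracy averaged over the two
tests; z-SIF standardizes SIF within each counterbalancing group (participants
who saw the same items in the same conditions), removing item-memorability
variance. The condition x test-type comparison is a two-way repeated-measures
ANOVA plus paired t contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

REQUIRED_COLS = {
    "participant", "condition", "test", "learned", "recalled",
}


def recall_accuracy(table: pd.DataFrame) -> pd.DataFrame:
    """Per participant x condition x test recall proportion among learned
    items. Empty cells yield NaN (missing), never zero."""
    missing = REQUIRED_COLS - set(table.columns)
    if missing:
        raise ValueError(f"recall table lacks columns {sorted(missing)}")
    learned = table[table["learned"].astype(bool)]
    grp = learned.groupby(["participant", "condition", "test"], sort=True)
    acc = grp["recalled"].mean().rename("accuracy").reset_index()
    return acc


def sif_and_zsif(
    accuracies: pd.DataFrame, groups: pd.Series | dict
) -> pd.DataFrame:
    """Per-participant SIF (Baseline - No-Think accuracy, mean over SP and IP)
    and z-SIF standardized within counterbalancing group."""
    wide = accuracies.pivot_table(
        index="participant", columns=["condition", "test"], values="accuracy"
    )
    base = wide["Baseline"].mean(axis=1)
    nothink = wide["No-Think"].mean(axis=1)
    sif = (base - nothink).rename("sif")
    g = pd.Series(groups).reindex(sif.index)
    out = pd.DataFrame({"sif": sif, "group": g})
    zs = []
    for _, sub in out.groupby("group"):
        if len(sub) < 2:
            raise ValueError("need >= 2 participants per group for z-SIF")
        sd = sub["sif"].std(ddof=0)
        if sd < 1e-12:
            raise ValueError("zero within-group SD; z-SIF undefined")
        zs.append((sub["sif"] - sub["sif"].mean()) / sd)
    out["zsif"] = pd.concat(zs).reindex(out.index)
    return out.reset_index().rename(columns={"index": "participant"})


def condition_test_anova(
    accuracies: pd.DataFrame,
    conditions: tuple[str, str] = ("No-Think", "Baseline"),
) -> dict:
    """Two-way repeated-measures ANOVA (condition x test type) on accuracy,
    plus the paired No-Think-vs-Baseline t test within each test type."""
    sub = accuracies[accuracies["condition"].isin(conditions)].copy()
    counts = sub.groupby(["participant"]).size()
    if sub["accuracy"].isna().any() or counts.nunique() != 1:
        raise ValueError("incomplete condition x test cells")
    res = AnovaRM(
        sub, depvar="accuracy", subject="participant",
        within=["condition", "test"],
    ).fit()
    tab = res.anova_table
    out = {
        "condition_F": float(tab.loc["condition", "F Value"]),
        "condition_p": float(tab.loc["condition", "Pr > F"]),
        "test_F": float(tab.loc["test", "F Value"]),
        "test_p": float(tab.loc["test", "Pr > F"]),
        "interaction_F": float(tab.loc["condition:test", "F Value"]),
        "interaction_p": float(tab.loc["condition:test", "Pr > F"]),
    }
    for test_type in sorted(sub["test"].unique()):
        piv = sub[sub["test"] == test_type].pivot_table(
            index="participant", columns="condition", values="accuracy"
        )
        t, p = sps.ttest_rel(piv[conditions[1]], piv[conditions[0]])
        out[f"paired_t_{test_type}"] = float(t)
        out[f"paired_p_{test_type}"] = float(p)
    return out


def forgetter_split(sif: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """High/low forgetter partition: median split on SIF, median assigned to
    the low set (same tie rule as the trial-level median split)."""
    v = sif.to_numpy(dtype=float)
    med = np.median(v)
    low = np.flatnonzero(v <= med)
    high = np.flatnonzero(v > med)
    return low, high
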