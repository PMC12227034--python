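#!/usr/bin/env python
"""Emotion-classification performance on the synthetic dataset.

Response-label bias (multinomial chi-square), unbiased hit rates per
participant x condition x emotion, the 5-SD response-time outlier rule, and
condition x emotion repeated-measures ANOVAs (Greenhouse-Geisser corrected
where Mauchly's test indicates non-sphericity) on unbiased hit rates and
median correct RTs.  Writes performance.csv, confusion.csv and
behavior_anova.csv under results/.
"""

from __future__ import annotations

from pathlib import Path

from gazemark.behavior_metrics import (
    confusion_matrix,
    performance_table,
    response_bias_test,
    response_label_summary,
    rt_outlier_filter,
)
from gazemark.core_data import load_dataset
from gazemark.stats_inference import rm_anova

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    _, trials = load_dataset(ROOT / "data" / "fixations.csv", ROOT / "data" / "trials.csv")

    counts = trials["response"].value_counts().to_dict()
    chi2, df, p = response_bias_test(counts)
    print(f"response bias: chi2({df}) = {chi2:.1f}, p = {p:.2g}")
    summary = response_label_summary(counts, trials["participant_id"].nunique())
    print(summary.round(2).to_string())

    filtered, removed = rt_outlier_filter(trials)
    print(f"RT outliers removed: {removed * 100:.2f}% of correct trials")

    perf = performance_table(filtered)
    perf.to_csv(ROOT / "performance.csv", index=False)
    confusion_matrix(trials).to_csv(ROOT / "confusion.csv")

    rows = []
    for dv in ("hu", "median_rt_s"):
        table = rm_anova(perf.dropna(subset=[dv]), dv, ["condition", "emotion"])
        table.insert(0, "dv", dv)
        rows.append(table)
        print(f"\nANOVA on {dv}:")
        print(
            table[["effect", "F", "df1_gg", "df2_gg", "p_reported", "np2"]]
            .round(4)
            .to_string(index=False)
        )
    import pandas as pd

    pd.concat(rows).to_csv(ROOT / "behavior_anova.csv", index=False)


if __name__ == "__main__":
    main()
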