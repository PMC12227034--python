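#!/usr/bin/env python
"""Leave-one-subject-out gaze decoding on the synthetic dataset.

Decodes the viewed emotion within each presentation condition, emotion on
correct-only vs incorrect-only trials collapsed over condition, and the
presentation condition itself, from duration-weighted fixation patterns
scored against the training folds' marginal fixation density maps.  Writes
decoding.csv (one row per analysis, Table-style: mean %, SD, t, one-sided
p, Cohen's d with one-sided CI lower bound) under results/.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from gazemark.core_data import CONDITIONS, load_dataset
from gazemark.gaze_decoding import DecodingSpec, loso_decode

ROOT = Path(__file__).resolve().parent.parent / "results"

SPECS: list[tuple[str, DecodingSpec]] = [
    *[
        (f"emotion | {cond} | all fixations, all trials",
         DecodingSpec(category_field="emotion", condition_filter=cond))
        for cond in CONDITIONS
    ],
    ("emotion | collapsed | all fixations, correct trials",
     DecodingSpec(category_field="emotion", trial_scope="correct_only")),
    ("emotion | collapsed | all fixations, incorrect trials",
     DecodingSpec(category_field="emotion", trial_scope="incorrect_only")),
    ("condition | all fixations, all trials", DecodingSpec(category_field="condition")),
    ("condition | first fixations, all trials",
     DecodingSpec(category_field="condition", fixation_scope="first")),
]


def main() -> None:
    fixations, trials = load_dataset(
        ROOT / "data" / "fixations.csv", ROOT / "data" / "trials.csv"
    )
    rows = []
    for name, spec in SPECS:
        res = loso_decode(fixations, trials, spec)
        rows.append(
            {
                "analysis": name,
                "mean_pct": 100 * res.mean,
                "sd_pct": 100 * res.sd,
                "chance_pct": 100 * res.chance,
                "t": res.t,
                "df": res.df,
                "p_one_sided": res.p_one_sided,
                "d": res.d,
                "d_ci_lower": res.d_ci_lower,
                "ties": res.tie_count,
            }
        )
        print(
            f"{name}: {100 * res.mean:.1f}% (SD {100 * res.sd:.1f}, chance "
            f"{100 * res.chance:.0f}%), t({res.df}) = {res.t:.2f}, "
            f"p = {res.p_one_sided:.2g}, d = {res.d:.2f} ({res.d_ci_lower:.2f}, inf)"
        )
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "decoding.csv", index=False)
    print(f"\nwrote {ROOT / 'decoding.csv'}")


if __name__ == "__main__":
    main()
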