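#!/usr/bin/env python
"""Fixation-density-map similarity analyses and heatmaps.

Within- vs between-emotion correlations of individual-participant FDMs
(all-trials maps against correct-only maps, Fisher-z + paired t), the
within-emotion correlations across all six condition pairs, and rendered
heatmaps of the group-level marginal FDMs per emotion.  Writes
cross_condition_similarity.csv and heatmaps/*.png under results/.
"""

from __future__ import annotations

from pathlib import Path

from gazemark.cli_report import render_heatmap
from gazemark.core_data import load_dataset
from gazemark.density_maps import (
    FdmSpec,
    category_fdms,
    cross_condition_similarity,
    marginal_maps,
    similarity_contrast,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fixations, trials = load_dataset(
        ROOT / "data" / "fixations.csv", ROOT / "data" / "trials.csv"
    )

    contrast = similarity_contrast(
        fixations, trials, FdmSpec(trial_scope="all"), FdmSpec(trial_scope="correct_only")
    )
    per = contrast.per_participant
    print(
        "within- vs between-emotion FDM correlations "
        "(all-trial maps vs correct-only maps):"
    )
    print(
        f"  within r = {per['within_r'].mean():.3f} (SD {per['within_r'].std():.3f}), "
        f"between r = {per['between_r'].mean():.3f} (SD {per['between_r'].std():.3f})"
    )
    print(
        f"  paired t({contrast.df}) = {contrast.t:.2f}, one-sided p = {contrast.p:.2g}, "
        f"d_z = {contrast.d_z:.2f}"
    )

    cross = cross_condition_similarity(fixations, trials)
    cross.to_csv(ROOT / "cross_condition_similarity.csv", index=False)
    print("\nwithin-emotion FDM correlations across condition pairs:")
    for row in cross.sort_values("mean_r", ascending=False).itertuples():
        print(f"  {row.condition_a} vs {row.condition_b}: "
              f"{row.mean_r:.3f} (SD {row.sd_r:.3f})")

    heat_dir = ROOT / "heatmaps"
    marg = marginal_maps(category_fdms(fixations, trials))
    for emotion, m in marg.items():
        render_heatmap(m, heat_dir / f"marginal_{emotion}.png")
    print(f"\nwrote marginal-FDM heatmaps to {heat_dir}")


if __name__ == "__main__":
    main()
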